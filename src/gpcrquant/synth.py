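"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* fields of non-overlapping yeast-like elliptical cells with a bright
  peripheral membrane band, dimmer cytoplasm, one vacuole disc, an
  additive illumination ramp and Poisson + read noise;
* two-channel vacuole line profiles whose marker channel carries two
  membrane peaks and whose cargo channel is either "full" (bright lumen)
  or "empty" (dim lumen);
* Hill-shaped dose-response plates on the half-log pheromone ladder;
* binomially sampled mating colony counts.

Effect presets encode the study's printed relative changes (membrane
abundance, Emax, EC50, empty-vacuole fold, mating probability) as
multipliers against a control preset, so each pipeline stage can be
validated by parameter recovery. Absolute intensity scales are free
choices; only the ratios are meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .dose import DOSE_LADDER_UM, hill_model
from .io import FluorImage, LabelMask
from .vacuole import LineProfile

logger = logging.getLogger("gpcrquant")

FIELD_SIZE = 1200
#: minimum jittered-grid pitch guaranteeing >= 3 px clearance between
#: ellipses with semi-axes up to 60 px and +/- 5 px centre jitter
_MIN_PITCH = 150.0


def field_capacity(size: int = FIELD_SIZE) -> int:
    """Number of cells placeable in one field at guaranteed clearance."""
    n = int(size // _MIN_PITCH)
    return n * n


FIELD_CAPACITY = field_capacity(FIELD_SIZE)

# absolute intensity scales (AU); arbitrary, only ratios carry meaning
MEMBRANE_AU = 8000.0
CYTOPLASM_AU = 1000.0
VACUOLE_AU = 1500.0
BASELINE_AU = 100.0
GRADIENT_LO_AU = 500.0
GRADIENT_HI_AU = 1500.0
READ_NOISE_SD = 20.0
MEMBRANE_BAND_PX = 4.0

# control Hill parameters (AU / uM)
HILL_CONTROL = {"b": 50.0, "emax": 1000.0, "ec50": 1.0, "hill_n": 1.2}


@dataclass(frozen=True)
class EffectPreset:
    """Relative effect sizes of one experimental condition vs control."""

    name: str
    membrane_scale: float = 1.0
    emax_scale: float = 1.0
    ec50_scale: float = 1.0
    empty_vacuole_prob: float = 0.15
    mating_prob: float = 0.78

    def __post_init__(self) -> None:
        if min(self.membrane_scale, self.emax_scale, self.ec50_scale) <= 0:
            raise ValueError("scale multipliers must be > 0")
        if not (0 <= self.empty_vacuole_prob <= 1 and 0 <= self.mating_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


def builtin_presets() -> dict[str, EffectPreset]:
    """Named effect presets calibrated to the study's printed changes.

    Membrane scales are 1 minus the printed percent reduction at the cell
    periphery (stationary 62%, low nitrogen 66%, rapamycin: Ste2 60%,
    Ste3 22%, Pma1 +16%); transcription scales follow the printed Emax /
    EC50 changes (rapamycin -26%, ypk1-delta +433% / -39%, atg8-delta
    +30%); vacuole presets fix the wild-type empty fraction at 0.15 and
    encode the 4-fold atg8-delta increase; mating probabilities are the
    printed 78% / 53% efficiencies.
    """
    presets = [
        EffectPreset("control"),
        EffectPreset("stationary", membrane_scale=0.38),
        EffectPreset("low_nitrogen", membrane_scale=0.34),
        EffectPreset("rapamycin_ste2", membrane_scale=0.40),
        EffectPreset("rapamycin_ste3", membrane_scale=0.78),
        EffectPreset("rapamycin_pma1", membrane_scale=1.16),
        EffectPreset("rapamycin_transcription", emax_scale=0.74),
        EffectPreset("ypk1_delta", emax_scale=5.33, ec50_scale=0.61),
        EffectPreset("atg8_delta_transcription", emax_scale=1.30),
        EffectPreset("wt_vacuole", empty_vacuole_prob=0.15),
        EffectPreset("atg8_vacuole", empty_vacuole_prob=0.60),
        EffectPreset("mating_control", mating_prob=0.78),
        EffectPreset("mating_rapamycin", mating_prob=0.53),
    ]
    return {p.name: p for p in presets}


def render_field(
    preset: EffectPreset,
    n_cells: int,
    seed: int,
    noise: bool = True,
    gradient: bool = True,
    size: int = FIELD_SIZE,
    label_offset: int = 0,
) -> tuple[FluorImage, LabelMask, pd.DataFrame]:
    """Render one field of non-overlapping cells with ground truth.

    Cells are ellipses (semi-axes U(45, 60) px) placed on a jittered grid,
    which guarantees pairwise clearance >= 3 px and keeps every cell large
    enough to survive the 5000-px size filter. Each cell has a 4-px
    peripheral membrane band at 8000 x membrane_scale AU, cytoplasm at
    1000 AU and one vacuole disc at 1500 AU. ``gradient`` adds a planar
    500 -> 1500 AU illumination ramp; ``noise`` adds Poisson counting
    noise plus Gaussian read noise (sd 20 AU).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    capacity = field_capacity(size)
    if n_cells > capacity:
        raise ValueError(
            f"cannot place {n_cells} non-overlapping cells in one {size}x{size} "
            f"field (capacity {capacity}); render multiple fields instead"
        )
    rng = np.random.default_rng(seed)
    grid_n = int(size // _MIN_PITCH)
    pitch = size / grid_n
    sites = [(pitch * (i + 0.5), pitch * (j + 0.5))
             for i in range(grid_n) for j in range(grid_n)]
    chosen = rng.choice(len(sites), size=n_cells, replace=False)

    img = np.full((size, size), BASELINE_AU, dtype=np.float64)
    labels = np.zeros((size, size), dtype=np.int32)
    membrane_au = MEMBRANE_AU * preset.membrane_scale
    truth_rows = []
    for k, si in enumerate(chosen):
        cid = label_offset + k + 1
        cy = sites[si][0] + rng.uniform(-5, 5)
        cx = sites[si][1] + rng.uniform(-5, 5)
        a = rng.uniform(45, 60)  # row semi-axis
        b = rng.uniform(45, 60)  # col semi-axis
        r0, r1 = int(np.floor(cy - a)) - 1, int(np.ceil(cy + a)) + 2
        c0, c1 = int(np.floor(cx - b)) - 1, int(np.ceil(cx + b)) + 2
        rr, cc = np.mgrid[r0:r1, c0:c1]
        inside = ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0
        depth = ndimage.distance_transform_edt(inside)
        membrane = inside & (depth <= MEMBRANE_BAND_PX)
        vac_r = 0.35 * min(a, b)
        vacuole = (rr - cy) ** 2 + (cc - cx) ** 2 <= vac_r ** 2
        crop = img[r0:r1, c0:c1]
        crop[inside] = CYTOPLASM_AU
        crop[vacuole & inside] = VACUOLE_AU
        crop[membrane] = membrane_au
        labels[r0:r1, c0:c1][inside] = cid
        truth_rows.append(
            {
                "cell_id": cid, "row": cy, "col": cx,
                "semi_axis_row": a, "semi_axis_col": b,
                "membrane_intensity": membrane_au,
                "cytoplasm_intensity": CYTOPLASM_AU,
                "vacuole_intensity": VACUOLE_AU,
                "group_id": preset.name,
            }
        )
    if gradient:
        ramp = np.linspace(GRADIENT_LO_AU, GRADIENT_HI_AU, size)
        img += ramp[np.newaxis, :]
    if noise:
        img = rng.poisson(img).astype(np.float64)
        img += rng.normal(0.0, READ_NOISE_SD, size=img.shape)
        img = np.round(img)
    if img.max() > 65535:
        logger.warning("rendered intensities exceed 65535; clipping")
    img = np.clip(img, 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(truth_rows)
    return FluorImage(pixels=img, channel="GFP"), LabelMask(labels=labels), truth


def render_cohort(
    preset: EffectPreset,
    n_cells: int,
    seed: int,
    noise: bool = True,
    gradient: bool = True,
    cells_per_field: int = 50,
) -> list[tuple[FluorImage, LabelMask, pd.DataFrame]]:
    """Render ``n_cells`` of one condition split across as many fields as
    needed (``cells_per_field`` each), with globally unique cell ids."""
    fields = []
    remaining = n_cells
    field_i = 0
    while remaining > 0:
        n = min(remaining, cells_per_field)
        fields.append(
            render_field(
                preset, n, seed=seed + field_i, noise=noise, gradient=gradient,
                label_offset=field_i * cells_per_field,
            )
        )
        remaining -= n
        field_i += 1
    return fields


def _gauss(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


def gen_profiles(
    preset: EffectPreset,
    n_cells: int,
    length: int = 101,
    seed: int = 0,
    noise: bool = True,
) -> tuple[list[LineProfile], pd.DataFrame]:
    """Generate two-channel vacuole line profiles with known phenotypes.

    The marker channel carries two sharp membrane peaks (sd 2 px) near
    one quarter and three quarters of the scan (jitter +/- 5 px) over a
    50 AU baseline. The cargo channel has 100 AU membrane shoulders at the
    peak positions and a lumen plateau at 3x the shoulder level for "full"
    cells or 0.3x for "empty" cells, drawn per Bernoulli(empty_vacuole_prob).
    Noise is Gaussian with sd = 5% of the local signal.
    """
    if length < 31:
        raise ValueError("profile length must be >= 31")
    rng = np.random.default_rng(seed)
    x = np.arange(length, dtype=float)
    q = length // 4
    shoulder = 100.0
    profiles: list[LineProfile] = []
    truth_rows = []
    for k in range(n_cells):
        pl = int(q + rng.integers(-5, 6))
        pr = int(3 * q + rng.integers(-5, 6))
        empty = bool(rng.random() < preset.empty_vacuole_prob)
        marker = 50.0 + 400.0 * (_gauss(x, pl, 2.0) + _gauss(x, pr, 2.0))
        plateau = (0.3 if empty else 3.0) * shoulder
        cargo = 10.0 + shoulder * (_gauss(x, pl, 2.0) + _gauss(x, pr, 2.0))
        cargo[pl + 2: pr - 1] += plateau
        if noise:
            marker = marker + rng.normal(0.0, 0.05 * marker)
            cargo = cargo + rng.normal(0.0, 0.05 * np.abs(cargo))
        profiles.append(
            LineProfile(marker=marker, cargo=cargo, cell_id=k + 1, group=preset.name)
        )
        truth_rows.append(
            {
                "cell_id": k + 1, "group": preset.name,
                "peak_left": pl, "peak_right": pr,
                "phenotype": "empty" if empty else "full",
            }
        )
    return profiles, pd.DataFrame(truth_rows)


def gen_dose_response(
    preset: EffectPreset,
    replicates: int = 9,
    cv: float = 0.10,
    seed: int = 0,
    doses_um: tuple[float, ...] = DOSE_LADDER_UM,
) -> pd.DataFrame:
    """Simulate a dose-response plate for one condition.

    The true curve is the control Hill curve (b 50 AU, Emax 1000 AU,
    EC50 1 uM, slope 1.2) with Emax and EC50 multiplied by the preset
    scales. Each well's normalized response is truth x (1 + N(0, cv)); the
    stored fluorescence is that value multiplied by a simulated culture
    density A600 ~ U(0.6, 0.8), which ``normalize_density`` must undo.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    truth = {
        "b": HILL_CONTROL["b"],
        "emax": HILL_CONTROL["emax"] * preset.emax_scale,
        "ec50": HILL_CONTROL["ec50"] * preset.ec50_scale,
        "hill_n": HILL_CONTROL["hill_n"],
    }
    rows = []
    for rep in range(1, replicates + 1):
        for d in doses_um:
            mu = hill_model(d, **truth)
            value = mu * (1.0 + rng.normal(0.0, cv)) if cv > 0 else mu
            density = rng.uniform(0.6, 0.8)
            rows.append(
                {
                    "group": preset.name, "replicate": f"rep{rep}",
                    "dose_uM": d, "fluorescence": value * density,
                    "a600": density,
                }
            )
    return pd.DataFrame(rows)


def gen_mating_counts(
    preset: EffectPreset,
    n_assays: int = 5,
    n_competent: float = 500.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate colony counts for quantitative mating assays.

    Per assay, the mating-competent count is Poisson(n_competent) and the
    diploid count Binomial(competent, mating_prob); dilution factors are
    equal, so efficiency estimates the mating probability directly.
    """
    if n_assays < 1:
        raise ValueError("n_assays must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(1, n_assays + 1):
        competent = int(rng.poisson(n_competent))
        diploid = int(rng.binomial(competent, preset.mating_prob)) if competent else 0
        rows.append(
            {
                "assay_id": f"assay{k}", "treatment": preset.name,
                "competent_colonies": competent, "diploid_colonies": diploid,
                "dilution_competent": 1.0, "dilution_diploid": 1.0,
            }
        )
    return pd.DataFrame(rows)
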