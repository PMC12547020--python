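"""Vacuolar lumen-vs-membrane cargo classification from two-channel line scans.

A line scan through the largest vacuolar body crosses the vacuole membrane
twice, producing two peaks in the membrane-marker channel (Vph1). The six
positions at those peaks +/- 1 define the vacuolar membrane; positions
strictly between the two flanking triplets define the lumen. The cargo
(receptor) channel is averaged over both index sets and the lumen:membrane
ratio decides the phenotype: > 1 -> the vacuole is "full" of cargo
(phenotype 1), < 1 -> "empty" (phenotype 2). Ratio exactly 1 is classified
full so the rule is total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.restoration import rolling_ball

from .io import FluorImage, RunConfig

logger = logging.getLogger("gpcrquant")


class UnclassifiableCell(ValueError):
    """The line profile does not support the two-peak classification."""


@dataclass
class LineProfile:
    """Paired marker (vacuole membrane) and cargo (receptor) intensity series."""

    marker: np.ndarray
    cargo: np.ndarray
    cell_id: int | str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.marker = np.asarray(self.marker, dtype=float)
        self.cargo = np.asarray(self.cargo, dtype=float)
        if self.marker.ndim != 1 or self.cargo.ndim != 1:
            raise ValueError("marker and cargo must be 1-D series")
        if self.marker.size != self.cargo.size:
            raise ValueError("marker and cargo lengths differ")
        if self.marker.size < 7:
            raise ValueError("line profile must have length >= 7")


@dataclass
class VacuolePhenotype:
    peak_left: int
    peak_right: int
    membrane_idx: np.ndarray
    lumen_idx: np.ndarray
    mem_mean: float
    lum_mean: float
    ratio: float
    klass: str  # "full" or "empty"


def rolling_ball_subtract(img: FluorImage, cfg: RunConfig | None = None) -> FluorImage:
    """Rolling-ball background subtraction (grayscale ball, radius 50 default).

    The background envelope obtained by rolling a ball of the configured
    radius under the intensity surface is subtracted; tiny negative
    residuals from numeric error are clipped to zero.
    """
    cfg = cfg or RunConfig()
    px = img.pixels.astype(np.float64)
    background = rolling_ball(px, radius=cfg.rollingball_radius)
    out = px - background
    out[(out < 0) & (out > -1e-6 * max(px.max(), 1.0))] = 0.0
    return FluorImage(pixels=out, channel=img.channel, pixel_size_um=img.pixel_size_um)


def sample_line(
    img: FluorImage, p0: tuple[float, float], p1: tuple[float, float]
) -> np.ndarray:
    """Bilinear samples along the segment p0 -> p1 at unit-pixel steps.

    Returns ceil(Euclidean distance) + 1 samples including both endpoints.
    """
    h, w = img.pixels.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise ValueError(f"endpoint {p} lies outside the image ({h}x{w})")
    dist = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    n = int(np.ceil(dist)) + 1
    rows = np.linspace(p0[0], p1[0], n)
    cols = np.linspace(p0[1], p1[1], n)
    return ndimage.map_coordinates(
        img.pixels.astype(float), [rows, cols], order=1, mode="nearest"
    )


def find_vacuole_peaks(marker: np.ndarray, min_sep: int = 10) -> tuple[int, int]:
    """Locate the two dominant membrane crossings in the marker channel.

    Strict local maxima are ranked by topographic prominence; among all
    pairs separated by at least ``min_sep`` samples, the pair with the
    greatest combined prominence is returned (left index first).
    """
    marker = np.asarray(marker, dtype=float)
    if marker.size < 7:
        raise UnclassifiableCell("profile too short for peak finding")
    peaks, props = find_peaks(marker, prominence=0)
    if peaks.size < 2:
        raise UnclassifiableCell(
            f"found {peaks.size} local maxima, need 2 separated by >= {min_sep}"
        )
    prom = props["prominences"]
    best: tuple[int, int] | None = None
    best_score = -np.inf
    for i in range(peaks.size):
        for j in range(i + 1, peaks.size):
            if peaks[j] - peaks[i] >= min_sep:
                score = prom[i] + prom[j]
                if score > best_score:
                    best_score = score
                    best = (int(peaks[i]), int(peaks[j]))
    if best is None:
        raise UnclassifiableCell(
            f"no pair of local maxima separated by >= {min_sep} samples"
        )
    return best


def classify_vacuole(profile: LineProfile, min_sep: int = 10) -> VacuolePhenotype:
    """Classify one cell's vacuole as cargo-full or cargo-empty.

    Membrane positions are the two marker peaks each with their immediate
    neighbours (six indices, clipped at the series bounds); the lumen is
    the closed range strictly between the triplets. The cargo channel is
    averaged over each set and klass = full iff lumen/membrane >= 1.
    """
    pl, pr = find_vacuole_peaks(profile.marker, min_sep=min_sep)
    if pl + 4 > pr:
        raise UnclassifiableCell(f"peaks at {pl},{pr} too close for a lumen")
    L = profile.cargo.size
    mem = np.unique(np.clip([pl - 1, pl, pl + 1, pr - 1, pr, pr + 1], 0, L - 1))
    if mem.size < 6:
        logger.warning(
            "cell %s: membrane triplet clipped at profile bounds (%d samples)",
            profile.cell_id, mem.size,
        )
    lum = np.arange(pl + 2, pr - 1)
    mem_mean = float(profile.cargo[mem].mean())
    lum_mean = float(profile.cargo[lum].mean())
    if mem_mean <= 0:
        raise UnclassifiableCell(f"non-positive membrane mean {mem_mean}")
    ratio = lum_mean / mem_mean
    return VacuolePhenotype(
        peak_left=pl,
        peak_right=pr,
        membrane_idx=mem,
        lumen_idx=lum,
        mem_mean=mem_mean,
        lum_mean=lum_mean,
        ratio=ratio,
        klass="full" if ratio >= 1 else "empty",
    )


def classify_profiles(
    profiles: list[LineProfile], min_sep: int = 10
) -> pd.DataFrame:
    """Classify a cohort of line profiles; unclassifiable cells are logged
    and excluded. Returns one row per classified cell."""
    rows = []
    n_excluded = 0
    for p in profiles:
        try:
            ph = classify_vacuole(p, min_sep=min_sep)
        except UnclassifiableCell as exc:
            n_excluded += 1
            logger.warning("cell %s excluded: %s", p.cell_id, exc)
            continue
        rows.append(
            {
                "cell_id": p.cell_id,
                "group": p.group,
                "peak_left": ph.peak_left,
                "peak_right": ph.peak_right,
                "mem_mean": ph.mem_mean,
                "lum_mean": ph.lum_mean,
                "ratio": ph.ratio,
                "klass": ph.klass,
            }
        )
    if n_excluded:
        logger.info("%d/%d cells unclassifiable", n_excluded, len(profiles))
    return pd.DataFrame(
        rows,
        columns=["cell_id", "group", "peak_left", "peak_right",
                 "mem_mean", "lum_mean", "ratio", "klass"],
    )


def empty_fraction(
    classified: pd.DataFrame,
    test_group: str | None = None,
    reference_group: str | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Per-group empty-vacuole fractions, plus the test/reference fold change.

    fold = fraction(test) / fraction(reference); None ("undefined") when the
    reference fraction is zero or groups are not named.
    """
    if classified.empty:
        raise ValueError("no classified cells")
    summary = (
        classified.groupby("group")["klass"]
        .agg(
            n_classified="size",
            n_empty=lambda s: int((s == "empty").sum()),
        )
        .reset_index()
    )
    summary["empty_fraction"] = summary["n_empty"] / summary["n_classified"]
    fold: float | None = None
    if test_group is not None and reference_group is not None:
        by_group = summary.set_index("group")["empty_fraction"]
        for g in (test_group, reference_group):
            if g not in by_group.index:
                raise KeyError(f"unknown group {g!r}")
        ref = by_group[reference_group]
        if ref == 0:
            logger.warning("reference empty fraction is 0; fold change undefined")
            fold = None
        else:
            fold = float(by_group[test_group] / ref)
    return summary, fold
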