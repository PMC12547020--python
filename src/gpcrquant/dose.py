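"""Hill dose-response fitting for pheromone-induced transcription assays.

Reporter fluorescence is normalized to culture density (A600), per-dose
replicate means are fit to a four-parameter Hill curve

    y(d) = b + Emax * d^n / (EC50^n + d^n)

by bounded least squares (all parameters bounded below by zero, unbounded
above), and 95% confidence intervals are derived from the asymptotic
covariance with a t-quantile at n_points - 4 degrees of freedom. Two fits
are compared parameter-by-parameter with the conservative CI-overlap rule:
a difference is called significant only when the intervals are disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("gpcrquant")

PARAM_NAMES = ("b", "emax", "ec50", "hill_n")

#: Half-log alpha-factor dose ladder (uM) used by the plate assay.
DOSE_LADDER_UM = (0.0, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0)


@dataclass
class HillFit:
    b: float
    emax: float
    ec50: float
    hill_n: float
    ci95: dict[str, tuple[float, float]]
    residual_sd: float
    n_points: int
    converged: bool
    flags: list[str] = field(default_factory=list)

    @property
    def params(self) -> dict[str, float]:
        return {"b": self.b, "emax": self.emax, "ec50": self.ec50, "hill_n": self.hill_n}


def hill_model(dose, b, emax, ec50, hill_n):
    """Hill curve value; dose 0 maps exactly to the baseline b."""
    dose = np.asarray(dose, dtype=float)
    out = np.full(dose.shape, float(b))
    pos = dose > 0
    dn = dose[pos] ** hill_n
    out[pos] = b + emax * dn / (ec50 ** hill_n + dn)
    return out if out.ndim else float(out)


def normalize_density(table: pd.DataFrame) -> pd.DataFrame:
    """Divide fluorescence by culture density (A600) row-wise.

    Expects columns group, replicate, dose_uM, fluorescence, a600; adds
    ``normalized``. Rows with non-positive density are an input error.
    """
    required = {"group", "dose_uM", "fluorescence", "a600"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"dose-response table missing columns: {sorted(missing)}")
    bad = table.index[table["a600"] <= 0].tolist()
    if bad:
        raise ValueError(f"non-positive culture density in rows {bad}")
    out = table.copy()
    out["normalized"] = out["fluorescence"] / out["a600"]
    return out


def dose_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-dose replicate means of the density-normalized response."""
    if "normalized" not in table.columns:
        table = normalize_density(table)
    return (
        table.groupby("dose_uM", as_index=False)["normalized"]
        .agg(mean_response="mean", n_replicates="size")
        .sort_values("dose_uM", ignore_index=True)
    )


def _initial_guess(dose: np.ndarray, y: np.ndarray) -> list[float]:
    b0 = float(y.min())
    emax0 = float(max(y.max() - y.min(), 1e-12))
    half = b0 + emax0 / 2
    pos = dose > 0
    if pos.any():
        ec50_0 = float(dose[pos][np.argmin(np.abs(y[pos] - half))])
    else:
        ec50_0 = 1.0
    return [b0, emax0, max(ec50_0, 1e-9), 1.0]


def fit_hill(
    table: pd.DataFrame, group: str | None = None, per_replicate: bool = False
) -> HillFit:
    """Fit the Hill curve to one group's per-dose means.

    ``table`` is a dose-response table (long format); if ``group`` is given
    the table is filtered first. Requires >= 4 distinct doses. By default
    the fit runs on per-dose replicate means; ``per_replicate=True`` fits
    every normalized well instead. The fit is flagged when it fails to
    converge, when the response is flat (Emax CI containing 0), or when
    EC50 falls more than 10x outside the tested positive dose range.
    """
    if group is not None:
        table = table[table["group"] == group]
    if len(table) == 0:
        raise ValueError("empty dose-response table")
    if per_replicate:
        norm = normalize_density(table)
        dose = norm["dose_uM"].to_numpy(dtype=float)
        y = norm["normalized"].to_numpy(dtype=float)
    else:
        means = dose_means(table)
        dose = means["dose_uM"].to_numpy(dtype=float)
        y = means["mean_response"].to_numpy(dtype=float)
    if np.unique(dose).size < 4:
        raise ValueError(f"need >= 4 distinct doses, got {np.unique(dose).size}")
    p0 = _initial_guess(dose, y)
    flags: list[str] = []
    converged = True
    try:
        popt, pcov = optimize.curve_fit(
            hill_model, dose, y, p0=p0,
            bounds=([0.0, 0.0, 0.0, 0.0], np.inf),
            maxfev=20000,
        )
    except RuntimeError as exc:
        logger.warning("Hill fit did not converge: %s", exc)
        popt = np.asarray(p0, dtype=float)
        pcov = np.full((4, 4), np.nan)
        converged = False
        flags.append("no_convergence")
    resid = y - hill_model(dose, *popt)
    dof = max(len(y) - 4, 1)
    residual_sd = float(np.sqrt((resid ** 2).sum() / dof))
    tq = stats.t.ppf(0.975, df=dof)
    se = np.sqrt(np.diag(pcov))
    ci95 = {
        name: (float(popt[i] - tq * se[i]), float(popt[i] + tq * se[i]))
        for i, name in enumerate(PARAM_NAMES)
    }
    b, emax, ec50, hill_n = (float(v) for v in popt)
    # flat data can converge to an Emax at machine scale with a degenerate
    # CI, so "negligible vs baseline" counts as no response as well
    if converged and (
        ci95["emax"][0] <= 0 <= ci95["emax"][1]
        or emax <= 1e-6 * max(abs(b), 1.0)
    ):
        flags.append("no_response")
    pos_doses = dose[dose > 0]
    if converged and pos_doses.size and not (
        pos_doses.min() / 10 <= ec50 <= pos_doses.max() * 10
    ):
        flags.append("ec50_out_of_range")
    return HillFit(
        b=b, emax=emax, ec50=ec50, hill_n=hill_n,
        ci95=ci95, residual_sd=residual_sd, n_points=len(y),
        converged=converged, flags=flags,
    )


def ci_overlap_significant(fit_a: HillFit, fit_b: HillFit, param: str) -> str:
    """CI-overlap comparison of one Hill parameter between two fits.

    Returns "significant" when the two 95% intervals are disjoint,
    "not_significant" when they overlap, and "indeterminate" when either
    fit carries a flag.
    """
    if param not in PARAM_NAMES:
        raise KeyError(f"unknown parameter {param!r}")
    if fit_a.flags or fit_b.flags or not (fit_a.converged and fit_b.converged):
        return "indeterminate"
    lo_a, hi_a = fit_a.ci95[param]
    lo_b, hi_b = fit_b.ci95[param]
    disjoint = hi_a < lo_b or hi_b < lo_a
    return "significant" if disjoint else "not_significant"


def fit_table(fits: dict[str, HillFit]) -> pd.DataFrame:
    """Flatten named HillFits into the output CSV schema."""
    rows = []
    for g, f in fits.items():
        row = {"group": g}
        for name in PARAM_NAMES:
            row[name] = f.params[name]
            row[f"{name}_ci_lo"], row[f"{name}_ci_hi"] = f.ci95[name]
        row.update(
            residual_sd=f.residual_sd, n_points=f.n_points,
            converged=f.converged, flags=";".join(f.flags),
        )
        rows.append(row)
    return pd.DataFrame(rows)
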