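"""Group-level statistics for per-cell measurements and mating assays.

Per-cell ring intensities are expressed as percentages of a control-group
mean (optionally within strata such as time points), summarized with mean,
SEM and a percentile bootstrap CI, and compared either pairwise (Welch's
unequal-variance t test) or across four groups with a one-way ANOVA
followed by Tukey's HSD. A mutant's two Tukey comparisons against the
untreated and rapamycin-treated wild-type groups assign it a rescue
category. Mating efficiency is the dilution-corrected percentage of
mating-competent cells that formed diploids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("gpcrquant")

RESCUE_CATEGORIES = ("no_rescue", "partial_rescue", "complete_rescue", "indeterminate")


@dataclass
class RescueResult:
    strain: str
    p_vs_wt_untreated: float
    p_vs_wt_treated: float
    category: str


def normalize_percent(
    measurements: pd.DataFrame,
    control_group: str,
    value_col: str = "mean_ring_intensity",
    stratum: str | None = None,
) -> pd.DataFrame:
    """Express each per-cell value as a percentage of the control-group mean.

    percent = 100 * value / mean(control values in the same stratum). The
    control group therefore averages 100% by construction. Raises if the
    control group is missing or its mean is non-positive in any stratum.
    """
    df = measurements.copy()
    strata = [stratum] if stratum else []
    def _norm(sub: pd.DataFrame) -> pd.DataFrame:
        ctrl = sub.loc[sub["group"] == control_group, value_col]
        if ctrl.empty:
            raise ValueError(f"control group {control_group!r} empty in a stratum")
        m = ctrl.mean()
        if m <= 0:
            raise ValueError(f"control mean {m} is not positive")
        sub = sub.copy()
        sub["percent"] = 100.0 * sub[value_col] / m
        return sub
    if strata:
        parts = []
        for _, sub in df.groupby(strata[0], sort=False):
            if sub.empty:
                raise ValueError("empty stratum")
            parts.append(_norm(sub))
        return pd.concat(parts, ignore_index=True)
    return _norm(df)


def summarize_groups(
    normalized: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    percent_col: str = "percent",
) -> pd.DataFrame:
    """Per-group mean percent, SEM and 95% percentile bootstrap CI."""
    rows = []
    for i, (g, sub) in enumerate(normalized.groupby("group", sort=False)):
        vals = sub[percent_col].to_numpy(dtype=float)
        lo, hi = bootstrap_ci(vals, B=B, seed=seed + i)
        rows.append(
            {
                "group": g,
                "n": vals.size,
                "mean_percent": float(vals.mean()),
                "sem_percent": float(vals.std(ddof=1) / np.sqrt(vals.size))
                if vals.size > 1 else 0.0,
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )
    return pd.DataFrame(rows)


def welch_t(
    a: np.ndarray,
    b: np.ndarray,
    tails: int = 2,
    direction: str = "less",
) -> tuple[float, float, float]:
    """Welch's unequal-variance t test.

    Returns (t, Welch-Satterthwaite df, p). With ``tails=1`` the p-value is
    one-sided for the alternative mean(a) < mean(b) (``direction="less"``)
    or mean(a) > mean(b) (``direction="greater"``).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        # identical degenerate samples: no evidence of difference
        na = a.size
        df = 2 * na - 2
        return 0.0, float(df), 1.0
    alternative = "two-sided" if tails == 2 else ("less" if direction == "less" else "greater")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def bootstrap_ci(
    values: np.ndarray, B: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """95% percentile bootstrap CI of the sample mean (deterministic per seed)."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(B, values.size))
    boot_means = values[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return float(lo), float(hi)


def anova_tukey(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus all-pairs Tukey HSD.

    Returns (F, overall p, pairwise adjusted-p matrix as a symmetric
    DataFrame indexed by group name). The HSD uses the classic pooled
    within-group variance and the studentized-range distribution.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    for g, s in zip(names, samples):
        if s.size < 2:
            raise ValueError(f"group {g!r} has n < 2")
    F, p_overall = stats.f_oneway(*samples)
    res = stats.tukey_hsd(*samples)
    mat = pd.DataFrame(res.pvalue, index=names, columns=names)
    return float(F), float(p_overall), mat


def classify_rescue(
    tukey_p: pd.DataFrame,
    strain: str,
    alpha: float = 0.05,
    mutant_treated: str | None = None,
    wt_untreated: str = "wt_untreated",
    wt_treated: str = "wt_treated",
) -> RescueResult:
    """Assign a rescue category from the mutant-treated group's two Tukey
    comparisons against the wild-type reference groups.

    Significantly different (p < alpha) only from untreated WT -> the
    mutant still internalizes the receptor: no_rescue. Different from both
    -> partial_rescue. Only from treated WT -> complete_rescue. Different
    from neither -> indeterminate.
    """
    mutant_treated = mutant_treated or f"{strain}_treated"
    for g in (mutant_treated, wt_untreated, wt_treated):
        if g not in tukey_p.index:
            raise KeyError(f"group {g!r} missing from the Tukey matrix")
    p_u = float(tukey_p.loc[mutant_treated, wt_untreated])
    p_t = float(tukey_p.loc[mutant_treated, wt_treated])
    sig_u, sig_t = p_u < alpha, p_t < alpha
    if sig_u and not sig_t:
        category = "no_rescue"
    elif sig_u and sig_t:
        category = "partial_rescue"
    elif not sig_u and sig_t:
        category = "complete_rescue"
    else:
        category = "indeterminate"
    return RescueResult(strain=strain, p_vs_wt_untreated=p_u,
                        p_vs_wt_treated=p_t, category=category)


def mating_efficiency(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-assay mating efficiency from colony counts.

    efficiency = 100 * (diploid_colonies * dilution_diploid)
                     / (competent_colonies * dilution_competent)

    Diploids are a subset of mating-competent cells, so a diploid estimate
    exceeding the competent estimate violates the counting model.
    """
    required = {"assay_id", "treatment", "competent_colonies", "diploid_colonies",
                "dilution_competent", "dilution_diploid"}
    missing = required - set(counts.columns)
    if missing:
        raise KeyError(f"mating counts table missing columns: {sorted(missing)}")
    competent = counts["competent_colonies"] * counts["dilution_competent"]
    diploid = counts["diploid_colonies"] * counts["dilution_diploid"]
    if (competent <= 0).any():
        bad = counts.index[competent <= 0].tolist()
        raise ValueError(f"zero mating-competent estimate in rows {bad}")
    if (diploid > competent).any():
        bad = counts.index[diploid > competent].tolist()
        raise ValueError(
            f"diploid estimate exceeds competent estimate in rows {bad}"
        )
    out = counts.copy()
    out["efficiency_percent"] = 100.0 * diploid / competent
    return out


def compare_mating(
    efficiencies: pd.DataFrame,
    treated: str,
    control: str,
) -> tuple[float, float, float]:
    """One-tailed Welch test that treated cells mate less efficiently.

    Returns (t, df, one-sided p) for the alternative
    mean(treated) < mean(control).
    """
    a = efficiencies.loc[efficiencies["treatment"] == treated, "efficiency_percent"]
    b = efficiencies.loc[efficiencies["treatment"] == control, "efficiency_percent"]
    if a.empty or b.empty:
        raise KeyError(f"unknown treatment group: {treated!r} or {control!r}")
    return welch_t(a.to_numpy(), b.to_numpy(), tails=1, direction="less")
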