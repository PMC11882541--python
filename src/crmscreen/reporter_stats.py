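"""Reporter-assay normalization and group comparisons.

Per-embryo GFP fluorescence is normalized to the co-transfected RFP signal
(transfection-efficiency control). Construct variants are compared to a
control construct with one-way ANOVA followed by Dunnett's many-to-one
multiple-comparison procedure at family-wise alpha = 0.05; a pooled-variance
two-tailed Student t-test is provided for simple two-group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FluorescenceRecord",
    "DunnettComparison",
    "DunnettResult",
    "DegenerateDataError",
    "normalize",
    "normalize_table",
    "anova_dunnett",
    "dunnett_mc",
    "two_sample_t",
    "mean_above_threshold",
    "summarize_groups",
]


class DegenerateDataError(ValueError):
    """Raised when the data has no within-group variability to test against."""


@dataclass(frozen=True)
class FluorescenceRecord:
    """Mean channel intensities for one embryo; ``normalized`` = GFP/RFP."""

    embryo_id: str
    group: str
    gfp_mean: float
    rfp_mean: float
    normalized: float = None  # filled in __post_init__

    def __post_init__(self) -> None:
        if self.gfp_mean < 0:
            raise ValueError("gfp_mean must be non-negative")
        if self.rfp_mean <= 0:
            raise ValueError("rfp_mean must be positive")
        object.__setattr__(self, "normalized", self.gfp_mean / self.rfp_mean)


@dataclass(frozen=True)
class DunnettComparison:
    group: str
    mean_difference: float   # group mean - control mean
    pvalue_adjusted: float
    significant: bool


@dataclass(frozen=True)
class DunnettResult:
    control: str
    comparisons: list[DunnettComparison]
    f_statistic: float
    f_pvalue: float
    alpha: float


def normalize(records: Sequence[FluorescenceRecord]) -> list[FluorescenceRecord]:
    """Records with the normalized (GFP/RFP) field populated; construction
    already computes it, so this is a validated pass-through."""
    return list(records)


def normalize_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``normalized`` column to a table with gfp_mean/rfp_mean columns."""
    if (df["rfp_mean"] <= 0).any():
        raise ValueError("rfp_mean must be positive for all records")
    out = df.copy()
    out["normalized"] = out["gfp_mean"] / out["rfp_mean"]
    return out


def _validate_groups(
    groups: Mapping[str, Sequence[float]], control_label: str
) -> dict[str, np.ndarray]:
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrs.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has n={v.size}; need n >= 2")
    return arrs


def anova_dunnett(
    groups: Mapping[str, Sequence[float]],
    control_label: str,
    alpha: float = 0.05,
    n_mc: int = 20000,
    seed: int | None = 0,
    method: str = "auto",
) -> DunnettResult:
    """One-way ANOVA plus Dunnett-adjusted many-to-one comparisons.

    ``method='auto'`` uses the analytic multivariate-t procedure
    (scipy.stats.dunnett); ``method='mc'`` uses an in-package Monte-Carlo
    max-|t| null with ``n_mc`` resamples, kept as an independent cross-check.

    Boundary behavior: if every group is constant and all means are equal the
    result is the degenerate identity comparison (differences 0, adjusted
    p = 1); constant groups with unequal means are untestable and raise
    :class:`DegenerateDataError`.
    """
    arrs = _validate_groups(groups, control_label)
    control = arrs[control_label]
    others = {k: v for k, v in arrs.items() if k != control_label}

    pooled_var = np.concatenate([v - v.mean() for v in arrs.values()]).var()
    if pooled_var == 0:
        if all(np.isclose(v.mean(), control.mean()) for v in others.values()):
            comps = [
                DunnettComparison(k, 0.0, 1.0, False) for k in others
            ]
            return DunnettResult(control_label, comps, 0.0, 1.0, alpha)
        raise DegenerateDataError("zero within-group variance with unequal means")

    f_stat, f_p = stats.f_oneway(*arrs.values())

    names = list(others)
    if method == "mc":
        padj = dunnett_mc(
            [others[k] for k in names], control, n_mc=n_mc, seed=seed
        )
    elif method in ("auto", "mvt"):
        res = stats.dunnett(
            *[others[k] for k in names],
            control=control,
            rng=np.random.default_rng(seed),
        )
        padj = np.asarray(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")

    comps = [
        DunnettComparison(
            group=k,
            mean_difference=float(others[k].mean() - control.mean()),
            pvalue_adjusted=float(min(1.0, p)),
            significant=bool(p < alpha),
        )
        for k, p in zip(names, padj)
    ]
    return DunnettResult(control_label, comps, float(f_stat), float(f_p), alpha)


def dunnett_mc(
    treatment_groups: Sequence[np.ndarray],
    control: np.ndarray,
    n_mc: int = 20000,
    seed: int | None = 0,
) -> np.ndarray:
    """Monte-Carlo Dunnett adjustment: adjusted p_i = P(max_j |T_j| >= |t_i|)
    under a shared-normal null with the observed group sizes."""
    rng = np.random.default_rng(seed)
    control = np.asarray(control, dtype=float)
    groups = [np.asarray(g, dtype=float) for g in treatment_groups]
    ns = [g.size for g in groups]
    n0 = control.size
    df = n0 + sum(ns) - (len(groups) + 1)

    def tstats(ctrl: np.ndarray, grps: list[np.ndarray]) -> np.ndarray:
        sse = np.sum((ctrl - ctrl.mean(axis=-1, keepdims=True)) ** 2, axis=-1)
        for g in grps:
            sse = sse + np.sum((g - g.mean(axis=-1, keepdims=True)) ** 2, axis=-1)
        s2 = sse / df
        return np.stack(
            [
                (g.mean(axis=-1) - ctrl.mean(axis=-1))
                / np.sqrt(s2 * (1 / g.shape[-1] + 1 / n0))
                for g in grps
            ],
            axis=0,
        )

    t_obs = tstats(control, groups)

    null_ctrl = rng.standard_normal((n_mc, n0))
    null_grps = [rng.standard_normal((n_mc, n)) for n in ns]
    t_null = tstats(null_ctrl, null_grps)       # k x n_mc
    max_null = np.abs(t_null).max(axis=0)       # n_mc

    return np.array(
        [(np.sum(max_null >= abs(t)) + 1) / (n_mc + 1) for t in t_obs]
    )


def two_sample_t(
    a: Sequence[float], b: Sequence[float], two_tailed: bool = True
) -> tuple[float, float]:
    """Pooled-variance Student t-test; raises on zero pooled variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / (a.size + b.size - 2)
    if sp2 == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise DegenerateDataError("zero pooled variance with unequal means")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    df = a.size + b.size - 2
    p = 2 * stats.t.sf(abs(t), df) if two_tailed else stats.t.sf(t, df)
    return float(t), float(min(1.0, p))


def mean_above_threshold(image: np.ndarray, threshold: float) -> float:
    """Mean intensity of the binary-thresholded region of interest of a
    grayscale image; fixture helper for synthetic assay data."""
    img = np.asarray(image, dtype=float)
    roi = img[img >= threshold]
    if roi.size == 0:
        raise ValueError("no pixels at or above threshold")
    return float(roi.mean())


def summarize_groups(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Box-plot summary table: n, median, quartiles and range per group."""
    rows = []
    for k, v in groups.items():
        v = np.asarray(v, dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append(
            {"group": k, "n": v.size, "median": med, "q1": q1, "q3": q3,
             "min": v.min(), "max": v.max()}
        )
    return pd.DataFrame(rows)
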