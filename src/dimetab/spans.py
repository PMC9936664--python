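"""Normalization-method selection by group-bias scoring (SPANS-style).

Normalization rescales each sample by per-sample factors (a maximum, a
median, a mean and standard deviation, ...). If those factors themselves
differ systematically between the experimental groups, the normalization
removes (or injects) biology rather than technical variation. This module
scores every combination of a *peak-subset method* and a *normalization
method* by how strongly the per-sample factors computed on that subset
associate with the grouping variable.

For each grid cell the procedure

1. selects a peak subset on log10 intensities (all peaks; the top-L
   fraction by mean detected log-intensity, L ∈ {0.05, 0.10, 0.20, 0.50};
   or peaks present in at least a proportion p of samples,
   p ∈ {0.5, 0.75, 1.0});
2. computes the per-sample normalization factors from the subset
   (location, plus a scale factor where the method defines one, i.e.
   zscore's standard deviation);
3. runs a Kruskal–Wallis test of each factor vector against the group
   labels (midranks, tie-corrected statistic, chi-square p-value);
4. scores the cell as the mean log10 p over the available factors.

A score of 0 (p = 1) means no detectable group bias; large negative scores
flag methods whose factors separate the groups. This scoring is a
reimplementation of the idea, not a port of any existing procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import NORMALIZATION_METHODS
from .preprocessing import IntensityMatrix

TOP_L_FRACTIONS = (0.05, 0.10, 0.20, 0.50)
PRESENCE_PROPORTIONS = (0.5, 0.75, 1.0)

#: which named factors feed the score, per normalization method
_METHOD_FACTORS = {
    "max": ("scale",),
    "minmax": ("location",),
    "mean": ("location",),
    "median": ("location",),
    "sum": ("scale",),
    "zscore": ("location", "scale"),
}


def _log_intensities(values: pd.DataFrame) -> pd.DataFrame:
    """log10 intensities with absences (zeros) masked as NaN."""
    out = values.astype(float).where(values > 0)
    return np.log10(out)


def _factors_log(sub: pd.DataFrame, method: str) -> pd.DataFrame | None:
    """Per-sample location/scale of ``method`` on NaN-masked log intensities;
    None when degenerate for any sample (no peaks, zero scale)."""
    loc = sub.agg("mean") if method in ("mean", "zscore") else None
    if method == "max":
        location, scale = sub.min() * 0.0, sub.max()
    elif method == "minmax":
        location, scale = sub.min(), sub.max() - sub.min()
    elif method == "mean":
        location, scale = loc, sub.max() - sub.min()
    elif method == "median":
        location, scale = sub.median(), sub.max() - sub.min()
    elif method == "sum":
        location, scale = sub.min() * 0.0, sub.sum(min_count=1)
    elif method == "zscore":
        location, scale = loc, sub.std(ddof=1)
    else:  # pragma: no cover
        raise ValidationError(f"unknown normalization method {method!r}")
    fac = pd.DataFrame({"location": location, "scale": scale})
    if fac.isna().any().any():
        return None
    if method != "max" and (fac["scale"] == 0).any():
        return None
    return fac


def _subsets(logvals: pd.DataFrame) -> list[tuple[str, float | None, pd.Index]]:
    """Enumerate (subset_method, parameter, peak index) triples."""
    detected = logvals.notna()
    n_samples = logvals.shape[1]
    out: list[tuple[str, float | None, pd.Index]] = [("all", None, logvals.index)]
    # mean detected log-intensity ranks peaks for the top-L subsets
    mean_log = logvals.mean(axis=1).fillna(-np.inf)
    order = mean_log.sort_values(ascending=False).index
    for frac in TOP_L_FRACTIONS:
        n = max(1, int(round(frac * len(order))))
        out.append(("top_l", frac, order[:n]))
    presence = detected.mean(axis=1)
    for p in PRESENCE_PROPORTIONS:
        idx = logvals.index[presence >= p]
        out.append(("presence", p, idx))
    return out


def spans_grid(
    matrix: IntensityMatrix,
    metadata: pd.DataFrame,
    grouping: str,
    methods: tuple[str, ...] = NORMALIZATION_METHODS,
) -> pd.DataFrame:
    """Score every (subset method × normalization method) combination.

    Returns a long-format DataFrame with columns ``subset_method,
    parameter, normalization_method, n_subset_peaks, score`` (score is NaN
    for empty or degenerate subsets). Higher scores mean less evidence of
    group bias.
    """
    if matrix.normalization != "raw":
        raise ValidationError("spans_grid expects the raw intensity matrix")
    groups = metadata.loc[matrix.sample_ids, grouping]
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValidationError("need >= 2 groups for bias scoring")
    small = counts[counts < 2]
    if not small.empty:
        raise ValidationError(
            f"every group needs >= 2 samples; too small: {list(small.index)}"
        )

    logvals = _log_intensities(matrix.values)
    labels = groups.to_numpy()
    rows = []
    for subset_method, param, idx in _subsets(logvals):
        sub = logvals.loc[idx]
        for method in methods:
            score = np.nan
            if len(idx) > 0:
                fac = _factors_log(sub, method)
                if fac is not None:
                    logps = []
                    for fname in _METHOD_FACTORS[method]:
                        vec = fac[fname].to_numpy()
                        logps.append(np.log10(_kw_pvalue(vec, labels)))
                    score = float(np.mean(logps))
            rows.append(
                {
                    "subset_method": subset_method,
                    "parameter": param,
                    "normalization_method": method,
                    "n_subset_peaks": len(idx),
                    "score": score,
                }
            )
    return pd.DataFrame(rows)


def _kw_pvalue(factor: np.ndarray, labels: np.ndarray) -> float:
    """Kruskal-Wallis p of a factor vector vs. group labels; a factor that
    is identical across samples carries no bias evidence (p = 1)."""
    by_group = [factor[labels == g] for g in np.unique(labels)]
    if np.ptp(factor) == 0:
        return 1.0
    stat, p = stats.kruskal(*by_group)
    return float(p)


def recommend_method(grid: pd.DataFrame) -> str:
    """The normalization method of the maximal-score cell; ties broken by
    the canonical method order (max, minmax, mean, median, sum, zscore)."""
    defined = grid.dropna(subset=["score"])
    if defined.empty:
        raise ValidationError("all SPANS scores are missing; cannot recommend a method")
    best = defined["score"].max()
    candidates = set(defined.loc[defined["score"] == best, "normalization_method"])
    for method in NORMALIZATION_METHODS:
        if method in candidates:
            return method
    raise AssertionError("unreachable")
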