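"""Data diagnostics and exploration: per-sample counts, composition
summaries, pairwise shared/unique peak sets and per-index group tests.

All operations work on the *annotated, filtered* peak table (see
:mod:`dimetab.preprocessing`). A peak counts as present in a sample when
its intensity there is > 0, and as present in a *group* when it is detected
in at least one sample of the group (configurable to "all samples").
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import sample_columns_of
from .preprocessing import has_formula

INDEX_NAMES = ("nosc", "gfe", "ai_mod", "dbe")


def diagnostics_counts(peaks: pd.DataFrame) -> pd.DataFrame:
    """Per-sample detected-peak and assigned-formula counts.

    Returns one row per sample with ``n_peaks`` (detected, intensity > 0)
    and ``n_with_formula`` (detected peaks carrying a molecular formula);
    ``n_with_formula <= n_peaks`` always. The sample with the fewest
    assigned formulas is flagged (``is_min_formulas``) as a potential
    outlier.
    """
    samples = sample_columns_of(peaks)
    detected = peaks[samples] > 0
    hf = has_formula(peaks)
    table = pd.DataFrame(
        {
            "n_peaks": detected.sum(axis=0),
            "n_with_formula": detected[hf].sum(axis=0) if hf.any() else 0,
        }
    )
    table.index.name = "sample_id"
    table["is_min_formulas"] = table["n_with_formula"] == table["n_with_formula"].min()
    return table


def error_distribution(peaks: pd.DataFrame) -> pd.DataFrame:
    """Long table (sample, mass, error_ppm) of assigned-formula errors for
    detected peaks — the data behind per-sample error scatterplots."""
    samples = sample_columns_of(peaks)
    hf = has_formula(peaks) & peaks["error_ppm"].notna()
    rows = []
    for s in samples:
        det = peaks.loc[hf & (peaks[s] > 0)]
        rows.append(
            pd.DataFrame(
                {"sample_id": s, "mass": det["mass"], "error_ppm": det["error_ppm"]}
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["sample_id", "mass", "error_ppm"]
    )


def _group_samples(metadata: pd.DataFrame, grouping: str) -> dict[str, list[str]]:
    return {
        g: list(idx) for g, idx in metadata.groupby(grouping, sort=True).groups.items()
    }


def _group_presence(
    peaks: pd.DataFrame, metadata: pd.DataFrame, grouping: str, mode: str = "any"
) -> pd.DataFrame:
    """Boolean peaks × groups membership matrix; ``mode`` is ``"any"``
    (detected in >= 1 sample of the group) or ``"all"``."""
    out = {}
    for g, samples in _group_samples(metadata, grouping).items():
        det = peaks[samples] > 0
        out[g] = det.any(axis=1) if mode == "any" else det.all(axis=1)
    return pd.DataFrame(out)


def composition_summary(
    peaks: pd.DataFrame, metadata: pd.DataFrame, grouping: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group percentage of formula-bearing detected peaks per compound
    class and per element class. Each group's percentages sum to 100."""
    hf = has_formula(peaks)
    presence = _group_presence(peaks, metadata, grouping)
    tables = []
    for kind in ("compound_class", "element_class"):
        rows = {}
        for g in presence.columns:
            members = peaks.loc[presence[g] & hf, kind]
            counts = members.value_counts()
            rows[g] = 100.0 * counts / counts.sum() if counts.sum() else counts
        tab = pd.DataFrame(rows).fillna(0.0)
        tab.index.name = kind
        tables.append(tab.sort_index())
    return tables[0], tables[1]


@dataclass
class GroupComparison:
    """Shared/unique peak sets for one unordered pair of groups."""

    group_a: str
    group_b: str
    shared: set = field(default_factory=set)
    unique_a: set = field(default_factory=set)
    unique_b: set = field(default_factory=set)
    class_breakdown: pd.DataFrame | None = None


def pairwise_compare(
    peaks: pd.DataFrame, metadata: pd.DataFrame, grouping: str, mode: str = "any"
) -> tuple[list[GroupComparison], pd.DataFrame]:
    """Shared and unique peaks for every unordered group pair, plus the
    full peaks × groups presence/absence matrix (for UpSet-style plots)."""
    presence = _group_presence(peaks, metadata, grouping, mode=mode)
    groups = list(presence.columns)
    if len(groups) < 2:
        warnings.warn("only one group; no pairwise comparisons", stacklevel=2)
        return [], presence
    comparisons = []
    for a, b in itertools.combinations(groups, 2):
        in_a, in_b = presence[a], presence[b]
        comp = GroupComparison(
            group_a=a,
            group_b=b,
            shared=set(peaks.index[in_a & in_b]),
            unique_a=set(peaks.index[in_a & ~in_b]),
            unique_b=set(peaks.index[in_b & ~in_a]),
        )
        breakdown = {}
        for label, ids in (("shared", comp.shared), (a, comp.unique_a), (b, comp.unique_b)):
            breakdown[label] = peaks.loc[sorted(ids), "compound_class"].value_counts()
        comp.class_breakdown = pd.DataFrame(breakdown).fillna(0).astype(int)
        comparisons.append(comp)
    return comparisons, presence


def index_group_tests(
    peaks: pd.DataFrame,
    metadata: pd.DataFrame,
    grouping: str,
    indices: tuple[str, ...] = INDEX_NAMES,
) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD per thermodynamic/molecular index.

    The observation unit is a (peak, sample) occurrence: each detected,
    formula-bearing peak contributes its index value once per sample it is
    detected in, unweighted by intensity. Tukey's studentized-range
    adjustment controls the family-wise error within each index.

    Returns a long table: index, group_a, group_b, mean_diff, p_adj,
    anova_F, anova_p. Indices where some group has < 2 observations are
    skipped with a warning.
    """
    samples = sample_columns_of(peaks)
    hf = has_formula(peaks)
    sample_group = metadata[grouping]
    rows = []
    for index_name in indices:
        vals, labels = [], []
        for s in samples:
            det = peaks.loc[hf & (peaks[s] > 0), index_name].dropna()
            vals.append(det.to_numpy())
            labels.append(np.repeat(sample_group.loc[s], len(det)))
        values = np.concatenate(vals)
        groups = np.concatenate(labels)
        counts = pd.Series(groups).value_counts()
        if len(counts) < 2 or (counts < 2).any():
            warnings.warn(
                f"index {index_name!r}: fewer than 2 groups with >= 2 "
                f"observations; skipped",
                stacklevel=2,
            )
            continue
        by_group = [values[groups == g] for g in counts.index]
        F, p = stats.f_oneway(*by_group)
        tukey = pairwise_tukeyhsd(values, groups)
        res = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        for _, r in res.iterrows():
            rows.append(
                {
                    "index": index_name,
                    "group_a": r["group1"],
                    "group_b": r["group2"],
                    "mean_diff": float(r["meandiff"]),
                    "p_adj": float(r["p-adj"]),
                    "anova_F": float(F),
                    "anova_p": float(p),
                }
            )
    return pd.DataFrame(rows)


def van_krevelen_data(
    peaks: pd.DataFrame, metadata: pd.DataFrame, grouping: str
) -> pd.DataFrame:
    """Long table (group, peak_id, O/C, H/C, compound class) behind van
    Krevelen scatter plots."""
    presence = _group_presence(peaks, metadata, grouping)
    hf = has_formula(peaks)
    rows = []
    for g in presence.columns:
        sub = peaks.loc[presence[g] & hf]
        rows.append(
            pd.DataFrame(
                {
                    "group": g,
                    "peak_id": sub.index,
                    "ratio_OC": sub["ratio_OC"].to_numpy(),
                    "ratio_HC": sub["ratio_HC"].to_numpy(),
                    "compound_class": sub["compound_class"].to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
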