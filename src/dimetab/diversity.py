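"""Per-sample chemodiversity: abundance-based indices (richness, Shannon,
Gini-Simpson, Chao1) and trait-based Rao quadratic entropy.

Diversity is always computed from the **raw** intensity matrix: raw
intensities are sum-normalized within each sample into relative abundances
p_i, regardless of which normalization the rest of the pipeline uses.

Chao1 is a count-based estimator; intensity data carries no counts, so raw
intensities are converted to pseudo-counts by dividing by the smallest
positive intensity in the sample and rounding. "Singletons" (F1) and
"doubletons" (F2) are peaks with pseudo-count 1 and 2, and
``chao1 = S_obs + F1 (F1 − 1) / (2 (F2 + 1))`` (bias-corrected form).
This adaptation is documented in docs/methods.md.

Rao's quadratic entropy ``Q = Σ_i Σ_j d_ij p_i p_j`` measures the expected
trait distance between two random draws from the sample; ``d_ij`` is the
Gower distance (equal trait weights, per-trait range scaling to [0, 1]).
Three trait sets mirror common usage for molecular data: elemental
composition (C,H,O,N,S,P counts), unsaturation/aromaticity (DBE, AImod)
and reactivity (GFE).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocessing import IntensityMatrix, has_formula

TRAIT_SETS: dict[str, tuple[str, ...]] = {
    "elemental_composition": ("C", "H", "O", "N", "S", "P"),
    "insaturation_aromaticity": ("dbe", "ai_mod"),
    "reactivity": ("gfe",),
}


def relative_abundance(matrix: IntensityMatrix, sample: str) -> pd.Series:
    """Sum-normalized abundances p_i over the sample's detected peaks."""
    if matrix.normalization != "raw":
        raise ValidationError("diversity metrics are computed from the raw matrix")
    col = matrix.values[sample]
    detected = col[col > 0]
    if detected.empty:
        raise ValidationError(f"sample {sample!r} has no detected peaks")
    return detected / detected.sum()


def abundance_diversity(matrix: IntensityMatrix, sample: str) -> dict[str, float]:
    """Richness, Shannon (nats), Gini-Simpson and Chao1 for one sample."""
    p = relative_abundance(matrix, sample)
    richness = len(p)
    shannon = float(-(p * np.log(p)).sum())
    gini_simpson = float(1.0 - (p**2).sum())

    raw = matrix.values[sample]
    detected = raw[raw > 0]
    pseudo = np.round(detected / detected.min()).astype(int)
    f1 = int((pseudo == 1).sum())
    f2 = int((pseudo == 2).sum())
    chao1 = richness + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return {
        "richness": richness,
        "shannon": shannon,
        "gini_simpson": gini_simpson,
        "chao1": float(chao1),
    }


def rank_abundance(matrix: IntensityMatrix, sample: str) -> pd.Series:
    """Relative abundances sorted descending (rank-abundance curve data)."""
    return relative_abundance(matrix, sample).sort_values(ascending=False, kind="stable")


def gower_distance(traits: pd.DataFrame) -> np.ndarray:
    """Pairwise Gower distance matrix on numeric trait columns.

    Each trait is range-scaled so its contribution lies in [0, 1]; traits
    with zero range are uninformative and are excluded from the average
    (as in the usual Gower formulation). The result lies in [0, 1].
    """
    X = traits.to_numpy(float)
    n, _ = X.shape
    D = np.zeros((n, n))
    k_inf = 0
    for j in range(X.shape[1]):
        rng = np.ptp(X[:, j])
        if rng == 0:
            continue
        D += np.abs(X[:, j][:, None] - X[:, j][None, :]) / rng
        k_inf += 1
    return D / k_inf if k_inf else D


def rao_entropy(p: pd.Series, traits: pd.DataFrame, trait_set: str) -> float:
    """Rao's quadratic entropy for one sample and one trait set.

    ``p`` is the sample's relative-abundance vector; ``traits`` the
    annotated peak table. Abundances are restricted to formula-bearing
    peaks with defined traits and renormalized before the double sum.
    """
    if trait_set not in TRAIT_SETS:
        raise ValidationError(f"unknown trait set {trait_set!r}; choose {list(TRAIT_SETS)}")
    cols = list(TRAIT_SETS[trait_set])
    sub = traits.loc[traits.index.intersection(p.index)]
    sub = sub[has_formula(sub)]
    tr = sub[cols].dropna()
    if len(tr) < 2:
        warnings.warn(
            f"fewer than 2 peaks with defined {trait_set!r} traits; Q = 0",
            stacklevel=2,
        )
        return 0.0
    q = p.loc[tr.index]
    q = (q / q.sum()).to_numpy()
    D = gower_distance(tr)
    return float(q @ D @ q)


def diversity_table(
    matrix: IntensityMatrix, annotated_peaks: pd.DataFrame
) -> pd.DataFrame:
    """Long table (sample, metric, trait_set, value) over all samples:
    abundance metrics plus Rao's Q for every trait set."""
    rows = []
    for s in matrix.sample_ids:
        metrics = abundance_diversity(matrix, s)
        for name, value in metrics.items():
            rows.append({"sample_id": s, "metric": name, "trait_set": "", "value": value})
        p = relative_abundance(matrix, s)
        for trait_set in TRAIT_SETS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                q = rao_entropy(p, annotated_peaks, trait_set)
            rows.append(
                {"sample_id": s, "metric": "rao_q", "trait_set": trait_set, "value": q}
            )
    return pd.DataFrame(rows)
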