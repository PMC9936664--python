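"""Ab initio mass-difference (transformation) networks.

FT-ICR MS mass accuracy is high enough that the *difference* between two
peak masses can be matched against the exact monoisotopic mass of a known
biochemical transformation (±CH2 methylation, ±H2O condensation, ...). For
each sample, every unordered pair of detected peaks whose mass difference
lies within a ppm tolerance of a key entry becomes a putative
transformation edge; the per-sample graphs and their statistics summarize
the chemical connectivity of the sample.

The tolerance is interpreted relative to the *key's* mass difference
(``|Δm − key| ≤ key · ppm · 1e-6``) by default; an alternative mode
relates it to the heavier peak's mass (``ppm_reference="peak"``), since
1 ppm of a small Δm is far stricter than 1 ppm of the measured masses.
A pair matching several key entries yields parallel edges by default
(``multi_match="all"``); ``multi_match="best"`` keeps only the
minimum-error match.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import sample_columns_of
from .preprocessing import has_formula

EDGE_COLUMNS = [
    "sample_id", "peak_lo", "peak_hi", "mass_lo", "mass_hi",
    "key_name", "category", "observed_delta", "error_ppm",
]


def match_transformations(
    masses: pd.Series,
    key: pd.DataFrame,
    ppm_tolerance: float = 1.0,
    sample_id: str = "",
    ppm_reference: str = "key",
    multi_match: str = "all",
) -> pd.DataFrame:
    """Match all pairwise mass differences of one sample against the key.

    ``masses`` maps peak_id -> mass for the peaks detected in the sample.
    Exactly equivalent to the O(n²·K) brute force, but implemented as a
    per-key windowed sweep over the sorted mass list.

    Returns an edge table with one row per (pair, key) match: peak ids and
    masses (lo < hi), key name/category, observed Δm and the relative
    error in ppm.
    """
    if ppm_tolerance <= 0:
        raise ValidationError("ppm_tolerance must be > 0")
    if (masses <= 0).any():
        raise ValidationError("masses must be strictly positive")
    order = np.argsort(masses.to_numpy(), kind="stable")
    m = masses.to_numpy()[order]
    ids = masses.index.to_numpy()[order]
    rows = []
    for _, entry in key.iterrows():
        delta = float(entry["mass_difference"])
        if ppm_reference == "key":
            tol = delta * ppm_tolerance * 1e-6
            lo_t = np.searchsorted(m, m + delta - tol, side="left")
            hi_t = np.searchsorted(m, m + delta + tol, side="right")
        elif ppm_reference == "peak":
            # tolerance scales with the heavier peak: m_hi in
            # [ (m_lo + delta) / (1 + eps), (m_lo + delta) / (1 - eps) ]
            eps = ppm_tolerance * 1e-6
            lo_t = np.searchsorted(m, (m + delta) / (1.0 + eps), side="left")
            hi_t = np.searchsorted(m, (m + delta) / (1.0 - eps), side="right")
        else:
            raise ValidationError("ppm_reference must be 'key' or 'peak'")
        for i in range(len(m)):
            for j in range(lo_t[i], hi_t[i]):
                if j == i:
                    continue
                obs = m[j] - m[i]
                if obs <= 0:
                    continue
                ref = delta if ppm_reference == "key" else m[j]
                err = abs(obs - delta) / ref * 1e6
                if err <= ppm_tolerance:
                    rows.append(
                        (sample_id, ids[i], ids[j], m[i], m[j],
                         entry["name"], entry["category"], obs, err)
                    )
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    if multi_match == "best" and not edges.empty:
        edges = (
            edges.sort_values(["error_ppm", "key_name"], kind="stable")
            .drop_duplicates(subset=["peak_lo", "peak_hi"], keep="first")
        )
    return edges.sort_values(
        ["mass_lo", "mass_hi", "key_name"], kind="stable", ignore_index=True
    )


def sample_edges(
    peaks: pd.DataFrame,
    key: pd.DataFrame,
    ppm_tolerance: float = 1.0,
    require_formula: bool = True,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Edge tables for every sample of a peak table.

    Peaks without a molecular formula are excluded by default (their class
    annotation is undefined); set ``require_formula=False`` to keep them.
    """
    samples = sample_columns_of(peaks)
    eligible = peaks if not require_formula else peaks[has_formula(peaks)]
    out = {}
    for s in samples:
        det = eligible.loc[eligible[s] > 0, "mass"]
        if len(det) < 2:
            out[s] = pd.DataFrame(columns=EDGE_COLUMNS)
            continue
        out[s] = match_transformations(
            det, key, ppm_tolerance=ppm_tolerance, sample_id=s, **kwargs
        )
    return out


@dataclass
class NetworkStats:
    sample_id: str
    n_nodes: int
    n_edges: int
    density: float
    mean_degree: float
    n_components: int
    n_isolated_detected: int
    per_key_counts: dict
    per_category_counts: dict


def build_network(
    edges: pd.DataFrame,
    annotated_peaks: pd.DataFrame,
    sample_id: str = "",
    n_detected: int | None = None,
) -> tuple[nx.MultiGraph, NetworkStats]:
    """Build one sample's transformation graph and its statistics.

    Nodes are peaks participating in >= 1 edge, annotated with mass,
    compound class and indices; parallel edges (one pair, several keys)
    are kept as a multigraph. ``n_detected`` (total detected peaks in the
    sample) lets the stats report how many detected peaks remained
    isolated and therefore outside the graph.
    """
    G = nx.MultiGraph(sample_id=sample_id)
    for _, e in edges.iterrows():
        G.add_edge(
            str(e["peak_lo"]), str(e["peak_hi"]),
            key_name=str(e["key_name"]), category=str(e["category"]),
            observed_delta=float(e["observed_delta"]), error_ppm=float(e["error_ppm"]),
        )
    for node in G.nodes:
        if node in annotated_peaks.index:
            row = annotated_peaks.loc[node]
            G.nodes[node].update(
                mass=float(row["mass"]),
                compound_class=str(row.get("compound_class", "")),
                nosc=float(row.get("nosc", np.nan)),
                gfe=float(row.get("gfe", np.nan)),
                dbe=float(row.get("dbe", np.nan)),
                ai_mod=float(row.get("ai_mod", np.nan)),
            )
    n, e_count = G.number_of_nodes(), G.number_of_edges()
    density = 2.0 * e_count / (n * (n - 1)) if n >= 2 else 0.0
    stats = NetworkStats(
        sample_id=sample_id,
        n_nodes=n,
        n_edges=e_count,
        density=density,
        mean_degree=(2.0 * e_count / n) if n else 0.0,
        n_components=nx.number_connected_components(G),
        n_isolated_detected=(n_detected - n) if n_detected is not None else 0,
        per_key_counts=edges["key_name"].value_counts().to_dict() if len(edges) else {},
        per_category_counts=edges["category"].value_counts().to_dict() if len(edges) else {},
    )
    return G, stats


def network_stats_table(stats: list[NetworkStats]) -> pd.DataFrame:
    rows = []
    for st in stats:
        rows.append(
            {
                "sample_id": st.sample_id,
                "n_nodes": st.n_nodes,
                "n_edges": st.n_edges,
                "density": st.density,
                "mean_degree": st.mean_degree,
                "n_components": st.n_components,
                "n_isolated_detected": st.n_isolated_detected,
            }
        )
    return pd.DataFrame(rows)


def transformation_summary(
    edges_by_sample: dict[str, pd.DataFrame], top_n: int = 15
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-sample transformation percentages and biotic/abiotic split.

    Returns (per-key percentage table [samples × keys], per-category
    percentage table, global top-``top_n`` keys by summed edge count).
    Samples with zero edges get all-zero rows.
    """
    if not any(len(e) for e in edges_by_sample.values()):
        raise ValidationError("no sample has any transformation edge")
    key_pct, cat_pct = {}, {}
    totals: pd.Series | None = None
    for s, edges in edges_by_sample.items():
        if len(edges) == 0:
            key_pct[s] = pd.Series(dtype=float)
            cat_pct[s] = pd.Series(dtype=float)
            continue
        counts = edges["key_name"].value_counts()
        key_pct[s] = 100.0 * counts / counts.sum()
        cats = edges["category"].value_counts()
        cat_pct[s] = 100.0 * cats / cats.sum()
        totals = counts if totals is None else totals.add(counts, fill_value=0)
    per_key = pd.DataFrame(key_pct).fillna(0.0).T.sort_index(axis=1)
    per_key.index.name = "sample_id"
    per_cat = pd.DataFrame(cat_pct).fillna(0.0).T.sort_index(axis=1)
    per_cat.index.name = "sample_id"
    top = list(totals.sort_values(ascending=False, kind="stable").index[:top_n])
    return per_key, per_cat, top
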