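"""Single-command orchestration of the six analysis steps.

Outputs are written into one subdirectory per step (``1_preprocessing`` ...
``6_networks``); a ``manifest.json`` records the configuration, package
version, seed, per-step status, produced files and timings. Every table is
CSV; graphs are additionally exported as GraphML. All randomness
(permutations, NMDS restarts) derives from ``config.rng_seed``, so two runs
with the same inputs and seed produce identical CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import time
import traceback
import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from . import diversity as dv
from . import exploration as ex
from . import multivariate as mv
from . import networks as nw
from .errors import ValidationError
from .io import RunConfig, read_metadata, read_report, read_transformation_key
from .preprocessing import IntensityMatrix, annotate_peaks, filter_peaks, normalize
from .spans import recommend_method, spans_grid

ALL_STEPS = ("preprocess", "diagnostics", "explore", "diversity", "stats", "networks")
DEFAULT_STEPS = ALL_STEPS[:-1]  # network construction is opt-in (slowest step)


def run_pipeline(
    report_path: str | Path,
    metadata_path: str | Path,
    config: RunConfig,
    outdir: str | Path,
    steps: tuple[str, ...] = DEFAULT_STEPS,
) -> dict:
    """Run the requested steps and return the manifest (also written to
    ``outdir/manifest.json``). ``preprocess`` always runs first; any step
    failure is recorded and its dependents are skipped."""
    unknown = set(steps) - set(ALL_STEPS)
    if unknown:
        raise ValidationError(f"unknown steps {sorted(unknown)}; choose from {ALL_STEPS}")
    steps = tuple(s for s in ALL_STEPS if s in set(steps) | {"preprocess"})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "seed": config.rng_seed,
        "config": dataclasses.asdict(config),
        "steps": {},
        "ok": True,
    }
    state: dict = {}

    runners = {
        "preprocess": _step_preprocess,
        "diagnostics": _step_diagnostics,
        "explore": _step_explore,
        "diversity": _step_diversity,
        "stats": _step_stats,
        "networks": _step_networks,
    }
    preprocess_failed = False
    for step in steps:
        entry = {"status": "skipped", "outputs": [], "seconds": 0.0}
        manifest["steps"][step] = entry
        if preprocess_failed and step != "preprocess":
            manifest["ok"] = False
            continue
        t0 = time.perf_counter()
        try:
            outputs = runners[step](report_path, metadata_path, config, outdir, state)
            entry["status"] = "ok"
            entry["outputs"] = [str(p.relative_to(outdir)) for p in outputs]
        except Exception:
            entry["status"] = "failed"
            entry["error"] = traceback.format_exc(limit=5)
            manifest["ok"] = False
            if step == "preprocess":
                preprocess_failed = True
        entry["seconds"] = round(time.perf_counter() - t0, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _write(df: pd.DataFrame, path: Path, **kwargs) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, **kwargs)
    return path


def _step_preprocess(report_path, metadata_path, config, outdir, state):
    report = read_report(report_path)
    meta = read_metadata(
        metadata_path, config.grouping,
        report_samples=report.attrs["sample_columns"],
    )
    # restrict intensity columns to the metadata's samples, in metadata order
    keep = [c for c in report.columns if c not in meta.index] + list(meta.index)
    report = report[[c for c in keep if c in report.columns]]
    report.attrs["sample_columns"] = list(meta.index)

    kept, audit = filter_peaks(report, config)
    annotated = annotate_peaks(kept)
    raw = IntensityMatrix.from_peaks(annotated)
    normalized = normalize(raw, config.normalization_method)

    state.update(meta=meta, annotated=annotated, raw=raw, normalized=normalized)
    d = outdir / "1_preprocessing"
    return [
        _write(annotated, d / "filtered_peaks.csv"),
        _write(raw.values, d / "raw_intensities.csv"),
        _write(normalized.values, d / "normalized_intensities.csv"),
        _write(audit.to_frame(), d / "filter_audit.csv"),
    ]


def _step_diagnostics(report_path, metadata_path, config, outdir, state):
    d = outdir / "2_diagnostics"
    counts = ex.diagnostics_counts(state["annotated"])
    errors = ex.error_distribution(state["annotated"])
    return [
        _write(counts, d / "peak_counts.csv"),
        _write(errors, d / "error_distribution.csv", index=False),
    ]


def _step_explore(report_path, metadata_path, config, outdir, state):
    d = outdir / "3_exploration"
    meta, annotated = state["meta"], state["annotated"]
    g1 = config.grouping[0]
    classes, elements = ex.composition_summary(annotated, meta, g1)
    comparisons, presence = ex.pairwise_compare(annotated, meta, g1)
    comp_rows = []
    for c in comparisons:
        comp_rows.append(
            {
                "group_a": c.group_a, "group_b": c.group_b,
                "n_shared": len(c.shared),
                "n_unique_a": len(c.unique_a), "n_unique_b": len(c.unique_b),
            }
        )
    tukey = ex.index_group_tests(annotated, meta, g1)
    vk = ex.van_krevelen_data(annotated, meta, g1)
    return [
        _write(classes, d / "composition_classes.csv"),
        _write(elements, d / "composition_elements.csv"),
        _write(presence, d / "group_presence.csv"),
        _write(pd.DataFrame(comp_rows), d / "pairwise_comparisons.csv", index=False),
        _write(tukey, d / "tukey_tests.csv", index=False),
        _write(vk, d / "van_krevelen.csv", index=False),
    ]


def _step_diversity(report_path, metadata_path, config, outdir, state):
    d = outdir / "4_chemodiversity"
    table = dv.diversity_table(state["raw"], state["annotated"])
    ranks = []
    for s in state["raw"].sample_ids:
        ra = dv.rank_abundance(state["raw"], s)
        ranks.append(
            pd.DataFrame(
                {"sample_id": s, "rank": range(1, len(ra) + 1),
                 "peak_id": ra.index, "relative_abundance": ra.to_numpy()}
            )
        )
    return [
        _write(table, d / "diversity_indices.csv", index=False),
        _write(pd.concat(ranks, ignore_index=True), d / "rank_abundance.csv", index=False),
    ]


def _step_stats(report_path, metadata_path, config, outdir, state):
    d = outdir / "5_statistics"
    meta, annotated = state["meta"], state["annotated"]
    dist = mv.compute_distance(state["normalized"])
    perm = mv.permanova(dist, meta, list(config.grouping), n_perm=999, seed=config.rng_seed)
    ord_ = mv.nmds(dist, seed=config.rng_seed)
    pca_comp, pca_idx = mv.pca_summaries(annotated, state["raw"])
    out = [
        _write(perm, d / "permanova.csv", index=False),
        _write(ord_.scores.assign(stress=ord_.stress), d / "nmds_scores.csv"),
    ]
    for res, tag in ((pca_comp, "composition"), (pca_idx, "indices")):
        out.append(_write(res.scores, d / f"pca_{tag}_scores.csv"))
        out.append(_write(res.loadings, d / f"pca_{tag}_loadings.csv"))
        out.append(
            _write(
                pd.DataFrame(
                    {"component": res.scores.columns,
                     "explained_variance": res.explained_variance}
                ),
                d / f"pca_{tag}_variance.csv", index=False,
            )
        )
    return out


def _step_networks(report_path, metadata_path, config, outdir, state):
    d = outdir / "6_networks"
    annotated = state["annotated"]
    key = read_transformation_key(config.transformation_key_path)
    edges_by_sample = nw.sample_edges(annotated, key, ppm_tolerance=config.ppm_tolerance)
    out = []
    stats = []
    gdir = d / "graphml"
    for s, edges in edges_by_sample.items():
        out.append(_write(edges, d / f"edges_{s}.csv", index=False))
        n_detected = int((annotated[s] > 0).sum())
        G, st = nw.build_network(edges, annotated, sample_id=s, n_detected=n_detected)
        stats.append(st)
        gdir.mkdir(parents=True, exist_ok=True)
        gpath = gdir / f"network_{s}.graphml"
        nx.write_graphml(G, gpath)
        out.append(gpath)
    out.append(_write(nw.network_stats_table(stats), d / "network_stats.csv", index=False))
    if any(len(e) for e in edges_by_sample.values()):
        per_key, per_cat, top = nw.transformation_summary(edges_by_sample)
        out.append(_write(per_key, d / "transformations_per_sample.csv"))
        out.append(_write(per_cat, d / "transformation_categories.csv"))
        out.append(
            _write(pd.DataFrame({"rank": range(1, len(top) + 1), "key_name": top}),
                   d / "top_transformations.csv", index=False)
        )
    else:
        warnings.warn("no transformation edges found in any sample", stacklevel=2)
    return out


def run_test_normalization(
    report_path: str | Path,
    metadata_path: str | Path,
    config: RunConfig,
    outdir: str | Path,
) -> tuple[pd.DataFrame, str]:
    """SPANS-style normalization selection: writes ``spans_scores.csv`` and
    returns (grid, recommended method)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = read_report(report_path)
    meta = read_metadata(
        metadata_path, config.grouping, report_samples=report.attrs["sample_columns"]
    )
    kept, _ = filter_peaks(report, config)
    matrix = IntensityMatrix.from_peaks(kept)
    matrix.values = matrix.values[list(meta.index)]
    grid = spans_grid(matrix, meta, config.grouping[0])
    grid.to_csv(outdir / "spans_scores.csv", index=False)
    method = recommend_method(grid)
    return grid, method
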