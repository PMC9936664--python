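"""Synthetic Formularity-style reports with known ground truth.

The generator emulates a direct-injection FT-ICR MS study: a set of CHONSP
molecular formulas with masses computed exactly from IUPAC monoisotopic
atomic masses, log-normal peak intensities with optional per-group
log10-fold-changes on a subset of peaks, per-sample dropout, a fraction of
unassigned (formula-less) peaks and of 13C isotopologue rows, and planted
homologous series (e.g. CH2 ladders) that guarantee known transformation
edges. Everything is driven by one seed; regenerating with the same spec
is byte-identical.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._elements import ELEMENTS, formula_mass
from .errors import ValidationError
from .io import _BUILTIN_KEY

_KEY_COMPOSITIONS = {name.split(" ")[0]: comp for name, comp, _ in _BUILTIN_KEY}


@dataclasses.dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults describe a small two-group study: 12 samples in two equal
    groups, 800 peaks, moderate biological noise (log10 sd 0.3), 10%
    dropout, a 0.3 log10-fold-change on 30% of peaks for group "B", 5%
    unassigned rows and 5% 13C isotopologues, no mass jitter (formula
    masses are exact, as needed for sub-ppm mass-difference matching).
    """

    n_samples: int = 12
    n_peaks: int = 800
    groups: Sequence[str] | None = None        # one label per sample
    groups2: Sequence[str] | None = None       # optional second variable
    c_range: tuple[int, int] = (4, 40)
    hc_range: tuple[float, float] = (0.5, 2.2)
    oc_range: tuple[float, float] = (0.0, 1.1)
    planted_series: Sequence[tuple[dict, str, int]] = ()   # (base, key name, n steps)
    group_effect: dict[str, float] | None = None  # group -> log10 fold change
    affected_fraction: float = 0.3
    base_log10_intensity: float = 6.0
    peak_sd: float = 0.5
    noise_sd: float = 0.3
    dropout_rate: float = 0.1
    frac_no_formula: float = 0.05
    frac_c13: float = 0.05
    error_sd_ppm: float = 0.15
    mass_jitter_ppm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.dropout_rate, self.frac_no_formula, self.frac_c13,
                     self.affected_fraction):
            if not 0 <= rate <= 1:
                raise ValidationError(f"rates must lie in [0, 1], got {rate}")
        if self.groups is not None and len(self.groups) != self.n_samples:
            raise ValidationError("groups must assign one label per sample")


def _sample_formulas(spec: FixtureSpec, rng: np.random.Generator, n: int) -> pd.DataFrame:
    C = rng.integers(spec.c_range[0], spec.c_range[1] + 1, n)
    H = np.maximum(1, np.round(C * rng.uniform(*spec.hc_range, n))).astype(int)
    O = np.round(C * rng.uniform(*spec.oc_range, n)).astype(int)
    N = rng.choice([0, 1, 2], n, p=[0.6, 0.3, 0.1])
    S = rng.choice([0, 1], n, p=[0.9, 0.1])
    P = rng.choice([0, 1], n, p=[0.95, 0.05])
    return pd.DataFrame({"C": C, "H": H, "O": O, "N": N, "S": S, "P": P})


def _series_peaks(spec: FixtureSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Formulas of the planted homologous series plus the edge truth table."""
    rows, truth = [], []
    for s_idx, (base, key_name, steps) in enumerate(spec.planted_series):
        comp_key = _KEY_COMPOSITIONS.get(key_name)
        if comp_key is None:
            raise ValidationError(f"unknown transformation {key_name!r} for planted series")
        for k in range(steps + 1):
            comp = {el: base.get(el, 0) + k * comp_key.get(el, 0) for el in ELEMENTS}
            if any(v < 0 for v in comp.values()):
                raise ValidationError(
                    f"planted series {s_idx} step {k} yields a negative element count"
                )
            rows.append(comp)
        for k in range(steps):
            truth.append({"series": s_idx, "key_name": key_name, "step": k})
    cols = list(ELEMENTS)
    formulas = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    return formulas, pd.DataFrame(truth)


def generate_report(
    spec: FixtureSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Generate (report, metadata, truth) for a synthetic study.

    ``report`` uses the Formularity column dialect (``Mass, C, H, O, N, S,
    P, C13, Error_ppm`` + one column per sample); ``metadata`` has
    ``SampleID`` and grouping columns ``Group`` (and ``Group2``); ``truth``
    holds the planted series edges, per-peak affected flags and the row
    masks for unassigned/isotopologue rows.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids = [f"S{i + 1:02d}" for i in range(spec.n_samples)]
    if spec.groups is None:
        half = spec.n_samples // 2
        groups = ["A"] * half + ["B"] * (spec.n_samples - half)
    else:
        groups = list(spec.groups)
    meta = pd.DataFrame({"SampleID": sample_ids, "Group": groups})
    if spec.groups2 is not None:
        meta["Group2"] = list(spec.groups2)

    series, series_truth = _series_peaks(spec)
    n_random = spec.n_peaks - len(series)
    if n_random < 0:
        raise ValidationError("planted series exceed n_peaks")
    formulas = pd.concat(
        [series, _sample_formulas(spec, rng, n_random)], ignore_index=True
    )
    n = len(formulas)
    n_series = len(series)

    mass = np.array([
        formula_mass({el: int(row[el]) for el in ELEMENTS}) for _, row in formulas.iterrows()
    ])
    if spec.mass_jitter_ppm > 0:
        mass = mass * (1.0 + rng.uniform(-1, 1, n) * spec.mass_jitter_ppm * 1e-6)

    # unassigned and 13C rows only among the random (non-planted) peaks
    no_formula = np.zeros(n, bool)
    c13 = np.zeros(n, bool)
    candidates = rng.permutation(np.arange(n_series, n))
    k_nf = int(round(spec.frac_no_formula * n))
    k_c13 = int(round(spec.frac_c13 * n))
    no_formula[candidates[:k_nf]] = True
    c13[candidates[k_nf:k_nf + k_c13]] = True
    formulas.loc[no_formula, list(ELEMENTS)] = 0

    error = rng.normal(0.0, spec.error_sd_ppm, n)
    error[no_formula] = np.nan

    # intensities: per-peak baseline + group effect on an affected subset
    base = rng.normal(spec.base_log10_intensity, spec.peak_sd, n)
    affected = np.zeros(n, bool)
    effect = spec.group_effect or {}
    if effect:
        n_aff = int(round(spec.affected_fraction * n))
        affected[rng.choice(n, n_aff, replace=False)] = True
    log10_int = np.empty((n, spec.n_samples))
    for j, g in enumerate(groups):
        shift = effect.get(g, 0.0) * affected
        log10_int[:, j] = base + shift + rng.normal(0.0, spec.noise_sd, n)
    intensities = 10.0 ** log10_int
    drop = rng.random((n, spec.n_samples)) < spec.dropout_rate
    drop[:n_series] = False  # planted series detected everywhere
    intensities[drop] = 0.0

    report = pd.DataFrame(
        {
            "Mass": mass,
            "C": formulas["C"], "H": formulas["H"], "O": formulas["O"],
            "N": formulas["N"], "S": formulas["S"], "P": formulas["P"],
            "C13": c13.astype(int),
            "Error_ppm": error,
        }
    )
    for j, s in enumerate(sample_ids):
        report[s] = intensities[:, j]

    truth = {
        "series_edges": series_truth,
        "affected_peaks": pd.DataFrame({"row": np.where(affected)[0]}),
        "no_formula_rows": pd.DataFrame({"row": np.where(no_formula)[0]}),
        "c13_rows": pd.DataFrame({"row": np.where(c13)[0]}),
    }
    return report, meta, truth


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write report/metadata/truth CSVs for a spec; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report, meta, truth = generate_report(spec)
    paths = {
        "report": outdir / "report.csv",
        "metadata": outdir / "metadata.csv",
    }
    report.to_csv(paths["report"], index=False)
    meta.to_csv(paths["metadata"], index=False)
    for name, table in truth.items():
        p = outdir / f"truth_{name}.csv"
        table.to_csv(p, index=False)
        paths[name] = p
    return paths
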