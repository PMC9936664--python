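"""Shared builders for toy peak tables and synthetic studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dimetab.io import RunConfig
from dimetab.preprocessing import IntensityMatrix, annotate_peaks


def make_peaks(rows: list[dict], sample_ids: list[str]) -> pd.DataFrame:
    """Build an internal-format peak table from row dicts.

    Each row dict may give mass, C, H, O, N, S, P, has_c13, error_ppm and
    per-sample intensities (under the sample id); omitted fields default to
    formula-less, non-isotopologue, intensity 0.
    """
    defaults = {"C": 0, "H": 0, "O": 0, "N": 0, "S": 0, "P": 0,
                "has_c13": False, "error_ppm": np.nan}
    full = []
    for r in rows:
        d = dict(defaults)
        d.update({s: 0.0 for s in sample_ids})
        d.update(r)
        full.append(d)
    peaks = pd.DataFrame(full)
    peaks.index = pd.Index([f"peak_{i}" for i in range(len(peaks))], name="peak_id")
    peaks.attrs["sample_columns"] = list(sample_ids)
    return peaks


def make_metadata(groups: dict[str, str], group2: dict[str, str] | None = None) -> pd.DataFrame:
    meta = pd.DataFrame({"Group": pd.Series(groups)})
    if group2:
        meta["Group2"] = pd.Series(group2)
    meta.index.name = "SampleID"
    meta.attrs["grouping"] = ["Group"] + (["Group2"] if group2 else [])
    return meta


@pytest.fixture
def default_config() -> RunConfig:
    return RunConfig(mass_window=(0.0, 2000.0), presence_min=1, grouping=("Group",))


@pytest.fixture
def annotated_two_group():
    """6 formula-bearing peaks, 4 samples in 2 groups, full detection."""
    rng = np.random.default_rng(11)
    rows = []
    for i in range(6):
        c = int(rng.integers(5, 25))
        rows.append(
            {
                "mass": 100.0 + 50 * i,
                "C": c,
                "H": int(max(1, round(c * rng.uniform(0.8, 2.0)))),
                "O": int(round(c * rng.uniform(0.1, 0.9))),
                "SampA1": 10.0 + i, "SampA2": 12.0 + i,
                "SampB1": 9.0 + i, "SampB2": 11.0 + i,
            }
        )
    peaks = annotate_peaks(make_peaks(rows, ["SampA1", "SampA2", "SampB1", "SampB2"]))
    meta = make_metadata({"SampA1": "A", "SampA2": "A", "SampB1": "B", "SampB2": "B"})
    return peaks, meta


def raw_matrix(peaks: pd.DataFrame) -> IntensityMatrix:
    return IntensityMatrix.from_peaks(peaks)
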