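"""Reading and validation of the three pipeline inputs.

The pipeline consumes (1) a molecular-formula/intensity report as produced
by formula-assignment software (Formularity-style CSV: one row per detected
peak, element counts, a 13C-isotopologue flag, assignment error in ppm and
one intensity column per sample), (2) a sample metadata table with up to two
grouping variables, and (3) a biochemical-transformation key of named exact
mass differences.

Peaks are held as a :class:`pandas.DataFrame` with one row per peak
("peak table"); intensities live in the same frame, one column per sample.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._elements import formula_mass
from .errors import FormatError, ParseError, ValidationError

#: canonical internal names for the per-peak attribute columns
PEAK_COLUMNS = ["mass", "C", "H", "O", "N", "S", "P", "has_c13", "error_ppm"]

#: default column-name mapping for Formularity report files
FORMULARITY_DIALECT: dict[str, str] = {
    "mass": "Mass",
    "C": "C",
    "H": "H",
    "O": "O",
    "N": "N",
    "S": "S",
    "P": "P",
    "has_c13": "C13",
    "error_ppm": "Error_ppm",
}

NORMALIZATION_METHODS = ("max", "minmax", "mean", "median", "sum", "zscore")
KEY_CATEGORIES = ("biotic", "abiotic", "unclassified")


@dataclasses.dataclass
class RunConfig:
    """Run configuration shared by all pipeline steps.

    Attributes
    ----------
    mass_window : (min, max) in Da; peaks outside are filtered out.
    error_max_ppm : maximum absolute formula-assignment error (inclusive).
    presence_min : minimum number of samples a peak must be detected in
        (int), or a fraction of samples (float in (0, 1]).
    normalization_method : one of ``max, minmax, mean, median, sum, zscore``.
    grouping : 1-2 metadata column names used as grouping variables.
    transformation_key_path : CSV path or ``"builtin"``.
    ppm_tolerance : mass-difference matching tolerance (ppm of the key mass).
    rng_seed : seed for every stochastic step (permutations, NMDS restarts).
    """

    mass_window: tuple[float, float] = (0.0, 2000.0)
    error_max_ppm: float = 0.5
    presence_min: float = 1
    normalization_method: str = "max"
    grouping: Sequence[str] = ("group1",)
    transformation_key_path: str = "builtin"
    ppm_tolerance: float = 1.0
    rng_seed: int = 42

    def __post_init__(self) -> None:
        lo, hi = self.mass_window
        if not lo < hi:
            raise ValidationError(f"mass_window min must be < max, got {self.mass_window}")
        if self.error_max_ppm <= 0:
            raise ValidationError("error_max_ppm must be > 0")
        if self.ppm_tolerance <= 0:
            raise ValidationError("ppm_tolerance must be > 0")
        if self.normalization_method not in NORMALIZATION_METHODS:
            raise ValidationError(
                f"unknown normalization method {self.normalization_method!r}; "
                f"choose one of {NORMALIZATION_METHODS}"
            )
        if not 1 <= len(self.grouping) <= 2:
            raise ValidationError("grouping must name 1 or 2 metadata columns")


def read_report(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sample_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a Formularity-style report CSV into a peak table.

    Parameters
    ----------
    path : CSV file with one row per detected peak.
    dialect : mapping from canonical column names (``mass, C, H, O, N, S, P,
        has_c13, error_ppm``) to the file's column names. Defaults to the
        Formularity names. ``has_c13`` and ``error_ppm`` are optional in the
        file (missing flag column means no 13C isotopologues; missing error
        column means error unknown and never filtered on).
    sample_columns : which of the remaining columns are per-sample
        intensities; by default every unmapped column.

    Returns
    -------
    DataFrame indexed by ``peak_id`` (stable, file row order) with the
    canonical peak columns followed by one intensity column per sample.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dia = dict(FORMULARITY_DIALECT)
    if dialect:
        dia.update(dialect)
    raw = pd.read_csv(path)

    mandatory = ["mass", "C", "H", "O", "N", "S", "P"]
    for canon in mandatory:
        if dia[canon] not in raw.columns:
            raise FormatError(
                f"report {path.name} is missing mandatory column "
                f"{dia[canon]!r} (for {canon!r})"
            )

    mapped = {canon: col for canon, col in dia.items() if col in raw.columns}
    peaks = pd.DataFrame(index=raw.index)
    peaks["mass"] = _numeric(raw[mapped["mass"]], mapped["mass"], path)
    for el in ("C", "H", "O", "N", "S", "P"):
        peaks[el] = _numeric(raw[mapped[el]], mapped[el], path).fillna(0).astype(int)
        if (peaks[el] < 0).any():
            row = int(peaks.index[peaks[el] < 0][0])
            raise ParseError(f"negative element count {el} at row {row + 2} of {path.name}")
    if "has_c13" in mapped:
        peaks["has_c13"] = _numeric(raw[mapped["has_c13"]], mapped["has_c13"], path).fillna(0) > 0
    else:
        peaks["has_c13"] = False
    if "error_ppm" in mapped:
        peaks["error_ppm"] = _numeric(raw[mapped["error_ppm"]], mapped["error_ppm"], path)
    else:
        peaks["error_ppm"] = np.nan

    if (peaks["mass"] <= 0).any() or peaks["mass"].isna().any():
        row = int(peaks.index[~(peaks["mass"] > 0)][0])
        raise ParseError(f"non-positive or missing mass at row {row + 2} of {path.name}")

    mapped_cols = set(mapped.values())
    if sample_columns is None:
        sample_columns = [c for c in raw.columns if c not in mapped_cols]
    if not sample_columns:
        raise FormatError(f"report {path.name} has no per-sample intensity columns")
    for col in sample_columns:
        vals = _numeric(raw[col], col, path)
        if vals.isna().any():
            warnings.warn(
                f"missing intensity cells in column {col!r} treated as 0 (absent)",
                stacklevel=2,
            )
            vals = vals.fillna(0.0)
        if (vals < 0).any():
            row = int(vals.index[vals < 0][0])
            raise ParseError(f"negative intensity in column {col!r} at row {row + 2}")
        peaks[col] = vals

    dup = peaks.duplicated(subset=["mass", "C", "H", "O", "N", "S", "P"], keep=False)
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate mass+formula rows in {path.name}; rows kept",
            stacklevel=2,
        )
    peaks.index = pd.Index([f"peak_{i}" for i in peaks.index], name="peak_id")
    peaks.attrs["sample_columns"] = list(sample_columns)
    return peaks


def _numeric(series: pd.Series, name: str, path: Path) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(series.index[bad][0])
        raise ParseError(
            f"non-numeric value {series[row]!r} in column {name!r} "
            f"at row {row + 2} of {path.name}"
        )
    return out


def sample_columns_of(peaks: pd.DataFrame) -> list[str]:
    """Names of the intensity columns of a peak table."""
    cols = peaks.attrs.get("sample_columns")
    if cols is None:  # reconstructed frame (e.g. read back from CSV)
        cols = [c for c in peaks.columns if c not in PEAK_COLUMNS]
    return list(cols)


def write_report(peaks: pd.DataFrame, path: str | Path) -> None:
    """Write a peak table back to CSV, numeric cells to 10 significant digits."""
    peaks.to_csv(path, float_format="%.10g")


def read_metadata(
    path: str | Path,
    grouping: Sequence[str],
    report_samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read and validate the sample metadata table.

    The first column (or a column named ``SampleID``) is the sample ID;
    ``grouping`` names 1-2 categorical columns. When ``report_samples`` is
    given, every metadata sample must appear among the report's intensity
    columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = pd.read_csv(path, dtype=str)
    id_col = "SampleID" if "SampleID" in meta.columns else meta.columns[0]
    if len(grouping) > 2:
        raise ValidationError(f"at most 2 grouping variables are supported, got {len(grouping)}")
    if len(grouping) < 1:
        raise ValidationError("at least 1 grouping variable is required")
    for g in grouping:
        if g not in meta.columns:
            raise FormatError(f"metadata {path.name} is missing grouping column {g!r}")
        if meta[g].isna().any():
            raise ValidationError(f"grouping column {g!r} has empty cells")
    if meta[id_col].duplicated().any():
        dup = meta[id_col][meta[id_col].duplicated()].iloc[0]
        raise ValidationError(f"duplicate sample ID {dup!r} in metadata")
    if report_samples is not None:
        missing = [s for s in meta[id_col] if s not in set(report_samples)]
        if missing:
            raise ValidationError(
                f"metadata samples absent from report intensity columns: {missing}"
            )
    meta = meta.set_index(id_col)
    meta.attrs["grouping"] = list(grouping)
    return meta


# ---------------------------------------------------------------------------
# biochemical-transformation key

#: curated default key of common biochemical mass differences. The exact
#: masses are computed from the element table at import; the biotic/abiotic
#: labels are a curated stand-in (documented in docs/methods.md) and the
#: whole key is replaceable via ``transformation_key_path``.
_BUILTIN_KEY: list[tuple[str, dict[str, int], str]] = [
    ("H2", {"H": 2}, "biotic"),                      # (de)hydrogenation
    ("H2O", {"H": 2, "O": 1}, "biotic"),             # (de)hydration / condensation
    ("CH2", {"C": 1, "H": 2}, "biotic"),             # methylation
    ("O", {"O": 1}, "abiotic"),                      # oxygenation
    ("NH3", {"N": 1, "H": 3}, "biotic"),             # amination
    ("NH", {"N": 1, "H": 1}, "abiotic"),
    ("CO", {"C": 1, "O": 1}, "abiotic"),
    ("CO2", {"C": 1, "O": 2}, "biotic"),             # (de)carboxylation
    ("CH2O", {"C": 1, "H": 2, "O": 1}, "biotic"),    # formaldehyde / hydroxymethylation
    ("C2H2O", {"C": 2, "H": 2, "O": 1}, "biotic"),   # acetylation
    ("C2H4", {"C": 2, "H": 4}, "biotic"),
    ("C2H2", {"C": 2, "H": 2}, "abiotic"),
    ("CHO2 (formate)", {"C": 1, "H": 2, "O": 2}, "biotic"),
    ("C2H4O2 (acetate)", {"C": 2, "H": 4, "O": 2}, "biotic"),
    ("C3H4O2 (pyruvate-CO)", {"C": 3, "H": 4, "O": 2}, "biotic"),
    ("SO3", {"S": 1, "O": 3}, "biotic"),             # sulfonation
    ("H2S", {"H": 2, "S": 1}, "biotic"),
    ("S", {"S": 1}, "abiotic"),
    ("HPO3", {"H": 1, "P": 1, "O": 3}, "biotic"),    # phosphorylation
    ("H3PO4", {"H": 3, "P": 1, "O": 4}, "biotic"),
    ("HNO2", {"H": 1, "N": 1, "O": 2}, "abiotic"),
    ("NO2", {"N": 1, "O": 2}, "abiotic"),
    ("C6H10O5 (glucose)", {"C": 6, "H": 10, "O": 5}, "biotic"),
    ("C5H8O4 (pentose)", {"C": 5, "H": 8, "O": 4}, "biotic"),
    ("C6H10O4 (deoxyhexose)", {"C": 6, "H": 10, "O": 4}, "biotic"),
    ("C2H3NO (glycine)", {"C": 2, "H": 3, "N": 1, "O": 1}, "biotic"),
    ("C3H5NO (alanine)", {"C": 3, "H": 5, "N": 1, "O": 1}, "biotic"),
    ("C3H5NO2 (serine)", {"C": 3, "H": 5, "N": 1, "O": 2}, "biotic"),
    ("C5H7NO3 (glutamate-H2O)", {"C": 5, "H": 7, "N": 1, "O": 3}, "biotic"),
    ("C9H9NO (phenylalanine-H2O)", {"C": 9, "H": 9, "N": 1, "O": 1}, "biotic"),
]


def builtin_transformation_key() -> pd.DataFrame:
    """The shipped default transformation key (sorted by mass difference)."""
    rows = [
        {"name": name, "mass_difference": formula_mass(comp), "category": cat}
        for name, comp, cat in _BUILTIN_KEY
    ]
    key = pd.DataFrame(rows).sort_values("mass_difference", ignore_index=True)
    return key


def read_transformation_key(path: str | Path) -> pd.DataFrame:
    """Read a transformation key CSV (``name, mass_difference, category``).

    ``path="builtin"`` returns the shipped default key.
    """
    if str(path) == "builtin":
        return builtin_transformation_key()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    key = pd.read_csv(path)
    needed = {"name", "mass_difference", "category"}
    if not needed.issubset(key.columns):
        raise FormatError(
            f"transformation key {path.name} must have columns {sorted(needed)}"
        )
    key["mass_difference"] = pd.to_numeric(key["mass_difference"])
    if (key["mass_difference"] <= 0).any():
        bad = key.loc[key["mass_difference"] <= 0, "name"].iloc[0]
        raise ValidationError(f"non-positive mass difference for key entry {bad!r}")
    if key["name"].duplicated().any():
        dup = key["name"][key["name"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate transformation name {dup!r}")
    unknown = set(key["category"]) - set(KEY_CATEGORIES)
    if unknown:
        raise ValidationError(
            f"unknown transformation categories {sorted(unknown)}; "
            f"allowed: {KEY_CATEGORIES}"
        )
    return key.sort_values("mass_difference", ignore_index=True)
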