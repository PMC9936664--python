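"""Peak filtering, thermodynamic/molecular indices, compound classes and
intensity normalization.

The indices summarize what a molecular formula implies about a compound's
redox state and structure:

* **NOSC** — nominal oxidation state of carbon, the average oxidation state
  of C atoms implied by the elemental composition (range −4 for CH4 to +4
  for CO2), for neutral molecules (charge Z = 0):
  ``NOSC = 4 − (4C + H − 3N − 2O + 5P − 2S) / C``
* **GFE** — Gibbs free energy of the carbon half-oxidation reaction in
  kJ (mol C)⁻¹, affine in NOSC: ``GFE = 60.3 − 28.5·NOSC``. More oxidized
  (higher-NOSC) compounds are thermodynamically more favorable to degrade.
* **AImod** — modified aromaticity index, the density of C=C double bonds
  after discounting carbonyl-type bonds (half of O counts toward π bonds):
  ``AImod = (1 + C − O/2 − S − (N + P + H)/2) / (C − O/2 − N − S − P)``,
  reported as 0 when the denominator ≤ 0 **or** the numerator < 0 (the
  usual convention for this index family).
* **DBE** — double-bond equivalents (rings + π bonds):
  ``DBE = 1 + (2C − H + N + P)/2``.

Compound classes are assigned from the (O/C, H/C) position on the van
Krevelen plane using an ordered rectangular-region table (lower bounds
inclusive, upper bounds exclusive; first match wins).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import RunConfig, sample_columns_of

GFE_INTERCEPT = 60.3   # kJ / mol C
GFE_SLOPE = -28.5      # kJ / mol C per NOSC unit

#: ordered van Krevelen regions: (class, O/C lo, O/C hi, H/C lo, H/C hi);
#: lower bounds inclusive, upper bounds exclusive, first match wins.
COMPOUND_CLASS_REGIONS: list[tuple[str, float, float, float, float]] = [
    ("Lipid", 0.0, 0.3, 1.5, 2.5),
    ("Protein", 0.3, 0.67, 1.5, 2.3),
    ("Carbohydrate", 0.67, 1.2, 1.5, 2.5),
    ("Unsaturated hydrocarbon", 0.0, 0.1, 0.7, 1.5),
    ("Lignin", 0.1, 0.67, 0.7, 1.5),
    ("Tannin", 0.67, 1.2, 0.5, 1.5),
    ("Condensed aromatic", 0.0, 0.67, 0.2, 0.7),
]

COMPOUND_CLASSES = [name for name, *_ in COMPOUND_CLASS_REGIONS] + ["Other"]


# ---------------------------------------------------------------------------
# filtering

def has_formula(peaks: pd.DataFrame) -> pd.Series:
    """A peak carries a molecular formula iff it has both C and H atoms."""
    return (peaks["C"] > 0) & (peaks["H"] > 0)


def filter_peaks(peaks: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the four peak filters in order: mass window, 13C isotopologue,
    assignment error, minimum presence.

    A peak is kept iff its mass lies in the closed ``mass_window``, it is not
    a 13C isotopologue, its absolute assignment error is ≤ ``error_max_ppm``
    (peaks without a formula, or without a reported error, pass this rule)
    and it is detected (intensity > 0) in at least ``presence_min`` samples.

    Returns
    -------
    kept : the surviving peak rows (order preserved).
    audit : removal counts per rule, in application order; sums to
        ``len(peaks) - len(kept)``.
    """
    samples = sample_columns_of(peaks)
    n_samples = len(samples)
    pmin = config.presence_min
    if 0 < pmin < 1:
        pmin = int(np.ceil(pmin * n_samples))
    pmin = int(pmin)
    if pmin > n_samples:
        raise ValidationError(
            f"presence_min={pmin} exceeds the number of samples ({n_samples})"
        )

    audit = {}
    lo, hi = config.mass_window
    keep = (peaks["mass"] >= lo) & (peaks["mass"] <= hi)
    audit["mass_window"] = int((~keep).sum())
    cur = peaks[keep]

    keep = ~cur["has_c13"].astype(bool)
    audit["isotope_13c"] = int((~keep).sum())
    cur = cur[keep]

    err_ok = cur["error_ppm"].abs() <= config.error_max_ppm
    keep = err_ok | ~has_formula(cur) | cur["error_ppm"].isna()
    audit["assignment_error"] = int((~keep).sum())
    cur = cur[keep]

    n_detected = (cur[samples] > 0).sum(axis=1)
    keep = n_detected >= pmin
    audit["presence"] = int((~keep).sum())
    cur = cur[keep]

    cur = cur.copy()
    cur.attrs["sample_columns"] = samples
    return cur, pd.Series(audit, name="n_removed")


# ---------------------------------------------------------------------------
# indices and classes

def compute_indices(C: int, H: int, O: int = 0, N: int = 0, S: int = 0, P: int = 0) -> dict:
    """Indices for a single elemental composition; raises if C or H is 0."""
    if C <= 0 or H <= 0:
        raise ValidationError("indices are undefined for peaks without a formula (C=0 or H=0)")
    nosc = 4.0 - (4.0 * C + H - 3.0 * N - 2.0 * O + 5.0 * P - 2.0 * S) / C
    gfe = GFE_INTERCEPT + GFE_SLOPE * nosc
    dbe = 1.0 + 0.5 * (2.0 * C - H + N + P)
    denom = C - 0.5 * O - N - S - P
    numer = 1.0 + C - 0.5 * O - S - 0.5 * (N + P + H)
    ai_mod = 0.0 if denom <= 0 or numer < 0 else numer / denom
    return {
        "ratio_OC": O / C,
        "ratio_HC": H / C,
        "nosc": nosc,
        "gfe": gfe,
        "dbe": dbe,
        "ai_mod": ai_mod,
    }


def assign_compound_class(ratio_OC: float, ratio_HC: float) -> str:
    """First matching van Krevelen region, or ``"Other"``."""
    for name, oc_lo, oc_hi, hc_lo, hc_hi in COMPOUND_CLASS_REGIONS:
        if oc_lo <= ratio_OC < oc_hi and hc_lo <= ratio_HC < hc_hi:
            return name
    return "Other"


def _element_class(row: pd.Series) -> str:
    return "".join(el for el in ("C", "H", "O", "N", "S", "P") if row[el] > 0)


def annotate_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Vectorized annotation of a peak table with ratios, indices, compound
    class and element class.

    Peaks without a molecular formula get NaN indices and class
    ``"Unassigned"``; they stay in the table (diagnostics counts them) but
    every downstream analysis that needs a formula excludes them.
    """
    out = peaks.copy()
    hf = has_formula(out)
    C = out["C"].to_numpy(float)
    H = out["H"].to_numpy(float)
    O = out["O"].to_numpy(float)
    N = out["N"].to_numpy(float)
    S = out["S"].to_numpy(float)
    P = out["P"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        nosc = 4.0 - (4.0 * C + H - 3.0 * N - 2.0 * O + 5.0 * P - 2.0 * S) / C
        oc = O / C
        hc = H / C
    dbe = 1.0 + 0.5 * (2.0 * C - H + N + P)
    denom = C - 0.5 * O - N - S - P
    numer = 1.0 + C - 0.5 * O - S - 0.5 * (N + P + H)
    ai = np.where((denom <= 0) | (numer < 0), 0.0, numer / np.where(denom == 0, np.nan, denom))

    mask = hf.to_numpy()
    out["ratio_OC"] = np.where(mask, oc, np.nan)
    out["ratio_HC"] = np.where(mask, hc, np.nan)
    out["nosc"] = np.where(mask, nosc, np.nan)
    out["gfe"] = np.where(mask, GFE_INTERCEPT + GFE_SLOPE * nosc, np.nan)
    out["dbe"] = np.where(mask, dbe, np.nan)
    out["ai_mod"] = np.where(mask, ai, np.nan)
    out["compound_class"] = [
        assign_compound_class(o, h) if m else "Unassigned"
        for o, h, m in zip(oc, hc, mask)
    ]
    out["element_class"] = [
        _element_class(row) if m else "" for (_, row), m in zip(out.iterrows(), mask)
    ]
    out.attrs["sample_columns"] = sample_columns_of(peaks)
    return out


# ---------------------------------------------------------------------------
# normalization

class IntensityMatrix:
    """A peaks × samples abundance matrix with its normalization state.

    ``values`` is a DataFrame indexed by peak_id with one column per sample.
    Zeros denote *absence* (non-detection): they are excluded from every
    per-sample statistic and remain exactly 0 after any normalization.
    """

    def __init__(self, values: pd.DataFrame, normalization: str = "raw",
                 factors: pd.DataFrame | None = None):
        self.values = values
        self.normalization = normalization
        self.factors = factors  # per-sample location/scale used, if normalized

    @classmethod
    def from_peaks(cls, peaks: pd.DataFrame) -> "IntensityMatrix":
        return cls(peaks[sample_columns_of(peaks)].astype(float).copy())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def peak_ids(self) -> list[str]:
        return list(self.values.index)


def normalization_factors(values: pd.DataFrame, method: str) -> pd.DataFrame:
    """Per-sample location and scale for a normalization method, computed
    over detected peaks only (zeros excluded).

    Every method is expressed as ``x' = (x − location) / scale``:

    ========  ==========  ================
    method    location    scale
    ========  ==========  ================
    max       0           max
    minmax    min         max − min
    mean      mean        max − min
    median    median      max − min
    sum       0           Σx
    zscore    mean        sd (ddof = 1)
    ========  ==========  ================
    """
    loc = {}
    scale = {}
    for s in values.columns:
        col = values[s]
        x = col[col > 0]
        if x.empty:
            raise ValidationError(f"sample {s!r} has no detected peaks")
        if method == "max":
            loc[s], scale[s] = 0.0, x.max()
        elif method == "minmax":
            loc[s], scale[s] = x.min(), x.max() - x.min()
        elif method == "mean":
            loc[s], scale[s] = x.mean(), x.max() - x.min()
        elif method == "median":
            loc[s], scale[s] = x.median(), x.max() - x.min()
        elif method == "sum":
            loc[s], scale[s] = 0.0, x.sum()
        elif method == "zscore":
            loc[s], scale[s] = x.mean(), x.std(ddof=1)
        else:
            raise ValidationError(f"unknown normalization method {method!r}")
        if scale[s] == 0 or not np.isfinite(scale[s]):
            raise ValidationError(
                f"normalization {method!r} is degenerate for sample {s!r} "
                f"(zero scale: constant or single-peak column)"
            )
    return pd.DataFrame({"location": loc, "scale": scale})


def normalize(matrix: IntensityMatrix, method: str) -> IntensityMatrix:
    """Normalize each sample column; absences (zeros) stay 0."""
    if matrix.normalization != "raw":
        raise ValidationError(
            f"matrix is already normalized ({matrix.normalization!r}); start from raw"
        )
    fac = normalization_factors(matrix.values, method)
    out = matrix.values.copy()
    for s in out.columns:
        col = out[s]
        detected = col > 0
        out[s] = np.where(
            detected, (col - fac.loc[s, "location"]) / fac.loc[s, "scale"], 0.0
        )
    return IntensityMatrix(out, normalization=method, factors=fac)


def denormalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Invert a normalization using the stored per-sample factors."""
    if matrix.factors is None or matrix.normalization == "raw":
        raise ValidationError("matrix carries no normalization factors to invert")
    out = matrix.values.copy()
    for s in out.columns:
        col = out[s]
        detected = col != 0
        out[s] = np.where(
            detected,
            col * matrix.factors.loc[s, "scale"] + matrix.factors.loc[s, "location"],
            0.0,
        )
    return IntensityMatrix(out, normalization="raw")
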