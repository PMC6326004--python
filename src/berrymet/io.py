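"""Reading and writing of peak tables, sample metadata and compound libraries.

All tabular formats are plain CSV. A peak table holds one deconvolved
RT-m/z feature per row (feature_id, rt_min, mz, then one column per
sample); missing intensities are empty cells, never zero — a written zero
is a measured zero. Retention times are minutes everywhere; second-based
windows are converted at the call sites that take them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .chem import monoisotopic_mass, parse_formula

PEAK_META_COLS = ["feature_id", "rt_min", "mz"]
SAMPLE_META_COLS = [
    "sample_id",
    "type",
    "temperature",
    "daylength",
    "block",
    "polarity",
    "injection_order",
]
LIBRARY_COLS = [
    "name",
    "formula",
    "neutral_mass",
    "compound_class",
    "charge",
    "rt_ref",
    "ms2_ref",
    "ms3_ref",
]

SAMPLE_TYPES = {"biological", "qa", "blank"}

#: tolerance for a library entry's stored mass vs its formula-recomputed mass
LIBRARY_MASS_TOL = 5e-4


class PeakTableError(ValueError):
    pass


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read a peak table CSV into a feature-per-row DataFrame.

    Returns a frame with columns feature_id (str), rt_min, mz, followed by
    one float column per sample; absent cells become NaN.
    """
    df = pd.read_csv(path, dtype={"feature_id": str})
    missing = [c for c in PEAK_META_COLS if c not in df.columns]
    if missing:
        raise PeakTableError(f"peak table {path} lacks columns {missing}")
    dup = df["feature_id"][df["feature_id"].duplicated()]
    if len(dup):
        raise PeakTableError(f"duplicate feature_id(s): {sorted(set(dup))}")
    sample_cols = [c for c in df.columns if c not in PEAK_META_COLS]
    for col in ["rt_min", "mz", *sample_cols]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise PeakTableError(f"malformed numeric cell in column {col!r}, row {row}") from exc
    if (df["rt_min"] < 0).any() or (df["mz"] <= 0).any():
        raise PeakTableError("rt_min must be >= 0 and mz > 0")
    return df


def write_peak_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(
        path, dtype={"sample_id": str, "temperature": str, "daylength": str, "block": str}
    )
    missing = [c for c in SAMPLE_META_COLS if c not in meta.columns]
    if missing:
        raise PeakTableError(f"sample metadata {path} lacks columns {missing}")
    return validate_sample_meta(meta)


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    bad = set(meta["type"]) - SAMPLE_TYPES
    if bad:
        raise PeakTableError(f"unknown sample type(s) {sorted(bad)}")
    bio = meta["type"] == "biological"
    design_cols = ["temperature", "daylength", "block"]
    for col in design_cols:
        vals = meta[col].astype("string")
        if (bio & (vals.isna() | (vals == ""))).any():
            raise PeakTableError(f"biological sample lacking {col}")
        # QA/blank injections carry no treatment coordinates
        if ((~bio) & vals.notna() & (vals != "")).any():
            raise PeakTableError(f"non-biological sample carries {col}")
    # one metadata row per (sample, polarity): ids repeat across polarities only
    if meta.duplicated(subset=["sample_id", "polarity"]).any():
        raise PeakTableError("duplicate (sample_id, polarity) in metadata")
    return meta


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def read_library(path: str | Path) -> pd.DataFrame:
    """Read a compound library CSV, recomputing and validating neutral masses.

    ms2_ref / ms3_ref are semicolon-separated fragment m/z lists (may be
    empty); charge is 1 for intrinsic cations (flavylium anthocyanins),
    0 for neutrals.
    """
    lib = pd.read_csv(path, dtype={"name": str, "formula": str, "compound_class": str})
    missing = [c for c in LIBRARY_COLS if c not in lib.columns]
    if missing:
        raise PeakTableError(f"library {path} lacks columns {missing}")
    for idx, row in lib.iterrows():
        calc = monoisotopic_mass(parse_formula(row["formula"]))
        if abs(calc - float(row["neutral_mass"])) > LIBRARY_MASS_TOL:
            raise PeakTableError(
                f"library entry {row['name']!r}: stored mass {row['neutral_mass']} "
                f"disagrees with formula mass {calc:.4f}"
            )
    if lib["name"].duplicated().any():
        raise PeakTableError("duplicate compound name in library")
    return lib


def write_library(lib: pd.DataFrame, path: str | Path) -> None:
    lib.to_csv(path, index=False, float_format="%.5f")


def parse_fragment_list(cell: object) -> list[float]:
    """Parse a 'm1;m2;...' reference-fragment cell; NaN/empty -> []."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return []
    return [float(tok) for tok in str(cell).split(";") if tok.strip()]


def sample_columns(peaks: pd.DataFrame) -> list[str]:
    return [c for c in peaks.columns if c not in PEAK_META_COLS]


def intensity_matrix(peaks: pd.DataFrame) -> pd.DataFrame:
    """Samples x features intensity matrix (the sklearn orientation)."""
    mat = peaks.set_index("feature_id")[sample_columns(peaks)].T
    mat.index.name = "sample_id"
    mat.columns.name = "feature_id"
    return mat.astype(float)
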