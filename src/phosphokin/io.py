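"""Reading and writing the pipeline's tabular formats.

All tables are plain TSV/CSV handled through pandas. The evidence table is
long format, one row per peptide ion (fragment) per sample:

    peptide  protein  phosphosites  fragment  sample  condition  intensity

``phosphosites`` is a semicolon-joined list of phosphosite keys
(``"P1_S45;P1_S49"``); an empty ``intensity`` field means the ion was not
observed in that sample. Intensities are linear scale and strictly positive.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .sites import parse_site_key

EVIDENCE_COLUMNS = ["peptide", "protein", "phosphosites", "fragment", "sample", "condition", "intensity"]


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_evidence(path) -> pd.DataFrame:
    """Load and validate a peptide-level evidence table (TSV or CSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"phosphosites": str})
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: evidence table missing columns {missing}")
    df = df[EVIDENCE_COLUMNS].copy()
    df["intensity"] = pd.to_numeric(df["intensity"], errors="coerce")
    validate_evidence(df, source=str(path))
    return df


def validate_evidence(df: pd.DataFrame, source: str = "evidence") -> None:
    """Check the evidence-table invariants; raise ParseError on violation."""
    observed = df["intensity"].dropna()
    if (observed <= 0).any():
        bad = df.index[df["intensity"] <= 0][0]
        raise ParseError(f"{source}: non-positive intensity at row {bad}; intensities must be strictly positive")
    dup = df.duplicated(subset=["peptide", "fragment", "sample"])
    if dup.any():
        raise ParseError(f"{source}: duplicate (peptide, fragment, sample) at row {df.index[dup][0]}")
    for idx, protein, sites in df[["protein", "phosphosites"]].itertuples():
        if not isinstance(sites, str) or not sites:
            raise ParseError(f"{source}: row {idx} has no phosphosite annotation")
        for key in sites.split(";"):
            p, _, _ = parse_site_key(key)
            if p != protein:
                raise ParseError(
                    f"{source}: row {idx} phosphosite {key!r} does not belong to protein {protein!r}"
                )


def write_evidence(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_design(path) -> pd.Series:
    """Read a design table (sample, condition) into a sample -> condition Series."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("sample", "condition"):
        if col not in df.columns:
            raise ParseError(f"{path}: design table missing column {col!r}")
    if df["sample"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids in design table")
    return pd.Series(df["condition"].values, index=df["sample"].values, name="condition")


def write_design(design: pd.Series, path) -> None:
    pd.DataFrame({"sample": design.index, "condition": design.values}).to_csv(
        Path(path), sep=_sep_for(path), index=False
    )


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a site-group x sample matrix; first column is the group key."""
    out = matrix.copy()
    out.insert(0, "site_group", out.index)
    out.to_csv(Path(path), sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    if "site_group" not in df.columns:
        raise ParseError(f"{path}: matrix missing 'site_group' column")
    return df.set_index("site_group")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), sep="\t", index=False, na_rep="")


def log2_intensities(df: pd.DataFrame) -> pd.Series:
    """log2 of the intensity column; missing stays missing."""
    with np.errstate(invalid="ignore"):
        return np.log2(df["intensity"])
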