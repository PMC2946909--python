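"""Tabular IO for the pipeline's artifacts.

All artifacts are plain delimited text (TSV by default, ``.`` decimal point,
UTF-8, one header row). The three shapes are:

* **pivot table** — peptide x sample amplitude matrix with consensus mass and
  migration time per peptide (columns ``protein_id``, ``mass_da``,
  ``cetime_min``, then one column per sample id);
* **metadata table** — one row per subject with diagnosis and clinical
  covariates;
* **panel table** — an ordered list of peptide ids, optionally annotated with
  sequence / protein name / accession.

Blank amplitude cells and explicit ``0`` both mean "not detected" and are
stored as 0; a peptide's detection frequency in a sample group is the fraction
of that group's samples with amplitude > 0.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "PeptideMatrix",
    "CohortTable",
    "PanelDefinition",
    "read_pivot_table",
    "write_pivot_table",
    "read_metadata",
    "write_metadata",
    "read_panel",
    "write_panel",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


PIVOT_INDEX_COLS = ["protein_id", "mass_da", "cetime_min"]

#: Clinical covariates that must be non-negative numbers when present.
NUMERIC_METADATA_COLS = [
    "age",
    "dm_duration",
    "weight",
    "serum_creatinine",
    "urinary_albumin",
    "acr",
    "gfr",
    "sbp",
    "dbp",
    "bmi",
    "tc",
    "hdl",
    "ldl",
    "tg",
]

DIAGNOSES = ("control", "t1d", "t2d")


@dataclass
class PeptideMatrix:
    """Cross-sample clustered peptide x sample amplitude table.

    Parameters
    ----------
    peptides
        Indexed by ``peptide_id`` (opaque string), columns ``mass_da``
        (neutral monoisotopic mass, Da) and ``cetime_min`` (normalized
        migration time, min).
    amplitudes
        Indexed identically, one float column per sample id. 0 means the
        peptide was not detected in that sample.
    """

    peptides: pd.DataFrame
    amplitudes: pd.DataFrame

    def __post_init__(self) -> None:
        self.peptides.index = self.peptides.index.astype(str)
        self.amplitudes.index = self.amplitudes.index.astype(str)
        self.amplitudes.columns = self.amplitudes.columns.astype(str)
        self.validate()

    def validate(self) -> None:
        if not self.peptides.index.is_unique:
            dup = self.peptides.index[self.peptides.index.duplicated()][0]
            raise ValidationError(f"duplicate peptide_id {dup!r}")
        if not self.peptides.index.equals(self.amplitudes.index):
            raise ValidationError("peptides and amplitudes index mismatch")
        if len(self.peptides):
            if (self.peptides["mass_da"] <= 0).any():
                raise ValidationError("mass_da must be > 0")
            if (self.peptides["cetime_min"] <= 0).any():
                raise ValidationError("cetime_min must be > 0")
        if len(self.amplitudes.columns) and len(self.amplitudes):
            vals = self.amplitudes.to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise ValidationError("non-finite amplitude")
            if (vals < 0).any():
                raise ValidationError("negative amplitude")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.amplitudes.columns)

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.peptides.index)

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (amplitude > 0)."""
        return self.amplitudes > 0

    def frequencies(self, groups: pd.Series | None = None) -> pd.DataFrame:
        """Per-group detection frequency of every peptide.

        ``groups`` maps sample_id -> group label; omitted, all samples form
        one group named ``"all"``.
        """
        det = self.detected()
        if groups is None:
            groups = pd.Series("all", index=det.columns)
        groups = groups.reindex(det.columns)
        return det.T.groupby(groups).mean().T

    def subset_samples(self, sample_ids) -> "PeptideMatrix":
        return PeptideMatrix(self.peptides.copy(), self.amplitudes[list(sample_ids)].copy())

    def subset_peptides(self, peptide_ids) -> "PeptideMatrix":
        ids = [str(p) for p in peptide_ids]
        return PeptideMatrix(self.peptides.loc[ids].copy(), self.amplitudes.loc[ids].copy())

    def equals(self, other: "PeptideMatrix", rtol: float = 0.0, atol: float = 1e-9) -> bool:
        if self.peptide_ids != other.peptide_ids or self.sample_ids != other.sample_ids:
            return False
        return np.allclose(
            self.peptides.to_numpy(float), other.peptides.to_numpy(float), rtol=rtol, atol=atol
        ) and np.allclose(
            self.amplitudes.to_numpy(float), other.amplitudes.to_numpy(float), rtol=rtol, atol=atol
        )


@dataclass
class CohortTable:
    """Per-subject clinical metadata, indexed by ``subject_id``.

    Always carries a ``diagnosis`` column in {control, t1d, t2d}; any other
    recognized clinical columns are validated, unknown columns pass through
    untouched.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data.index = self.data.index.astype(str)
        self.validate()

    def validate(self) -> None:
        df = self.data
        if not df.index.is_unique:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate subject_id {dup!r}")
        if "diagnosis" not in df.columns:
            raise FormatError("metadata table lacks a 'diagnosis' column")
        if df["diagnosis"].isna().any():
            raise ValidationError("diagnosis missing for some subjects")
        bad = set(df["diagnosis"].astype(str).str.lower()) - set(DIAGNOSES)
        if bad:
            raise ValidationError(f"unknown diagnosis value(s): {sorted(bad)}")
        for col in NUMERIC_METADATA_COLS:
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce")
                if ((vals < 0) & df[col].notna()).any():
                    sub = df.index[(vals < 0).fillna(False)][0]
                    raise ValidationError(f"negative {col} for subject {sub!r}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def diagnosis(self) -> pd.Series:
        return self.data["diagnosis"].astype(str).str.lower()


@dataclass
class PanelDefinition:
    """Ordered peptide-id list defining a biomarker panel."""

    peptide_ids: list[str]
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.peptide_ids = [str(p) for p in self.peptide_ids]
        if not self.peptide_ids:
            raise ValidationError("panel is empty")
        seen: set[str] = set()
        for p in self.peptide_ids:
            if p in seen:
                raise ValidationError(f"duplicate peptide_id {p!r} in panel")
            seen.add(p)

    def __len__(self) -> int:
        return len(self.peptide_ids)


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r}")


def read_pivot_table(path, dialect: str = "tsv") -> PeptideMatrix:
    """Read a peptide x sample pivot table.

    Blank cells are not-detected (0). Raises :class:`FormatError` on an empty
    file, a repeated peptide id, or a non-numeric amplitude cell (the error
    names the offending row and column).
    """
    try:
        df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty pivot table") from exc
    missing = [c for c in PIVOT_INDEX_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    ids = df["protein_id"].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate peptide_id {dup!r}")
    sample_cols = [c for c in df.columns if c not in PIVOT_INDEX_COLS]

    def _num(col: str) -> np.ndarray:
        raw = df[col].str.strip().replace("", "0")
        out = np.empty(len(raw), dtype=float)
        for i, s in enumerate(raw):
            try:
                out[i] = float(s)  # exact round-trip parsing
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {df[col].iloc[i]!r} in column "
                    f"{col!r}, row {i + 2}"
                ) from None
        return out

    peptides = pd.DataFrame(
        {"mass_da": _num("mass_da"), "cetime_min": _num("cetime_min")},
        index=pd.Index(ids, name="peptide_id"),
    )
    amplitudes = pd.DataFrame(
        {c: _num(c) for c in sample_cols}, index=peptides.index
    )
    return PeptideMatrix(peptides, amplitudes)


def write_pivot_table(
    matrix: PeptideMatrix, path, dialect: str = "tsv", zero_as_blank: bool = False
) -> None:
    """Write a pivot table readable back by :func:`read_pivot_table`."""
    matrix.validate()
    cols = {
        "protein_id": matrix.peptides.index,
        "mass_da": matrix.peptides["mass_da"].map(lambda v: repr(float(v))),
        "cetime_min": matrix.peptides["cetime_min"].map(lambda v: repr(float(v))),
    }
    for c in matrix.sample_ids:
        cols[c] = matrix.amplitudes[c].map(
            lambda v: "" if (zero_as_blank and v == 0) else repr(float(v))
        )
    pd.DataFrame(cols, index=matrix.peptides.index).to_csv(
        path, sep=_sep(dialect), index=False
    )


def read_metadata(path, dialect: str = "tsv") -> CohortTable:
    """Read a subject metadata table (must contain subject_id + diagnosis)."""
    try:
        df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty metadata table") from exc
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}: missing 'subject_id' column")
    if "diagnosis" not in df.columns:
        raise FormatError(f"{path}: missing 'diagnosis' column")
    df = df.replace("", np.nan)
    for col in NUMERIC_METADATA_COLS:
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise FormatError(
                    f"{path}: unparseable number {df[col].iloc[row]!r} in "
                    f"column {col!r}, row {row + 2}"
                )
            df[col] = vals
    df = df.set_index("subject_id")
    df["diagnosis"] = df["diagnosis"].astype(str).str.lower()
    return CohortTable(df)


def write_metadata(cohort: CohortTable, path, dialect: str = "tsv") -> None:
    cohort.data.to_csv(path, sep=_sep(dialect), index=True, index_label="subject_id")


def read_panel(path, dialect: str = "tsv") -> PanelDefinition:
    """Read an ordered peptide-id panel; extra columns become annotations."""
    try:
        df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty panel table") from exc
    if "protein_id" not in df.columns:
        raise FormatError(f"{path}: missing 'protein_id' column")
    if not len(df):
        raise FormatError(f"{path}: panel has no rows")
    ids = [str(x) for x in df["protein_id"]]
    ann = df.drop(columns=["protein_id"])
    ann.index = pd.Index(ids, name="peptide_id")
    try:
        return PanelDefinition(ids, ann)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_panel(panel: PanelDefinition, path, dialect: str = "tsv") -> None:
    out = pd.DataFrame({"protein_id": panel.peptide_ids})
    if len(panel.annotations.columns):
        out = pd.concat(
            [out, panel.annotations.reset_index(drop=True)], axis=1
        )
    out.to_csv(path, sep=_sep(dialect), index=False)
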