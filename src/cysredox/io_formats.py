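"""Readers and writers for the tabular and sequence formats the pipeline touches.

All tabular formats are tab-separated UTF-8 text with a header row and "."
as the decimal mark.  Peptide quantification tables are normalized internally
to *long* form (one row per peptide x sample) regardless of the input dialect,
because downstream site aggregation operates on long tables.

Missing values may be encoded as an empty cell, ``NA``/``NaN``, or — for raw
intensities — ``0`` (a zero intensity is treated as not observed).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SampleMeta",
    "ProteinRecord",
    "PeptideQuantRecord",
    "read_sample_meta",
    "write_sample_meta",
    "read_fasta",
    "write_fasta",
    "read_peptide_table",
    "write_peptide_table",
    "read_lfq_table",
    "write_matrix",
    "read_matrix",
    "read_psm_table",
    "write_psm_table",
    "read_thiol_table",
    "write_thiol_table",
    "parse_assigned_mods",
]

_VALID_GROUPS = ("tumor", "healthy")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
_NA_STRINGS = ("", "NA", "NaN", "nan", "N/A")


@dataclass(frozen=True)
class SampleMeta:
    """One measured sample: a tissue piece from one patient, tumor or healthy.

    ``pair_key`` groups the tumor and healthy piece of the same patient for
    paired analyses; it appears at most once per group.
    """

    sample_id: str
    patient_id: str
    group: str
    pair_key: str

    def __post_init__(self) -> None:
        if self.group not in _VALID_GROUPS:
            raise ValueError(
                f"group must be one of {_VALID_GROUPS}, got {self.group!r}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence keyed by its database accession."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for accession {self.accession!r}")
        bad = set(self.sequence) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence of {self.accession!r} contains non-standard "
                f"residues: {sorted(bad)}"
            )


@dataclass(frozen=True)
class PeptideQuantRecord:
    """One peptide observed in one sample with its light/heavy (L/H) ratio.

    The L/H ratio compares NEM-labelled (reduced in situ, light) to
    d5-NEM-labelled (oxidized in situ, heavy) signal, so it reads as
    Cys_red/Cys_ox for the cysteines the peptide carries.
    """

    peptide: str
    protein_accessions: tuple[str, ...]
    sample_id: str
    ratio_lh: float | None = None
    cys_labels: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ratio_lh is not None and not self.ratio_lh > 0:
            raise ValueError(f"ratio_LH must be > 0, got {self.ratio_lh}")
        if self.cys_labels and "C" not in self.peptide:
            raise ValueError("cys_labels given for a peptide without cysteine")


def validate_sample_meta(meta: Iterable[SampleMeta]) -> list[SampleMeta]:
    """Check the invariants of a sample sheet and return it as a list."""
    meta = list(meta)
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s): {dupes}")
    seen: set[tuple[str, str]] = set()
    for m in meta:
        key = (m.pair_key, m.group)
        if key in seen:
            raise ValueError(
                f"pair_key {m.pair_key!r} appears more than once in group "
                f"{m.group!r}"
            )
        seen.add(key)
    return meta


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = _read_tsv(path, required=("sample_id", "patient_id", "group", "pair_key"))
    meta = [
        SampleMeta(
            sample_id=str(r.sample_id),
            patient_id=str(r.patient_id),
            group=str(r.group),
            pair_key=str(r.pair_key),
        )
        for r in df.itertuples(index=False)
    ]
    return validate_sample_meta(meta)


def write_sample_meta(meta: Iterable[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [(m.sample_id, m.patient_id, m.group, m.pair_key) for m in meta],
        columns=["sample_id", "patient_id", "group", "pair_key"],
    ).to_csv(path, sep="\t", index=False)


def group_samples(meta: Iterable[SampleMeta]) -> dict[str, list[str]]:
    """Sample ids per group, in sheet order."""
    out: dict[str, list[str]] = {g: [] for g in _VALID_GROUPS}
    for m in meta:
        out[m.group].append(m.sample_id)
    return out


# ---------------------------------------------------------------------------
# FASTA


def _accession_from_header(header: str) -> str:
    """First token of the header; UniProt pipe format yields the accession.

    ``sp|P04406|G3P_HUMAN`` -> ``P04406``; any other header falls back to the
    full first whitespace-delimited token.
    """
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return token


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = _accession_from_header(rec.description or rec.id)
        if acc in seen:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        seen.add(acc)
        records.append(ProteinRecord(accession=acc, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Peptide quantification tables


def _read_tsv(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", na_values=list(_NA_STRINGS), keep_default_na=True
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def read_peptide_table(path: str | Path, dialect: str = "long") -> pd.DataFrame:
    """Read a peptide quantification table into long form.

    Dialects
    --------
    ``long``
        Columns ``peptide, protein, sample, L, H`` (intensities) or
        ``peptide, protein, sample, ratio`` (precomputed L/H).
    ``wide``
        Columns ``peptide, protein`` followed by one ratio column per sample
        (FragPipe/IonQuant style).

    Returns a DataFrame with columns ``peptide, protein, sample_id, ratio_lh``
    where ``protein`` holds the primary (razor) accession string, possibly
    semicolon-separated when the search assigned several.
    """
    if dialect == "long":
        df = _read_tsv(path, required=("peptide", "protein", "sample"))
        if "ratio" in df.columns:
            ratio = pd.to_numeric(df["ratio"], errors="coerce")
        elif {"L", "H"}.issubset(df.columns):
            light = pd.to_numeric(df["L"], errors="coerce").replace(0, np.nan)
            heavy = pd.to_numeric(df["H"], errors="coerce").replace(0, np.nan)
            n_zero_h = int((pd.to_numeric(df["H"], errors="coerce") == 0).sum())
            if n_zero_h:
                warnings.warn(
                    f"{n_zero_h} row(s) with H = 0; ratio treated as missing"
                )
            ratio = light / heavy
        else:
            raise ValueError(
                f"{path}: long dialect needs either a 'ratio' column or both "
                "'L' and 'H'"
            )
        bad = ratio <= 0
        if bad.any():
            warnings.warn(f"{int(bad.sum())} non-positive ratio(s) set to missing")
            ratio = ratio.mask(bad)
        out = pd.DataFrame(
            {
                "peptide": df["peptide"].astype(str),
                "protein": df["protein"].astype(str),
                "sample_id": df["sample"].astype(str),
                "ratio_lh": ratio,
            }
        )
        return out.dropna(subset=["ratio_lh"]).reset_index(drop=True)

    if dialect == "wide":
        df = _read_tsv(path, required=("peptide", "protein"))
        sample_cols = [c for c in df.columns if c not in ("peptide", "protein")]
        if not sample_cols:
            raise ValueError(f"{path}: wide dialect has no sample columns")
        long = df.melt(
            id_vars=["peptide", "protein"],
            value_vars=sample_cols,
            var_name="sample_id",
            value_name="ratio_lh",
        )
        long["ratio_lh"] = pd.to_numeric(long["ratio_lh"], errors="coerce")
        long = long.dropna(subset=["ratio_lh"])
        bad = long["ratio_lh"] <= 0
        if bad.any():
            warnings.warn(f"{int(bad.sum())} non-positive ratio(s) set to missing")
            long = long[~bad]
        long["peptide"] = long["peptide"].astype(str)
        long["protein"] = long["protein"].astype(str)
        return long.reset_index(drop=True)

    raise ValueError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")


def write_peptide_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a long-form peptide table (columns as produced by the reader)."""
    cols = ["peptide", "protein", "sample_id", "ratio_lh"]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def read_long_peptide_table(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for tables written by :func:`write_peptide_table`."""
    df = _read_tsv(path, required=("peptide", "protein", "sample_id", "ratio_lh"))
    df["ratio_lh"] = pd.to_numeric(df["ratio_lh"], errors="coerce")
    return df.dropna(subset=["ratio_lh"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# LFQ matrices


def read_lfq_table(path: str | Path, log_scale: bool = False) -> pd.DataFrame:
    """Read a protein x sample LFQ matrix (first column = protein id).

    With ``log_scale=False`` (the default) values are raw intensities: zeros
    become missing and the matrix is log2-transformed.  With
    ``log_scale=True`` values are taken as already log-scale.
    """
    df = pd.read_csv(path, sep="\t", na_values=list(_NA_STRINGS), index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")
    if not log_scale:
        df = df.mask(df <= 0)
        df = np.log2(df)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=list(_NA_STRINGS), index_col=0)
    return df.apply(pd.to_numeric, errors="coerce")


# ---------------------------------------------------------------------------
# PSM tables

_MOD_RE = re.compile(r"(\d+)([A-Z])\(([-+]?\d+(?:\.\d+)?)\)")


def parse_assigned_mods(text: str | float | None) -> list[tuple[int, str, float]]:
    """Parse an assigned-modification string like ``"5R(54.0106), 12C(125.0477)"``.

    Returns a list of (1-based peptide position, residue, delta mass in Da).
    """
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return []
    return [
        (int(pos), res, float(mass)) for pos, res, mass in _MOD_RE.findall(str(text))
    ]


def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read a PSM table with columns ``psm_id, peptide, sample, assigned_mods``.

    An optional ``delta_mass`` column (open-search mass shift, Da) is carried
    through.  The returned frame adds a ``mods`` column holding parsed
    (position, residue, delta) triples.
    """
    df = _read_tsv(path, required=("psm_id", "peptide", "sample"))
    out = pd.DataFrame(
        {
            "psm_id": df["psm_id"].astype(str),
            "peptide": df["peptide"].astype(str),
            "sample_id": df["sample"].astype(str),
        }
    )
    mods_col = df["assigned_mods"] if "assigned_mods" in df.columns else None
    out["mods"] = (
        mods_col.map(parse_assigned_mods)
        if mods_col is not None
        else [[] for _ in range(len(df))]
    )
    if "delta_mass" in df.columns:
        out["delta_mass"] = pd.to_numeric(df["delta_mass"], errors="coerce")
    return out


def write_psm_table(df: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "psm_id": df["psm_id"],
            "peptide": df["peptide"],
            "sample": df["sample_id"],
            "assigned_mods": df["mods"].map(
                lambda mods: ", ".join(f"{p}{r}({m:.4f})" for p, r, m in mods)
            ),
        }
    )
    if "delta_mass" in df.columns:
        out["delta_mass"] = df["delta_mass"]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Thiol (MRM) tables

_THIOL_COLS = ("analyte", "sample", "peak_area", "is_area", "protein_mg")


def read_thiol_table(path: str | Path) -> pd.DataFrame:
    """Read MRM thiol measurements.

    Required columns: analyte, sample, peak_area (a.u.), is_area (internal
    standard peak area, a.u.), protein_mg (tissue protein content, mg).
    """
    df = _read_tsv(path, required=_THIOL_COLS)
    out = pd.DataFrame(
        {
            "analyte": df["analyte"].astype(str),
            "sample_id": df["sample"].astype(str),
            "peak_area": pd.to_numeric(df["peak_area"], errors="coerce"),
            "is_area": pd.to_numeric(df["is_area"], errors="coerce"),
            "protein_mg": pd.to_numeric(df["protein_mg"], errors="coerce"),
        }
    )
    if (out["is_area"] <= 0).any() or (out["protein_mg"] <= 0).any():
        raise ValueError(f"{path}: is_area and protein_mg must be positive")
    return out


def write_thiol_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.rename(columns={"sample_id": "sample"})
    out.to_csv(
        path,
        sep="\t",
        index=False,
        columns=["analyte", "sample", "peak_area", "is_area", "protein_mg"],
    )
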