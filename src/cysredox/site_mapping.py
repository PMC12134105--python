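"""Peptide-to-site mapping and median aggregation of cysteine redox ratios.

Each quantified cysteine-containing peptide is located in its protein
sequence, its cysteines are assigned 1-based residue coordinates (the usual
Cys^139-style site notation), and the peptide-level L/H ratios of all
peptides covering the same cysteine are collapsed to one per-site per-sample
median.  The resulting site x sample matrix is the unit of all downstream
redox statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .io_formats import ProteinRecord, SampleMeta, read_matrix, write_matrix

__all__ = [
    "CysSite",
    "SiteRatioMatrix",
    "locate_cysteines",
    "aggregate_site_ratios",
    "site_report",
    "write_site_report",
    "read_site_report",
]


@dataclass(frozen=True)
class CysSite:
    """One cysteine residue in one protein, 1-based coordinate."""

    accession: str
    residue_index: int

    @property
    def site_id(self) -> str:
        return f"{self.accession}_C{self.residue_index}"


@dataclass
class SiteRatioMatrix:
    """Cysteine sites x samples matrix of median Cys_red/Cys_ox (L/H) ratios.

    ``values`` is indexed by site_id; ``support`` counts the peptides behind
    each cell; ``site_index`` maps site_id to (accession, residue_index).
    ``n_skipped`` counts peptide observations dropped for unresolvable
    accessions.
    """

    values: pd.DataFrame
    support: pd.DataFrame
    site_index: pd.DataFrame
    n_skipped: int = 0
    multi_protein_peptides: int = field(default=0)

    def __post_init__(self) -> None:
        with_value = self.values.notna()
        if ((self.values <= 0) & with_value).any().any():
            raise ValueError("site ratios must be positive where present")
        if (self.support[with_value].fillna(1) < 1).any().any():
            raise ValueError("support must be >= 1 wherever a value exists")


def locate_cysteines(peptide: str, protein: ProteinRecord) -> list[CysSite]:
    """Residue coordinates of every cysteine of ``peptide`` within ``protein``.

    Uses the first occurrence when the peptide matches at several positions
    (an ambiguity warning is emitted).  A peptide without cysteine yields an
    empty list; a peptide absent from the protein is an error.
    """
    start = protein.sequence.find(peptide)
    if start < 0:
        raise ValueError(
            f"peptide {peptide!r} not found in protein {protein.accession!r}"
        )
    if protein.sequence.find(peptide, start + 1) >= 0:
        warnings.warn(
            f"peptide {peptide!r} occurs more than once in "
            f"{protein.accession!r}; using first occurrence"
        )
    return [
        CysSite(protein.accession, start + offset + 1)
        for offset, residue in enumerate(peptide)
        if residue == "C"
    ]


def _primary_accession(protein_field: str) -> str:
    # FragPipe-style multi-protein assignments are semicolon separated with
    # the razor protein listed first.
    return protein_field.split(";")[0].strip()


def aggregate_site_ratios(
    peptides: pd.DataFrame,
    proteins: Iterable[ProteinRecord],
    meta: Iterable[SampleMeta],
    policy: Literal["share", "drop_multi"] = "share",
    protein_policy: Literal["razor", "all"] = "razor",
) -> SiteRatioMatrix:
    """Collapse peptide-level L/H ratios to per-site per-sample medians.

    ``peptides`` is a long table (peptide, protein, sample_id, ratio_lh).
    Under ``policy="share"`` a peptide carrying several cysteines contributes
    its single ratio to every contained site; ``policy="drop_multi"`` keeps
    only single-cysteine peptides.  ``protein_policy`` controls whether a
    multi-protein assignment maps to the first (razor) accession only or is
    duplicated to all listed accessions.
    """
    by_acc = {p.accession: p for p in proteins}
    meta = list(meta)
    sample_ids = [m.sample_id for m in meta]

    n_skipped = 0
    n_multi_protein = 0
    rows: list[tuple[str, str, int, str, float]] = []
    # cache site lookups per (peptide, accession)
    site_cache: dict[tuple[str, str], list[CysSite] | None] = {}

    for peptide, protein_field, sample_id, ratio in peptides[
        ["peptide", "protein", "sample_id", "ratio_lh"]
    ].itertuples(index=False):
        if protein_policy == "all":
            accessions = [a.strip() for a in str(protein_field).split(";")]
        else:
            accessions = [_primary_accession(str(protein_field))]
        if len(str(protein_field).split(";")) > 1:
            n_multi_protein += 1
        for acc in accessions:
            key = (peptide, acc)
            if key not in site_cache:
                protein = by_acc.get(acc)
                if protein is None or protein.sequence.find(peptide) < 0:
                    site_cache[key] = None
                else:
                    site_cache[key] = locate_cysteines(peptide, protein)
            sites = site_cache[key]
            if sites is None:
                n_skipped += 1
                continue
            if policy == "drop_multi" and len(sites) > 1:
                continue
            for site in sites:
                rows.append(
                    (site.accession, site.site_id, site.residue_index, sample_id, ratio)
                )

    if n_skipped:
        warnings.warn(
            f"{n_skipped} peptide observation(s) skipped: accession not in "
            "FASTA or peptide not found in sequence"
        )

    if not rows:
        empty = pd.DataFrame(index=pd.Index([], name="site_id"), columns=sample_ids)
        return SiteRatioMatrix(
            values=empty.astype(float),
            support=empty.astype(float),
            site_index=pd.DataFrame(columns=["accession", "residue_index"]),
            n_skipped=n_skipped,
            multi_protein_peptides=n_multi_protein,
        )

    long = pd.DataFrame(
        rows, columns=["accession", "site_id", "residue_index", "sample_id", "ratio"]
    )
    grouped = long.groupby(["site_id", "sample_id"])["ratio"]
    values = grouped.median().unstack("sample_id")
    support = grouped.size().unstack("sample_id")
    values = values.reindex(columns=sample_ids).rename_axis(
        index="site_id", columns=None
    )
    support = support.reindex(columns=sample_ids).rename_axis(
        index="site_id", columns=None
    )

    site_index = (
        long[["site_id", "accession", "residue_index"]]
        .drop_duplicates("site_id")
        .set_index("site_id")
        .loc[values.index]
    )
    return SiteRatioMatrix(
        values=values,
        support=support,
        site_index=site_index,
        n_skipped=n_skipped,
        multi_protein_peptides=n_multi_protein,
    )


def site_report(matrix: SiteRatioMatrix) -> pd.DataFrame:
    """Flat per-site table: coordinates, per-sample medians, support counts."""
    report = matrix.site_index.join(matrix.values)
    support = matrix.support.add_prefix("n_peptides_")
    return report.join(support)


def write_site_report(matrix: SiteRatioMatrix, path: str | Path) -> None:
    site_report(matrix).to_csv(path, sep="\t", index_label="site_id")


def read_site_report(path: str | Path) -> SiteRatioMatrix:
    df = pd.read_csv(path, sep="\t", index_col="site_id")
    support_cols = [c for c in df.columns if c.startswith("n_peptides_")]
    sample_cols = [
        c for c in df.columns if c not in support_cols + ["accession", "residue_index"]
    ]
    values = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    support = df[support_cols].apply(pd.to_numeric, errors="coerce")
    support.columns = [c[len("n_peptides_"):] for c in support_cols]
    return SiteRatioMatrix(
        values=values,
        support=support,
        site_index=df[["accession", "residue_index"]],
    )


def check_sites_against_fasta(
    matrix: SiteRatioMatrix, proteins: Iterable[ProteinRecord]
) -> None:
    """Assert that every emitted site has 'C' at its coordinate."""
    by_acc = {p.accession: p for p in proteins}
    for site_id, (acc, idx) in matrix.site_index.iterrows():
        seq = by_acc[acc].sequence
        if not (1 <= idx <= len(seq)) or seq[idx - 1] != "C":
            raise AssertionError(f"site {site_id} does not point at a cysteine")
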