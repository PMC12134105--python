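"""Direction-signed protein sets, subcellular breakdowns and over-representation.

Site-level differential results are rolled up to proteins: a protein counts as
redox-affected in a direction as soon as one of its cysteines is significant
in that direction (the any-site rule).  Because lower Cys_red/Cys_ox (L/H) in
tumor means more oxidation in tumor, a negative tumor-minus-healthy log2
difference puts the protein in the "more oxidized in tumor" set.

Over-representation uses the one-sided hypergeometric tail against a
user-supplied annotation collection (GMT), with Benjamini-Hochberg control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from scipy.stats import hypergeom

from .stats_core import bh_adjust

__all__ = [
    "SignedProteinSets",
    "AnnotationCollection",
    "build_signed_sets",
    "subcellular_breakdown",
    "hypergeom_ora",
    "read_gmt",
    "read_class_table",
    "SUBCELLULAR_CLASSES",
]

SUBCELLULAR_CLASSES = (
    "cytosolic",
    "organelle_membrane",
    "extracellular_secreted",
    "other_unknown",
)


@dataclass(frozen=True)
class SignedProteinSets:
    """Venn partition of redox-affected proteins by oxidation direction."""

    more_ox_tumor_only: frozenset[str]
    more_ox_healthy_only: frozenset[str]
    both: frozenset[str]

    def __post_init__(self) -> None:
        a, b, c = self.more_ox_tumor_only, self.more_ox_healthy_only, self.both
        if a & b or a & c or b & c:
            raise ValueError("signed protein sets must be pairwise disjoint")

    @property
    def union(self) -> frozenset[str]:
        return self.more_ox_tumor_only | self.more_ox_healthy_only | self.both

    def sizes(self) -> dict[str, int]:
        return {
            "more_ox_tumor_only": len(self.more_ox_tumor_only),
            "more_ox_healthy_only": len(self.more_ox_healthy_only),
            "both": len(self.both),
            "union": len(self.union),
        }


@dataclass(frozen=True)
class AnnotationCollection:
    """Named term -> member sets over a fixed accession universe."""

    terms: Mapping[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.terms.items():
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"term {term_id!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


def build_signed_sets(
    site_results: pd.DataFrame,
    site_index: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    use_q: bool = False,
) -> SignedProteinSets:
    """Roll site-level differential calls up to direction-signed protein sets.

    ``site_results`` is a per-site test table (index = site_id) with
    ``mean_diff`` and ``p_value``/``q_value`` columns; ``site_index`` maps
    site_id to protein accession.  A site with tumor-minus-healthy log2 L/H
    below zero and p (or q) < ``alpha`` marks its protein as more oxidized in
    tumor, above zero as more oxidized in healthy; proteins hit in both
    directions land in ``both``.
    """
    if isinstance(site_index, pd.Series):
        site_index = site_index.to_dict()
    stat_col = "q_value" if use_q else "p_value"
    ox_tumor: set[str] = set()
    ox_healthy: set[str] = set()
    for site_id, row in site_results.iterrows():
        p = row[stat_col]
        if pd.isna(p) or p >= alpha:
            continue
        if site_id not in site_index:
            raise ValueError(f"site {site_id!r} has no accession mapping")
        acc = site_index[site_id]
        if row["mean_diff"] < 0:
            ox_tumor.add(acc)
        elif row["mean_diff"] > 0:
            ox_healthy.add(acc)
    both = ox_tumor & ox_healthy
    return SignedProteinSets(
        more_ox_tumor_only=frozenset(ox_tumor - both),
        more_ox_healthy_only=frozenset(ox_healthy - both),
        both=frozenset(both),
    )


def subcellular_breakdown(
    sets: SignedProteinSets, classes: Mapping[str, str]
) -> pd.DataFrame:
    """Percentage of each signed set falling in each subcellular class.

    ``classes`` maps accession to one of :data:`SUBCELLULAR_CLASSES`;
    unclassified accessions count as ``other_unknown``.  Percentages are
    computed over the set size, so each row sums to 100 (within rounding)
    when ``other_unknown`` is included.
    """
    bad = {c for c in classes.values()} - set(SUBCELLULAR_CLASSES)
    if bad:
        raise ValueError(f"unknown subcellular class(es): {sorted(bad)}")
    rows = {}
    for name, members in (
        ("more_ox_tumor_only", sets.more_ox_tumor_only),
        ("more_ox_healthy_only", sets.more_ox_healthy_only),
        ("both", sets.both),
    ):
        counts = dict.fromkeys(SUBCELLULAR_CLASSES, 0)
        for acc in members:
            counts[classes.get(acc, "other_unknown")] += 1
        n = len(members)
        rows[name] = {
            cls: (100.0 * k / n if n else float("nan"))
            for cls, k in counts.items()
        } | {"n": n}
    return pd.DataFrame.from_dict(rows, orient="index")


def hypergeom_ora(
    query: set[str] | frozenset[str], annotations: AnnotationCollection
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each term.

    For a universe of size N, a term of size K and a query of size n with
    overlap k, p = P(X >= k) under sampling without replacement.  Returns one
    row per term with overlap, p, BH q, and genes(%) = 100 * k / K (the share
    of the term matched by the query).
    """
    query = set(query)
    offenders = query - annotations.universe
    if offenders:
        raise ValueError(
            f"query accessions outside the universe: {sorted(offenders)[:10]}"
        )
    n_universe = len(annotations.universe)
    n_query = len(query)
    rows = []
    for term_id, (term_name, members) in annotations.terms.items():
        k = len(query & members)
        big_k = len(members)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_query))
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "term_size": big_k,
                "overlap": k,
                "p_value": min(p, 1.0),
                "genes_pct": 100.0 * k / big_k if big_k else float("nan"),
            }
        )
    result = pd.DataFrame(rows).set_index("term_id")
    result["q_value"] = bh_adjust(result["p_value"])
    return result.sort_values("p_value")


def read_gmt(path: str | Path, universe: set[str] | None = None) -> AnnotationCollection:
    """Read a GMT file (term_id <TAB> description <TAB> member...).

    If ``universe`` is not given, it defaults to the union of all members.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            term_id, name, members = parts[0], parts[1], parts[2:]
            terms[term_id] = (name, frozenset(m for m in members if m))
    if universe is None:
        universe = set().union(*(m for _, m in terms.values())) if terms else set()
    return AnnotationCollection(terms=terms, universe=frozenset(universe))


def read_class_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (accession, subcellular class)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (accession, class)")
    acc_col, cls_col = df.columns[:2]
    return dict(zip(df[acc_col].astype(str), df[cls_col].astype(str)))
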