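"""Methylglyoxal-derived modification scoring.

Two MG-derived adducts matter here: the hydroimidazolone MG-H1 (+54.0106 Da,
on arginine) and carboxyethyl-lysine CEL (+72.0211 Da, on lysine).  The
module scores the targeted search (per-sample MG-H1 frequency as a percentage
of all PSMs, plus the at-least-10-samples matrix filter) and offers a
simplified open-search delta-mass summarizer with greedy peak binning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .io_formats import SampleMeta

__all__ = [
    "MGH1_DELTA",
    "CEL_DELTA",
    "KNOWN_DELTAS",
    "DeltaMassSpec",
    "has_mod",
    "mgh1_frequency",
    "filter_mgh1_matrix",
    "summarize_delta_masses",
]

MGH1_DELTA = 54.0106
CEL_DELTA = 72.0211
NEM_DELTA = 125.0477
D5NEM_DELTA = 130.0791
OX_MET_DELTA = 15.9949

KNOWN_DELTAS = {
    MGH1_DELTA: "MG-H1",
    CEL_DELTA: "CEL",
    NEM_DELTA: "NEM",
    D5NEM_DELTA: "d5-NEM",
    OX_MET_DELTA: "Oxidation",
}


@dataclass(frozen=True)
class DeltaMassSpec:
    """Open-search summarization parameters: a reported peak needs at least
    ``min_psm`` PSMs, bins grow greedily within ``peak_width`` Da of the
    running center, and annotation matches a known mass within
    ``precursor_tol`` Da."""

    min_psm: int = 10
    peak_width: float = 0.002
    precursor_tol: float = 0.01


def has_mod(
    mods: Iterable[tuple[int, str, float]],
    delta: float,
    residues: str = "R",
    tol: float = 0.01,
) -> bool:
    """True if any (pos, residue, mass) entry matches ``delta`` on ``residues``."""
    return any(
        res in residues and abs(mass - delta) <= tol for _, res, mass in mods
    )


def mgh1_frequency(
    psms: pd.DataFrame,
    meta: Iterable[SampleMeta],
    denominator: Literal["all", "arginine"] = "all",
    tol: float = 0.01,
) -> pd.DataFrame:
    """Per-sample MG-H1 modification frequency as a percentage of PSMs.

    A PSM counts as modified if it carries at least one +54.0106 Da adduct on
    an arginine.  The default denominator is all PSMs of the sample; the
    ``arginine`` alternative restricts it to arginine-containing PSMs.
    Samples without PSMs get a missing frequency (with a warning).
    """
    meta = list(meta)
    is_mod = psms["mods"].map(lambda m: has_mod(m, MGH1_DELTA, "R", tol))
    if denominator == "arginine":
        in_denominator = psms["peptide"].str.contains("R")
    elif denominator == "all":
        in_denominator = pd.Series(True, index=psms.index)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")

    rows = []
    by_sample_total = psms.loc[in_denominator].groupby("sample_id").size()
    by_sample_mod = (
        psms.loc[in_denominator & is_mod].groupby("sample_id").size()
    )
    group_of = {m.sample_id: m.group for m in meta}
    pair_of = {m.sample_id: m.pair_key for m in meta}
    empty = []
    for m in meta:
        total = int(by_sample_total.get(m.sample_id, 0))
        n_mod = int(by_sample_mod.get(m.sample_id, 0))
        if total == 0:
            empty.append(m.sample_id)
            freq = np.nan
        else:
            freq = 100.0 * n_mod / total
        rows.append(
            {
                "sample_id": m.sample_id,
                "group": group_of[m.sample_id],
                "pair_key": pair_of[m.sample_id],
                "n_psms": total,
                "n_modified": n_mod,
                "frequency_pct": freq,
            }
        )
    if empty:
        warnings.warn(f"sample(s) with zero PSMs: {empty}")
    return pd.DataFrame(rows).set_index("sample_id")


def filter_mgh1_matrix(
    matrix: pd.DataFrame, meta: Iterable[SampleMeta], min_count: int = 10
) -> pd.DataFrame:
    """Keep features observed in at least ``min_count`` samples of one group.

    This is the absolute-count analogue of the fraction-based valid-value
    filter, applied to MG-H1 peptide quantification matrices.
    """
    meta = list(meta)
    tumor = [m.sample_id for m in meta if m.group == "tumor"]
    healthy = [m.sample_id for m in meta if m.group == "healthy"]
    n_t = matrix[tumor].notna().sum(axis=1)
    n_h = matrix[healthy].notna().sum(axis=1)
    return matrix.loc[(n_t >= min_count) | (n_h >= min_count)]


def summarize_delta_masses(
    deltas: Iterable[float] | pd.Series,
    spec: DeltaMassSpec = DeltaMassSpec(),
) -> pd.DataFrame:
    """Greedy peak binning of open-search precursor mass shifts.

    Deltas are sorted and accumulated into a bin while each new value stays
    within ``peak_width`` Da of the running bin center (the mean of the bin so
    far); bins with fewer than ``min_psm`` PSMs are suppressed.  Each reported
    bin is annotated with the nearest known modification mass within
    ``precursor_tol`` Da, if any.
    """
    values = np.sort(np.asarray(list(deltas), dtype=float))
    values = values[~np.isnan(values)]
    bins: list[tuple[float, int]] = []
    if values.size:
        center = values[0]
        count = 1
        total = values[0]
        for v in values[1:]:
            if abs(v - center) <= spec.peak_width:
                count += 1
                total += v
                center = total / count
            else:
                bins.append((center, count))
                center, count, total = v, 1, v
        bins.append((center, count))

    rows = []
    for center, count in bins:
        if count < spec.min_psm:
            continue
        annotation = ""
        best = spec.precursor_tol
        for mass, name in KNOWN_DELTAS.items():
            if abs(center - mass) <= best:
                best = abs(center - mass)
                annotation = name
        rows.append(
            {"center_mass": center, "psm_count": count, "annotation": annotation}
        )
    return pd.DataFrame(rows, columns=["center_mass", "psm_count", "annotation"])
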