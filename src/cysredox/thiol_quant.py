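"""Small-molecule thiol quantification from MRM peak areas.

Analytes are differential-alkylation pairs: the NEM adduct of a thiol marks
the form that was reduced in the tissue, the d5-NEM adduct the form that was
oxidized (alkylated only after TCEP reduction).  Every peak area is
normalized to the stable-isotope internal standard (13C,15N-GSH-d5-NEM) of
the same run and to the tissue protein content, giving relative abundances in
IS-ratio units per mg protein.  Derived panel values: total glutathione =
GSH + GSSG, and reduced + oxidized sums for the glutathione precursors and
degradation products (Cys, HCys, GluCys, CysGly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import SampleMeta

__all__ = [
    "Transition",
    "ANALYTE_REGISTRY",
    "normalize_thiol",
    "normalize_table",
    "biological_sums",
    "tumor_healthy_ratio",
]


@dataclass(frozen=True)
class Transition:
    parent_mz: float
    product_mz: float
    dwell_ms: float
    collision_energy: float


@dataclass(frozen=True)
class AnalyteEntry:
    role: str  # reduced | oxidized | disulfide | intermediate | internal_standard
    transitions: tuple[Transition, ...]

    @property
    def quantifier(self) -> Transition:
        # first listed transition quantifies; the rest are qualifiers
        return self.transitions[0]


def _entry(role: str, *transitions: tuple[float, float, float, float]) -> AnalyteEntry:
    return AnalyteEntry(role, tuple(Transition(*t) for t in transitions))


# MRM transition registry (parent m/z, product m/z, dwell ms, CE in V).
ANALYTE_REGISTRY: dict[str, AnalyteEntry] = {
    "GSH": _entry("reduced", (308.0, 179.0, 65.0, -19.0)),
    "GSSG": _entry("disulfide", (613.0, 355.0, 65.6, -20.0)),
    "GSH-NEM": _entry(
        "reduced", (433.0, 304.0, 65.6, -17.0), (433.0, 201.0, 65.6, -21.0)
    ),
    "GSH-d5NEM": _entry(
        "oxidized", (438.0, 309.0, 65.6, -17.0), (438.0, 206.0, 65.6, -21.0)
    ),
    "IS": _entry(
        "internal_standard",
        (441.0, 312.0, 100.0, -17.0),
        (441.0, 206.0, 100.0, -21.0),
    ),
    "sLG": _entry(
        "intermediate",
        (380.0, 223.05, 100.0, -18.0),
        (380.0, 148.1, 100.0, -22.0),
        (380.0, 76.05, 100.0, -37.0),
    ),
    "CysGly-NEM": _entry(
        "reduced", (304.0, 287.0, 65.6, -14.0), (304.0, 201.0, 65.6, -15.0)
    ),
    "CysGly-d5NEM": _entry(
        "oxidized", (309.0, 292.0, 65.6, -14.0), (309.0, 206.0, 65.6, -15.0)
    ),
    "Cys-NEM": _entry(
        "reduced", (247.11, 230.05, 65.6, -14.0), (247.11, 201.05, 65.6, -13.0)
    ),
    "Cys-d5NEM": _entry(
        "oxidized", (252.11, 235.05, 65.6, -14.0), (252.11, 206.05, 65.6, -13.0)
    ),
    "GluCys-NEM": _entry(
        "reduced", (376.0, 247.0, 65.6, -15.0), (376.0, 201.1, 65.6, -20.0)
    ),
    "GluCys-d5NEM": _entry(
        "oxidized", (381.0, 252.05, 65.6, -15.0), (381.0, 206.1, 65.6, -20.0)
    ),
    "HCys-NEM": _entry(
        "reduced", (261.0, 56.05, 65.6, -16.0), (261.0, 215.05, 65.6, -12.0)
    ),
    "HCys-d5NEM": _entry(
        "oxidized", (266.0, 56.05, 65.6, -16.0), (266.0, 222.05, 65.6, -12.0)
    ),
}

# redox pairs behind the "sum of oxidized and reduced forms" panel entries
REDOX_PAIRS = {
    "Cys_total": ("Cys-NEM", "Cys-d5NEM"),
    "HCys_total": ("HCys-NEM", "HCys-d5NEM"),
    "GluCys_total": ("GluCys-NEM", "GluCys-d5NEM"),
    "CysGly_total": ("CysGly-NEM", "CysGly-d5NEM"),
}


def normalize_thiol(peak_area: float, is_area: float, protein_mg: float) -> float:
    """(peak_area / internal-standard area) / protein content [mg]."""
    if not is_area > 0:
        raise ValueError(f"internal-standard area must be > 0, got {is_area}")
    if not protein_mg > 0:
        raise ValueError(f"protein content must be > 0, got {protein_mg}")
    if peak_area < 0:
        raise ValueError(f"peak area must be >= 0, got {peak_area}")
    return (peak_area / is_area) / protein_mg


def normalize_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Normalize a long thiol table and pivot to samples x analytes.

    Input columns: analyte, sample_id, peak_area, is_area, protein_mg.
    """
    if (measurements["is_area"] <= 0).any() or (
        measurements["protein_mg"] <= 0
    ).any():
        raise ValueError("is_area and protein_mg must be positive")
    if (measurements["peak_area"] < 0).any():
        raise ValueError("peak areas must be non-negative")
    norm = (
        measurements["peak_area"]
        / measurements["is_area"]
        / measurements["protein_mg"]
    )
    long = measurements[["sample_id", "analyte"]].assign(value=norm)
    return long.pivot_table(
        index="sample_id", columns="analyte", values="value", aggfunc="mean"
    )


def biological_sums(values: pd.DataFrame) -> pd.DataFrame:
    """Derived thiol panel per sample.

    ``values`` is samples x analytes (normalized abundances).  Adds
    total_glutathione = GSH + GSSG (GSSG counted once, not as two glutathione
    equivalents) and reduced+oxidized totals for each precursor/degradation
    pair; the underlying single analytes are carried through so redox pairs
    can be inspected alongside the sums.  A missing constituent leaves the
    derived value missing, with a warning.
    """
    panel = values.copy()
    derived: dict[str, tuple[str, str]] = {
        "total_glutathione": ("GSH", "GSSG"),
        **REDOX_PAIRS,
    }
    missing_terms = []
    for name, (a, b) in derived.items():
        if a in values.columns and b in values.columns:
            panel[name] = values[a] + values[b]
        else:
            panel[name] = np.nan
            missing_terms.append(name)
    if missing_terms:
        warnings.warn(
            f"constituents missing for derived value(s): {missing_terms}"
        )
    return panel


def tumor_healthy_ratio(
    panel: pd.DataFrame,
    meta: Iterable[SampleMeta],
    log2: bool = False,
) -> pd.DataFrame:
    """Per-patient tumor/healthy ratio for every panel column.

    ``panel`` is samples x analytes.  Pairs are matched via ``pair_key``; a
    missing member or a zero healthy value leaves the ratio missing (the
    latter with a warning).  With ``log2=True`` the ratios are returned on a
    log2 scale.
    """
    meta = list(meta)
    tumor_by_pair = {m.pair_key: m.sample_id for m in meta if m.group == "tumor"}
    healthy_by_pair = {m.pair_key: m.sample_id for m in meta if m.group == "healthy"}
    pairs = sorted(k for k in tumor_by_pair if k in healthy_by_pair)
    rows = {}
    n_zero_healthy = 0
    for pair in pairs:
        t_id, h_id = tumor_by_pair[pair], healthy_by_pair[pair]
        if t_id not in panel.index or h_id not in panel.index:
            rows[pair] = pd.Series(np.nan, index=panel.columns)
            continue
        t = panel.loc[t_id]
        h = panel.loc[h_id]
        zero_h = (h == 0) & t.notna()
        n_zero_healthy += int(zero_h.sum())
        ratio = t / h.mask(h == 0)
        rows[pair] = ratio
    if n_zero_healthy:
        warnings.warn(
            f"{n_zero_healthy} ratio(s) undefined due to zero healthy value"
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "pair_key"
    if log2:
        out = np.log2(out.mask(out <= 0))
    return out
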