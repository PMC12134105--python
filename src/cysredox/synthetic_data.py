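"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a paired tumor/healthy tissue cohort
measured by differential-alkylation redox proteomics, label-free protein
quantification, PSM-level modification searches and MRM thiol panels:

* a paired two-group design (one tumor and one healthy piece per patient);
* per-site ground-truth oxidation effects, sparse, on the log2 L/H scale
  (more oxidation = lower Cys_red/Cys_ox ratio);
* multiplicative lognormal measurement noise;
* intensity-dependent (left-censored, MNAR) or completely random missingness;
* group-dependent per-PSM modification rates;
* per-analyte fold changes for the thiol panel.

Every generator is a pure function of its specification objects (the seed is
part of the spec), so outputs are byte-reproducible.  Each generated table
comes with a truth table that joins losslessly on feature/sample keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_formats import ProteinRecord, SampleMeta, validate_sample_meta

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "NoiseSpec",
    "make_meta",
    "tryptic_digest",
    "generate_proteome",
    "generate_redox_experiment",
    "generate_lfq_experiment",
    "generate_psm_table",
    "generate_thiol_table",
    "default_cohort_specs",
]

# residue frequencies loosely following the human proteome; cysteine density
# is set separately so site coverage is controllable
_RESIDUES = "ADEFGHIKLMNPQRSTVWY"
_RESIDUE_FREQS = np.array(
    [8.3, 5.4, 6.8, 3.9, 7.1, 2.6, 5.9, 5.5, 9.7, 2.4, 4.0, 6.3, 4.4, 5.7, 6.6, 8.1, 5.3, 1.2, 2.9]
)
_RESIDUE_FREQS = _RESIDUE_FREQS / _RESIDUE_FREQS.sum()


@dataclass(frozen=True)
class CohortSpec:
    """Cohort geometry: 70 patient pairs by default, desk-scale proteome."""

    n_pairs: int = 70
    n_proteins: int = 120
    mean_protein_length: int = 360
    cys_density: float = 0.022
    max_missed_cleavages: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")


@dataclass(frozen=True)
class EffectSpec:
    """Planted effects.

    Redox: disjoint site fractions pushed toward oxidation in tumor
    (log2 L/H shifted down by ``log2_ratio_shift``) or in healthy tissue
    (tumor log2 L/H shifted up).  LFQ: a fraction of proteins differentially
    abundant with random sign.  MG-H1: per-PSM modification probabilities per
    group (healthy > tumor by default, matching the observed direction).
    Thiols: multiplicative tumor/healthy fold change per analyte, defaults in
    the directions seen in tissue (glutathione species and precursors up in
    tumor, sLG down).
    """

    frac_sites_oxidized_in_tumor: float = 0.05
    frac_sites_oxidized_in_healthy: float = 0.05
    log2_ratio_shift: float = 1.0
    lfq_frac_de: float = 0.10
    lfq_log2fc: float = 1.0
    mgh1_rate_tumor: float = 0.01
    mgh1_rate_healthy: float = 0.03
    thiol_fold_changes: dict[str, float] = field(
        default_factory=lambda: {
            "GSH": 2.0,
            "GSSG": 2.0,
            "GSH-NEM": 2.0,
            "GSH-d5NEM": 2.0,
            "Cys-NEM": 1.5,
            "Cys-d5NEM": 1.5,
            "HCys-NEM": 1.5,
            "HCys-d5NEM": 1.5,
            "GluCys-NEM": 1.5,
            "GluCys-d5NEM": 1.5,
            "CysGly-NEM": 1.5,
            "CysGly-d5NEM": 1.5,
            "sLG": 0.6,
        }
    )

    def __post_init__(self) -> None:
        for name in (
            "frac_sites_oxidized_in_tumor",
            "frac_sites_oxidized_in_healthy",
            "mgh1_rate_tumor",
            "mgh1_rate_healthy",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement noise and missingness.

    ``sigma_log2_ratio``/``sigma_log2_lfq`` are lognormal noise SDs on the
    log2 scale.  ``missingness`` is ``MCAR`` (uniform at ``missing_rate``) or
    ``MNAR_intensity`` (logistic in a latent log-intensity, centered at the
    ``missing_rate`` quantile — the left-censored pattern that motivates
    downshifted-normal imputation)."""

    sigma_log2_ratio: float = 0.5
    sigma_log2_lfq: float = 0.5
    missingness: str = "MNAR_intensity"
    missing_rate: float = 0.2
    mnar_steepness: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma_log2_ratio <= 0 or self.sigma_log2_lfq <= 0:
            raise ValueError("noise sigmas must be > 0")
        if self.missingness not in ("MCAR", "MNAR_intensity"):
            raise ValueError(f"unknown missingness {self.missingness!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def make_meta(n_pairs: int) -> list[SampleMeta]:
    """Paired sample sheet: patient P001..P<n>, one tumor + one healthy each."""
    meta = []
    for i in range(1, n_pairs + 1):
        patient = f"P{i:03d}"
        for group, suffix in (("tumor", "T"), ("healthy", "H")):
            meta.append(
                SampleMeta(
                    sample_id=f"{patient}_{suffix}",
                    patient_id=patient,
                    group=group,
                    pair_key=patient,
                )
            )
    return validate_sample_meta(meta)


# ---------------------------------------------------------------------------
# Proteome


def tryptic_digest(
    sequence: str,
    max_missed_cleavages: int = 2,
    min_length: int = 6,
    max_length: int = 30,
) -> list[tuple[int, str]]:
    """In-silico tryptic peptides: cut after K/R except before P.

    Returns (0-based start, peptide) for fragments with up to
    ``max_missed_cleavages`` missed cleavages within the length window.
    """
    cut_after = [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    boundaries = [0] + [i + 1 for i in cut_after] + [len(sequence)]
    peptides = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + max_missed_cleavages, len(boundaries))):
            start, end = boundaries[i], boundaries[j]
            if min_length <= end - start <= max_length:
                peptides.append((start, sequence[start:end]))
    return peptides


def _random_sequence(rng: np.random.Generator, length: int, cys_density: float) -> str:
    base = rng.choice(list(_RESIDUES), size=length, p=_RESIDUE_FREQS)
    is_cys = rng.random(length) < cys_density
    base[is_cys] = "C"
    return "".join(base)


def generate_proteome(
    spec: CohortSpec,
) -> tuple[list[ProteinRecord], pd.DataFrame, pd.DataFrame]:
    """Random protein sequences plus a cysteine-site and peptide catalog.

    Returns ``(proteins, site_catalog, peptide_catalog)``.  The site catalog
    lists every cysteine covered by at least one tryptic peptide
    (columns: site_id, accession, residue_index); the peptide catalog lists
    the covering peptides with their site assignments (semicolon-joined
    site_ids per peptide).
    """
    rng = np.random.default_rng(spec.seed)
    proteins: list[ProteinRecord] = []
    site_rows = []
    peptide_rows = []
    for k in range(spec.n_proteins):
        acc = f"SYN{k:04d}"
        length = int(rng.normal(spec.mean_protein_length, spec.mean_protein_length / 4))
        length = max(length, 60)
        seq = _random_sequence(rng, length, spec.cys_density)
        proteins.append(ProteinRecord(accession=acc, sequence=seq))
        covered: set[int] = set()
        for start, peptide in tryptic_digest(seq, spec.max_missed_cleavages):
            cys_positions = [
                start + offset + 1
                for offset, r in enumerate(peptide)
                if r == "C"
            ]
            if not cys_positions:
                continue
            # peptides occurring more than once in the protein are ambiguous
            if seq.find(peptide) != start or seq.find(peptide, start + 1) >= 0:
                continue
            covered.update(cys_positions)
            peptide_rows.append(
                {
                    "peptide": peptide,
                    "accession": acc,
                    "site_ids": ";".join(f"{acc}_C{p}" for p in cys_positions),
                }
            )
        for pos in sorted(covered):
            site_rows.append(
                {"site_id": f"{acc}_C{pos}", "accession": acc, "residue_index": pos}
            )
    site_catalog = pd.DataFrame(site_rows, columns=["site_id", "accession", "residue_index"])
    peptide_catalog = pd.DataFrame(
        peptide_rows, columns=["peptide", "accession", "site_ids"]
    ).drop_duplicates(subset=["peptide", "accession"])
    return proteins, site_catalog, peptide_catalog


# ---------------------------------------------------------------------------
# Redox experiment


def _missing_mask(
    rng: np.random.Generator, shape: tuple[int, int], noise: NoiseSpec
) -> np.ndarray:
    """Boolean mask of cells to drop, MCAR or logistic-in-intensity MNAR."""
    if noise.missing_rate == 0:
        return np.zeros(shape, dtype=bool)
    if noise.missingness == "MCAR":
        return rng.random(shape) < noise.missing_rate
    # latent log-intensity: a per-feature abundance plus per-cell scatter
    latent = rng.normal(size=(shape[0], 1)) + 0.5 * rng.normal(size=shape)
    threshold = np.quantile(latent, noise.missing_rate)
    p_miss = expit(noise.mnar_steepness * (threshold - latent))
    return rng.random(shape) < p_miss


def generate_redox_experiment(
    cohort: CohortSpec,
    effects: EffectSpec,
    noise: NoiseSpec,
    proteome: tuple[list[ProteinRecord], pd.DataFrame, pd.DataFrame] | None = None,
) -> dict:
    """Simulate a peptide-level L/H quantification table with site truth.

    Per site s and group g the true log2 ratio is mu_sg: 0 at baseline,
    ``-log2_ratio_shift`` in tumor for tumor-oxidized sites and in healthy
    for healthy-oxidized sites (disjoint site subsets).  Each covering
    peptide in each sample observes ``2**(mu_sg + eps)`` with
    eps ~ Normal(0, sigma_log2_ratio^2); a multi-cysteine peptide reports the
    mean mu of its sites.  Missingness per the noise spec.

    Returns a dict with keys ``peptides`` (long table), ``truth`` (per-site
    mu_tumor, mu_healthy, true_log2_diff), ``meta``, ``proteins``,
    ``site_catalog``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cohort.seed, 1]))
    if proteome is None:
        proteome = generate_proteome(cohort)
    proteins, site_catalog, peptide_catalog = proteome
    meta = make_meta(cohort.n_pairs)
    n_sites = len(site_catalog)

    u = rng.random(n_sites)
    ox_tumor = u < effects.frac_sites_oxidized_in_tumor
    ox_healthy = (~ox_tumor) & (
        u < effects.frac_sites_oxidized_in_tumor + effects.frac_sites_oxidized_in_healthy
    )
    mu_tumor = np.where(ox_tumor, -effects.log2_ratio_shift, 0.0)
    mu_healthy = np.where(ox_healthy, -effects.log2_ratio_shift, 0.0)
    truth = pd.DataFrame(
        {
            "site_id": site_catalog["site_id"],
            "mu_tumor": mu_tumor,
            "mu_healthy": mu_healthy,
            "true_log2_diff": mu_tumor - mu_healthy,
        }
    ).set_index("site_id")

    mu_by_site = dict(zip(site_catalog["site_id"], zip(mu_tumor, mu_healthy)))
    pep_mu_tumor = np.empty(len(peptide_catalog))
    pep_mu_healthy = np.empty(len(peptide_catalog))
    for i, sites in enumerate(peptide_catalog["site_ids"]):
        ids = sites.split(";")
        mt, mh = zip(*(mu_by_site[s] for s in ids))
        pep_mu_tumor[i] = float(np.mean(mt))
        pep_mu_healthy[i] = float(np.mean(mh))

    sample_ids = [m.sample_id for m in meta]
    is_tumor = np.array([m.group == "tumor" for m in meta])
    n_pep = len(peptide_catalog)
    mu = np.where(is_tumor[None, :], pep_mu_tumor[:, None], pep_mu_healthy[:, None])
    eps = rng.normal(0.0, noise.sigma_log2_ratio, size=(n_pep, len(sample_ids)))
    log2_ratio = mu + eps
    missing = _missing_mask(rng, log2_ratio.shape, noise)

    pep_idx, sample_idx = np.nonzero(~missing)
    peptides = pd.DataFrame(
        {
            "peptide": peptide_catalog["peptide"].to_numpy()[pep_idx],
            "protein": peptide_catalog["accession"].to_numpy()[pep_idx],
            "sample_id": np.array(sample_ids)[sample_idx],
            "ratio_lh": np.exp2(log2_ratio[~missing]),
        }
    )
    return {
        "peptides": peptides,
        "truth": truth,
        "meta": meta,
        "proteins": proteins,
        "site_catalog": site_catalog,
    }


# ---------------------------------------------------------------------------
# LFQ experiment


def generate_lfq_experiment(
    cohort: CohortSpec, effects: EffectSpec, noise: NoiseSpec
) -> dict:
    """Simulate a protein x sample log2 LFQ matrix with per-protein truth.

    Baseline log2 abundances ~ Normal(25, 2); a ``lfq_frac_de`` fraction of
    proteins shifts by ±``lfq_log2fc`` in tumor (random sign); lognormal
    noise; left-censored missingness tied to the simulated intensity itself
    under MNAR.  Returns dict with ``matrix`` (log2 scale), ``truth``
    (per-protein log2fc), ``meta``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cohort.seed, 2]))
    meta = make_meta(cohort.n_pairs)
    sample_ids = [m.sample_id for m in meta]
    is_tumor = np.array([m.group == "tumor" for m in meta])
    n = cohort.n_proteins

    base = rng.normal(25.0, 2.0, size=n)
    is_de = rng.random(n) < effects.lfq_frac_de
    sign = rng.choice([-1.0, 1.0], size=n)
    log2fc = np.where(is_de, sign * effects.lfq_log2fc, 0.0)
    values = (
        base[:, None]
        + np.where(is_tumor[None, :], log2fc[:, None], 0.0)
        + rng.normal(0.0, noise.sigma_log2_lfq, size=(n, len(sample_ids)))
    )
    if noise.missing_rate > 0:
        if noise.missingness == "MNAR_intensity":
            z = (values - values.mean()) / values.std()
            threshold = np.quantile(z, noise.missing_rate)
            p_miss = expit(noise.mnar_steepness * (threshold - z))
            missing = rng.random(values.shape) < p_miss
        else:
            missing = rng.random(values.shape) < noise.missing_rate
        values = np.where(missing, np.nan, values)

    accessions = [f"SYN{k:04d}" for k in range(n)]
    matrix = pd.DataFrame(values, index=accessions, columns=sample_ids)
    matrix.index.name = "protein"
    truth = pd.DataFrame({"log2fc": log2fc}, index=pd.Index(accessions, name="protein"))
    return {"matrix": matrix, "truth": truth, "meta": meta}


# ---------------------------------------------------------------------------
# PSM table


def generate_psm_table(
    cohort: CohortSpec,
    effects: EffectSpec,
    n_psms_per_sample: int = 2000,
) -> dict:
    """Simulate a PSM table with group-dependent MG-H1 rates.

    Each sample contributes ``n_psms_per_sample`` PSMs; a PSM is MG-H1
    modified with the per-group probability from the effect spec (healthy >
    tumor by default).  Modified PSMs carry a +54.0106 Da adduct on an
    arginine; every PSM records an open-search ``delta_mass`` (0 for
    unmodified, the adduct mass for modified, with small mass error).

    Returns dict with ``psms``, ``truth`` (the two rates), ``meta``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cohort.seed, 3]))
    meta = make_meta(cohort.n_pairs)
    rows = []
    psm_counter = 0
    for m in meta:
        rate = (
            effects.mgh1_rate_tumor if m.group == "tumor" else effects.mgh1_rate_healthy
        )
        modified = rng.random(n_psms_per_sample) < rate
        for is_mod in modified:
            length = int(rng.integers(8, 25))
            residues = rng.choice(list(_RESIDUES), size=length, p=_RESIDUE_FREQS)
            if is_mod:
                pos = int(rng.integers(0, length - 1))
                residues[pos] = "R"
                residues[-1] = rng.choice(["K", "R"])
                peptide = "".join(residues)
                mods = [(pos + 1, "R", 54.0106)]
                delta = 54.0106 + rng.normal(0.0, 0.0004)
            else:
                residues[-1] = rng.choice(["K", "R"])
                peptide = "".join(residues)
                mods = []
                delta = rng.normal(0.0, 0.0004)
            psm_counter += 1
            rows.append(
                {
                    "psm_id": f"PSM{psm_counter:07d}",
                    "peptide": peptide,
                    "sample_id": m.sample_id,
                    "mods": mods,
                    "delta_mass": delta,
                }
            )
    psms = pd.DataFrame(rows)
    truth = {
        "mgh1_rate_tumor": effects.mgh1_rate_tumor,
        "mgh1_rate_healthy": effects.mgh1_rate_healthy,
    }
    return {"psms": psms, "truth": truth, "meta": meta}


# ---------------------------------------------------------------------------
# Thiol table

# baseline normalized abundances (IS-ratio per mg protein), arbitrary but
# ordered like a tissue panel: glutathione dominates, sLG is a trace analyte
_THIOL_BASELINES = {
    "GSH": 5.0,
    "GSSG": 1.0,
    "GSH-NEM": 4.0,
    "GSH-d5NEM": 0.8,
    "Cys-NEM": 1.2,
    "Cys-d5NEM": 0.4,
    "HCys-NEM": 0.3,
    "HCys-d5NEM": 0.1,
    "GluCys-NEM": 0.5,
    "GluCys-d5NEM": 0.15,
    "CysGly-NEM": 0.8,
    "CysGly-d5NEM": 0.25,
    "sLG": 0.2,
}


def generate_thiol_table(
    cohort: CohortSpec,
    effects: EffectSpec,
    noise: NoiseSpec,
    sigma_log2: float = 0.4,
) -> dict:
    """Simulate a long MRM thiol table (peak areas + IS + protein content).

    True normalized abundance = baseline x fold (tumor only) x lognormal
    noise; the emitted peak area re-multiplies the per-sample internal
    standard area and protein content so that normalization exactly inverts
    the construction.  Returns dict with ``measurements``, ``truth``
    (per-analyte fold change), ``meta``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cohort.seed, 4]))
    meta = make_meta(cohort.n_pairs)
    rows = []
    for m in meta:
        is_area = float(rng.lognormal(np.log(1e5), 0.1))
        protein_mg = float(rng.uniform(1.0, 3.0))
        for analyte, baseline in _THIOL_BASELINES.items():
            fold = effects.thiol_fold_changes.get(analyte, 1.0)
            value = baseline * (fold if m.group == "tumor" else 1.0)
            value *= float(np.exp2(rng.normal(0.0, sigma_log2)))
            rows.append(
                {
                    "analyte": analyte,
                    "sample_id": m.sample_id,
                    "peak_area": value * is_area * protein_mg,
                    "is_area": is_area,
                    "protein_mg": protein_mg,
                }
            )
    measurements = pd.DataFrame(rows)
    truth = pd.Series(
        {a: effects.thiol_fold_changes.get(a, 1.0) for a in _THIOL_BASELINES},
        name="fold_change",
    )
    return {"measurements": measurements, "truth": truth, "meta": meta}


def default_cohort_specs(seed: int = 0) -> tuple[CohortSpec, EffectSpec, NoiseSpec]:
    """Default desk-scale study conditions: 70 pairs, ~120 proteins,
    sparse oxidation effects, MNAR missingness."""
    return CohortSpec(seed=seed), EffectSpec(), NoiseSpec()
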