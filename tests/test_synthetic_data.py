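import numpy as np
import pandas as pd
import pytest

from cysredox import synthetic_data as sd
from cysredox.site_mapping import aggregate_site_ratios


def brute_force_tryptic(seq, max_missed, min_len=6, max_len=30):
    """Independent in-silico digestion oracle: enumerate every substring and
    keep those whose boundaries are valid tryptic termini with the allowed
    number of internal missed cleavages."""
    def is_cut(i):  # cut between i-1 and i
        return 0 < i < len(seq) and seq[i - 1] in "KR" and seq[i] != "P"

    out = set()
    for start in range(len(seq)):
        if not (start == 0 or is_cut(start)):
            continue
        for end in range(start + min_len, min(start + max_len, len(seq)) + 1):
            if not (end == len(seq) or is_cut(end)):
                continue
            missed = sum(1 for i in range(start + 1, end) if is_cut(i))
            if missed <= max_missed:
                out.add((start, seq[start:end]))
    return out


class TestProteome:
    def test_protein_count_and_site_invariant(self):
        proteins, sites, peptides = sd.generate_proteome(
            sd.CohortSpec(n_proteins=10, seed=2)
        )
        assert len(proteins) == 10
        by_acc = {p.accession: p.sequence for p in proteins}
        for _, row in sites.iterrows():
            assert by_acc[row.accession][row.residue_index - 1] == "C"

    def test_digest_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            seq = "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=rng.integers(30, 120))
            )
            got = set(sd.tryptic_digest(seq, max_missed_cleavages=2))
            assert got == brute_force_tryptic(seq, 2)

    def test_catalog_peptides_locate_uniquely(self):
        proteins, _, peptides = sd.generate_proteome(
            sd.CohortSpec(n_proteins=20, seed=3)
        )
        by_acc = {p.accession: p.sequence for p in proteins}
        for _, row in peptides.iterrows():
            seq = by_acc[row.accession]
            first = seq.find(row.peptide)
            assert first >= 0
            assert seq.find(row.peptide, first + 1) < 0


class TestRedoxExperiment:
    def test_zero_effects_zero_noise_gives_exact_unit_ratios(self):
        cohort = sd.CohortSpec(n_pairs=3, n_proteins=5, seed=4)
        effects = sd.EffectSpec(
            frac_sites_oxidized_in_tumor=0.0, frac_sites_oxidized_in_healthy=0.0
        )
        noise = sd.NoiseSpec(sigma_log2_ratio=1e-12, missing_rate=0.0)
        sim = sd.generate_redox_experiment(cohort, effects, noise)
        assert np.allclose(sim["peptides"]["ratio_lh"], 1.0)

    def test_fixed_seed_reproduces_byte_identical_tables(self):
        cohort = sd.CohortSpec(n_pairs=4, n_proteins=10, seed=5)
        a = sd.generate_redox_experiment(cohort, sd.EffectSpec(), sd.NoiseSpec())
        b = sd.generate_redox_experiment(cohort, sd.EffectSpec(), sd.NoiseSpec())
        pd.testing.assert_frame_equal(a["peptides"], b["peptides"])
        pd.testing.assert_frame_equal(a["truth"], b["truth"])

    def test_truth_joins_losslessly_to_site_catalog(self):
        sim = sd.generate_redox_experiment(
            sd.CohortSpec(n_pairs=3, n_proteins=10, seed=6),
            sd.EffectSpec(),
            sd.NoiseSpec(),
        )
        assert set(sim["truth"].index) == set(sim["site_catalog"]["site_id"])

    def test_site_estimates_correlate_with_truth(self):
        """End-to-end recovery: aggregated per-site log2 ratio differences
        track the planted oxidation shifts."""
        cohort = sd.CohortSpec(n_pairs=20, n_proteins=40, seed=7)
        effects = sd.EffectSpec(
            frac_sites_oxidized_in_tumor=0.15, frac_sites_oxidized_in_healthy=0.15
        )
        sim = sd.generate_redox_experiment(cohort, effects, sd.NoiseSpec())
        matrix = aggregate_site_ratios(sim["peptides"], sim["proteins"], sim["meta"])
        log_vals = np.log2(matrix.values)
        meta = sim["meta"]
        t_cols = [m.sample_id for m in meta if m.group == "tumor"]
        h_cols = [m.sample_id for m in meta if m.group == "healthy"]
        est = log_vals[t_cols].mean(axis=1) - log_vals[h_cols].mean(axis=1)
        truth = sim["truth"]["true_log2_diff"].reindex(est.index)
        complete = est.notna() & truth.notna()
        r = np.corrcoef(est[complete], truth[complete])[0, 1]
        assert r > 0.8


class TestLfqExperiment:
    def test_truth_fraction_and_shape(self):
        sim = sd.generate_lfq_experiment(
            sd.CohortSpec(n_pairs=10, n_proteins=200, seed=8),
            sd.EffectSpec(lfq_frac_de=0.2),
            sd.NoiseSpec(),
        )
        assert sim["matrix"].shape == (200, 20)  # 10 pairs = 20 samples
        frac_de = (sim["truth"]["log2fc"] != 0).mean()
        assert frac_de == pytest.approx(0.2, abs=0.08)

    def test_mnar_missingness_is_intensity_dependent(self):
        sim = sd.generate_lfq_experiment(
            sd.CohortSpec(n_pairs=20, n_proteins=300, seed=9),
            sd.EffectSpec(lfq_frac_de=0.0),
            sd.NoiseSpec(missing_rate=0.3, missingness="MNAR_intensity"),
        )
        mat = sim["matrix"].to_numpy()
        observed = mat[~np.isnan(mat)]
        # observed values sit above the overall simulated mean of 25
        assert np.median(observed) > 25.0


class TestPsmAndThiol:
    def test_zero_rate_gives_zero_modified(self):
        sim = sd.generate_psm_table(
            sd.CohortSpec(n_pairs=2, seed=10),
            sd.EffectSpec(mgh1_rate_tumor=0.0, mgh1_rate_healthy=0.0),
            n_psms_per_sample=200,
        )
        assert sim["psms"]["mods"].map(len).sum() == 0

    def test_modified_psms_carry_arginine_adduct(self):
        sim = sd.generate_psm_table(
            sd.CohortSpec(n_pairs=2, seed=11),
            sd.EffectSpec(mgh1_rate_tumor=0.5, mgh1_rate_healthy=0.5),
            n_psms_per_sample=100,
        )
        modified = sim["psms"][sim["psms"]["mods"].map(len) > 0]
        assert len(modified) > 0
        for _, row in modified.iterrows():
            pos, res, mass = row["mods"][0]
            assert res == "R"
            assert row["peptide"][pos - 1] == "R"
            assert mass == pytest.approx(54.0106)

    def test_thiol_table_covers_registry_analytes_for_every_sample(self):
        sim = sd.generate_thiol_table(
            sd.CohortSpec(n_pairs=3, seed=12), sd.EffectSpec(), sd.NoiseSpec()
        )
        counts = sim["measurements"].groupby("sample_id").size()
        assert (counts == 13).all()
        assert len(counts) == 6
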