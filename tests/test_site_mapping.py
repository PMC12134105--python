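import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cysredox.io_formats import ProteinRecord
from cysredox.site_mapping import (
    CysSite,
    aggregate_site_ratios,
    check_sites_against_fasta,
    locate_cysteines,
    read_site_report,
    site_report,
    write_site_report,
)
from cysredox.synthetic_data import make_meta


def brute_force_sites(peptide: str, sequence: str) -> list[int]:
    """Independent oracle: scan every protein position for the peptide and
    list cysteine coordinates of the first match."""
    for start in range(len(sequence) - len(peptide) + 1):
        if sequence[start : start + len(peptide)] == peptide:
            return [
                start + i + 1 for i, r in enumerate(peptide) if r == "C"
            ]
    raise AssertionError("peptide not in protein")


class TestLocateCysteines:
    def test_one_based_coordinates(self):
        protein = ProteinRecord("P1", "MKCACW")
        sites = locate_cysteines("KCACW", protein)
        assert [s.residue_index for s in sites] == [3, 5]
        assert sites[0].site_id == "P1_C3"

    def test_peptide_without_cysteine_yields_empty(self):
        assert locate_cysteines("MKAR", ProteinRecord("P1", "MKARW")) == []

    def test_absent_peptide_raises_naming_both(self):
        with pytest.raises(ValueError, match="CCC.*P1"):
            locate_cysteines("CCC", ProteinRecord("P1", "MKARW"))

    def test_ambiguous_peptide_uses_first_occurrence_and_warns(self):
        protein = ProteinRecord("P1", "ACKGGACKG")
        with pytest.warns(UserWarning, match="first occurrence"):
            sites = locate_cysteines("ACK", protein)
        assert [s.residue_index for s in sites] == [2]

    def test_agrees_with_exhaustive_scan_on_random_pairs(self):
        rng = np.random.default_rng(11)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(1000):
            seq = "".join(rng.choice(alphabet, size=rng.integers(20, 80)))
            start = int(rng.integers(0, len(seq) - 8))
            peptide = seq[start : start + int(rng.integers(5, 9))]
            protein = ProteinRecord("PX", seq)
            with pytest.warns((UserWarning,)) if seq.count(peptide) > 1 else _noop():
                got = [s.residue_index for s in locate_cysteines(peptide, protein)]
            assert got == brute_force_sites(peptide, seq)


class _noop:
    def __enter__(self):
        return self

    def __exit__(self, *args):
        return False


def _toy_peptides(rows):
    return pd.DataFrame(rows, columns=["peptide", "protein", "sample_id", "ratio_lh"])


class TestAggregation:
    protein = ProteinRecord("P1", "MKCAKAAACR")
    meta = make_meta(2)  # samples P001_T/H, P002_T/H

    def test_median_of_supporting_peptides(self):
        rows = [
            ("KCAK", "P1", "P001_T", 0.5),
            ("MKCAK", "P1", "P001_T", 1.0),
            ("MKCAKAAACR", "P1", "P001_T", 4.0),
        ]
        m = aggregate_site_ratios(_toy_peptides(rows), [self.protein], self.meta)
        assert m.values.loc["P1_C3", "P001_T"] == 1.0
        assert m.support.loc["P1_C3", "P001_T"] == 3

    def test_single_peptide_site_is_identity(self):
        rows = [("KCAK", "P1", "P002_H", 2.5)]
        m = aggregate_site_ratios(_toy_peptides(rows), [self.protein], self.meta)
        assert m.values.loc["P1_C3", "P002_H"] == 2.5

    def test_multi_cys_peptide_shares_ratio_under_share_policy(self):
        rows = [("MKCAKAAACR", "P1", "P001_T", 2.0)]
        m = aggregate_site_ratios(_toy_peptides(rows), [self.protein], self.meta)
        assert m.values.loc["P1_C3", "P001_T"] == 2.0
        assert m.values.loc["P1_C9", "P001_T"] == 2.0

    def test_drop_multi_policy_keeps_single_cys_peptides_only(self):
        rows = [
            ("MKCAKAAACR", "P1", "P001_T", 2.0),
            ("KCAK", "P1", "P001_T", 1.0),
        ]
        m = aggregate_site_ratios(
            _toy_peptides(rows), [self.protein], self.meta, policy="drop_multi"
        )
        assert list(m.values.index) == ["P1_C3"]
        assert m.values.loc["P1_C3", "P001_T"] == 1.0

    def test_unresolvable_accession_skipped_and_counted(self):
        rows = [("KCAK", "NOPE", "P001_T", 1.0), ("KCAK", "P1", "P001_T", 1.0)]
        with pytest.warns(UserWarning, match="skipped"):
            m = aggregate_site_ratios(_toy_peptides(rows), [self.protein], self.meta)
        assert m.n_skipped == 1
        assert m.values.shape[0] == 1

    @given(perm=st.permutations(range(4)))
    def test_median_permutation_invariant_in_peptide_order(self, perm):
        rows = [
            ("KCAK", "P1", "P001_T", r) for r in (0.5, 1.0, 2.0, 8.0)
        ]
        shuffled = [rows[i] for i in perm]
        a = aggregate_site_ratios(_toy_peptides(rows), [self.protein], self.meta)
        b = aggregate_site_ratios(_toy_peptides(shuffled), [self.protein], self.meta)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_emitted_sites_satisfy_cysteine_invariant(self):
        rows = [("MKCAKAAACR", "P1", "P001_T", 2.0)]
        m = aggregate_site_ratios(_toy_peptides(rows), [self.protein], self.meta)
        check_sites_against_fasta(m, [self.protein])


class TestSiteReport:
    def test_report_rows_and_round_trip(self, tmp_path):
        protein = ProteinRecord("P1", "MKCAKAAACR")
        meta = make_meta(2)
        rows = [
            ("KCAK", "P1", "P001_T", 1.5),
            ("AAACR", "P1", "P002_H", 0.5),
        ]
        m = aggregate_site_ratios(_toy_peptides(rows), [protein], meta)
        report = site_report(m)
        assert len(report) == 2
        path = tmp_path / "sites.tsv"
        write_site_report(m, path)
        back = read_site_report(path)
        pd.testing.assert_frame_equal(back.values, m.values, check_dtype=False)
        pd.testing.assert_frame_equal(
            back.site_index, m.site_index, check_dtype=False
        )

    def test_empty_matrix_round_trips_header_only(self, tmp_path):
        meta = make_meta(2)
        m = aggregate_site_ratios(
            _toy_peptides([]), [ProteinRecord("P1", "MKC")], meta
        )
        assert m.values.empty
        path = tmp_path / "sites.tsv"
        write_site_report(m, path)
        assert path.read_text().startswith("site_id")
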