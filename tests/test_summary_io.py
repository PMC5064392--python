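"""Reading, validating and pairing summary-statistic panels."""

import numpy as np
import pytest

from gwas_efficiency.errors import FormatError, NoOverlapError, ValidationError
from gwas_efficiency.summary_io import (
    LocusRecord,
    StudyPanel,
    best_trait_per_snp,
    pair_studies,
    read_summary_table,
    select_min_n_gap,
    write_summary_table,
)
from tests.conftest import make_record, write_tsv


class TestReadSummaryTable:
    def test_well_formed_table(self, tmp_path):
        path = write_tsv(
            tmp_path / "a.tsv",
            [
                ("FTO", "BMI", 320000, "1e-60"),
                ("MC4R", "BMI", 318000, "2.4e-30"),
                ("TMEM18", "BMI", 315000, "1e-25"),
                ("GIPR", "BMI", 250000, "0.03"),
            ],
        )
        panel = read_summary_table(path, "giant", "BMI")
        assert len(panel) == 4
        assert panel.records[0].neglog10_p == pytest.approx(60.0)
        assert panel.records[3].n == 250_000

    def test_p_zero_names_offending_row(self, tmp_path):
        path = write_tsv(
            tmp_path / "a.tsv",
            [("FTO", "BMI", 1000, "1e-5"), ("MC4R", "BMI", 1000, "0")],
        )
        with pytest.raises(ValidationError, match="line 3"):
            read_summary_table(path, "s", "BMI")

    def test_missing_n_column_is_format_error(self, tmp_path):
        path = write_tsv(
            tmp_path / "a.tsv", [("FTO", "BMI", "1e-5")], header=("locus_id", "trait", "p")
        )
        with pytest.raises(FormatError, match="n"):
            read_summary_table(path, "s", "BMI")

    def test_neglog10_p_column_preferred(self, tmp_path):
        path = write_tsv(
            tmp_path / "a.tsv",
            [("FTO", "BMI", 1000, "350.5")],
            header=("locus_id", "trait", "n", "neglog10_p"),
        )
        panel = read_summary_table(path, "s", "BMI")
        assert panel.records[0].neglog10_p == 350.5  # beyond double-precision p

    def test_dot_marks_missing_optional_fields(self, tmp_path):
        path = write_tsv(
            tmp_path / "a.tsv",
            [("FTO", "rs1558902", "BMI", 1000, "1e-5", ".", ".")],
            header=("locus_id", "snp_id", "trait", "n", "p", "effect", "se"),
        )
        rec = read_summary_table(path, "s", "BMI").records[0]
        assert rec.effect is None and rec.se is None and rec.snp_id == "rs1558902"

    def test_round_trip_is_lossless(self, tmp_path):
        panel = StudyPanel(
            "s",
            "BMI",
            [make_record("FTO", n=7, neglog10_p=123.456789012345, effect=0.1, se=0.02)],
        )
        write_summary_table(panel, tmp_path / "a.tsv")
        back = read_summary_table(tmp_path / "a.tsv", "s", "BMI")
        assert back.records[0] == panel.records[0]


class TestLocusRecordInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"locus_id": ""},
            {"n": 0},
            {"neglog10_p": -1.0},
            {"neglog10_p": float("inf")},
            {"se": 0.0},
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        base = dict(locus_id="FTO", trait="BMI", n=1000, neglog10_p=5.0)
        with pytest.raises(ValidationError):
            LocusRecord(**{**base, **kwargs})

    def test_duplicate_keys_rejected_in_panel(self):
        with pytest.raises(ValidationError, match="duplicate"):
            StudyPanel("s", "BMI", [make_record("FTO"), make_record("FTO")])


class TestPairStudies:
    def test_pairs_overlap_and_reports_omissions(self, toy_panels):
        panel_a, panel_b = toy_panels
        result = pair_studies(panel_a, panel_b)
        assert len(result.pairs) == 4
        omitted = {(o[0], o[1]) for o in result.omitted}
        assert omitted == {("SEC16B", "giant_2015"), ("NEGR1", "giant_2010")}
        # every input locus is either paired or reported omitted
        assert 2 * len(result.pairs) + len(result.omitted) == len(panel_a) + len(panel_b)

    def test_per_locus_larger_designation(self, toy_panels):
        """One locus with the sample-size order reversed takes its larger
        record from the other panel, as for RASA2-style cases."""
        panel_a, panel_b = toy_panels
        by_locus = {p.locus_id: p for p in pair_studies(panel_a, panel_b).pairs}
        assert by_locus["FTO"].larger_study_label == "giant_2015"
        assert by_locus["GIPR"].larger_study_label == "giant_2010"
        assert by_locus["GIPR"].larger.n == 260_000

    def test_symmetric_up_to_designation(self, toy_panels):
        panel_a, panel_b = toy_panels
        fwd = pair_studies(panel_a, panel_b)
        rev = pair_studies(panel_b, panel_a)
        fwd_set = {(p.locus_id, p.larger.n, p.smaller.n) for p in fwd.pairs}
        rev_set = {(p.locus_id, p.larger.n, p.smaller.n) for p in rev.pairs}
        assert fwd_set == rev_set

    def test_identical_panels_flag_ties(self, toy_panels):
        panel_a, _ = toy_panels
        result = pair_studies(panel_a, panel_a)
        assert all(p.tie for p in result.pairs)
        assert all(p.larger.n == p.smaller.n for p in result.pairs)

    def test_zero_overlap_raises(self):
        a = StudyPanel("a", "BMI", [make_record("FTO")])
        b = StudyPanel("b", "BMI", [make_record("MC4R")])
        with pytest.raises(NoOverlapError):
            pair_studies(a, b)

    def test_trait_family_mismatch_rejected(self):
        a = StudyPanel("a", "BMI", [make_record("FTO")])
        b = StudyPanel("b", "lipids", [make_record("FTO", trait="LDL")])
        with pytest.raises(ValidationError):
            pair_studies(a, b)

    def test_snp_key_pairing(self):
        a = StudyPanel("a", "BMI", [make_record("FTO", n=2000, snp_id="rs1558902")])
        b = StudyPanel("b", "BMI", [make_record("FTO_region", n=1000, snp_id="rs1558902")])
        result = pair_studies(a, b, key="snp")
        assert result.pairs[0].locus_id == "rs1558902"


class TestSelectMinNGap:
    def test_boundary_inclusive(self):
        from tests.conftest import make_pair

        pairs = [make_pair(n1=100_000 + g, n2=100_000, locus_id=f"L{g}") for g in (5_000, 10_000, 50_000)]
        kept = select_min_n_gap(pairs, 10_000)
        assert [p.locus_id for p in kept] == ["L10000", "L50000"]

    def test_zero_gap_keeps_all_and_is_idempotent(self):
        from tests.conftest import make_pair

        pairs = [make_pair(n1=100_000 + g, n2=100_000, locus_id=f"L{g}") for g in (0, 3, 9)]
        assert select_min_n_gap(pairs, 0) == pairs
        once = select_min_n_gap(pairs, 5)
        assert select_min_n_gap(once, 5) == once

    def test_monotone_in_gap(self):
        from tests.conftest import make_pair

        rng = np.random.default_rng(0)
        pairs = [
            make_pair(n1=100_000 + int(g), n2=100_000, locus_id=f"L{i}")
            for i, g in enumerate(rng.integers(0, 60_000, size=30))
        ]
        for g1, g2 in [(0, 10_000), (10_000, 30_000)]:
            assert set(p.locus_id for p in select_min_n_gap(pairs, g2)) <= set(
                p.locus_id for p in select_min_n_gap(pairs, g1)
            )


class TestBestTraitPerSnp:
    def test_argmin_p_wins(self):
        recs = [
            make_record("CELSR2", trait="TC", p=1e-9, snp_id="rs629301"),
            make_record("CELSR2", trait="LDL", p=1e-12, snp_id="rs629301"),
            make_record("CELSR2", trait="HDL", p=0.01, snp_id="rs629301"),
            make_record("CELSR2", trait="TG", p=1e-5, snp_id="rs629301"),
        ]
        sel = best_trait_per_snp(recs)
        assert [r.trait for r in sel.records] == ["LDL"]
        assert sel.ties == {}

    def test_single_record_group_is_identity(self):
        recs = [make_record("APOE", trait="TC", p=1e-30, snp_id="rs7412")]
        assert best_trait_per_snp(recs).records == recs

    def test_tie_broken_by_canonical_trait_order_and_flagged(self):
        recs = [
            make_record("X", trait="HDL", p=1e-8, snp_id="rs1"),
            make_record("X", trait="LDL", p=1e-8, snp_id="rs1"),
            make_record("X", trait="TG", p=1e-3, snp_id="rs1"),
        ]
        sel = best_trait_per_snp(recs)
        assert sel.records[0].trait == "LDL"
        assert sel.ties == {"rs1": ("LDL", "HDL")}

    def test_matches_exhaustive_comparison(self):
        """Winner agrees with a brute-force scan over every record per SNP."""
        rng = np.random.default_rng(1)
        traits = ["TC", "LDL", "HDL", "TG"]
        recs = []
        for i in range(40):
            for t in rng.choice(traits, size=rng.integers(1, 5), replace=False):
                recs.append(
                    make_record(f"G{i}", trait=t, neglog10_p=float(rng.integers(1, 50)), snp_id=f"rs{i}")
                )
        sel = best_trait_per_snp(recs)
        for winner in sel.records:
            group = [r for r in recs if r.snp_id == winner.snp_id]
            assert winner.neglog10_p == max(r.neglog10_p for r in group)

    def test_unknown_trait_rejected(self):
        with pytest.raises(ValidationError):
            best_trait_per_snp([make_record("X", trait="BMI", snp_id="rs1")])
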