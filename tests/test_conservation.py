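import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gblscreen.conservation import (
    MAX_IC,
    MotifPattern,
    align_homologs,
    column_information,
    count_motif_patterns,
    estimate_amplifiable,
    extract_window_variants,
    reference_columns,
    select_motif_windows,
)
from gblscreen.synth_fixtures import RECEPTOR_ANCHOR, SYNTHASE_ANCHOR, simulate_homolog_proteins


class TestAlignHomologs:
    def test_identical_sequences_align_gapless(self):
        msa = align_homologs(["MKVLYFHF" * 5] * 3, 0)
        assert msa.ncols == 40
        assert all("-" not in row for row in msa.rows)

    def test_insertion_opens_columns(self):
        ref = "MKVAEILRWQDNST" * 3
        withins = ref[:20] + "GGG" + ref[20:]
        msa = align_homologs([ref, withins], 0)
        assert msa.ncols == len(ref) + 3
        # ungapping reproduces the inputs
        assert msa.rows[0].replace("-", "") == ref
        assert msa.rows[1].replace("-", "") == withins

    def test_motif_columns_nearly_invariant(self):
        prots = simulate_homolog_proteins(20, "receptor", identity=0.7, seed=1)
        msa = align_homologs(prots, 0)
        cols = reference_columns(msa)
        for r in range(RECEPTOR_ANCHOR, RECEPTOR_ANCHOR + 4):
            column = [row[cols[r]] for row in msa.rows]
            modal = max(column.count(c) for c in set(column))
            assert modal / len(column) >= 0.9

    def test_too_few_sequences(self):
        with pytest.raises(ValueError, match="at least 2"):
            align_homologs(["MKVLYFHFAA" * 3], 0)


class TestColumnInformation:
    def test_invariant_column_near_max(self):
        msa = align_homologs(["W" * 30] * 100, 0)
        prof = column_information(msa)
        assert prof.information[0] == pytest.approx(MAX_IC, abs=0.15)
        assert (prof.information <= MAX_IC + 1e-9).all()

    def test_uniform_column_near_zero(self):
        rows = [aa * 5 for aa in "ACDEFGHIKLMNPQRSTVWY"]
        msa = align_homologs(rows, 0)
        # column 0 sees every residue once (ignore alignment quirks: gapless here)
        prof = column_information(msa)
        occupied = prof.occupancy == 1.0
        assert prof.information[occupied].min() < 0.35

    def test_permutation_invariant_across_rows(self):
        prots = simulate_homolog_proteins(12, "receptor", identity=0.7, seed=3)
        m1 = align_homologs(prots, 0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(m1.rows))
        from gblscreen.conservation import Msa
        m2 = Msa([m1.ids[i] for i in perm], [m1.rows[i] for i in perm], m1.ids[perm[0]])
        p1, p2 = column_information(m1), column_information(m2)
        assert np.allclose(p1.information, p2.information)

    def test_motif_columns_beat_flanks(self):
        prots = simulate_homolog_proteins(20, "receptor", identity=0.7, seed=2)
        msa = align_homologs(prots, 0)
        prof = column_information(msa)
        cols = reference_columns(msa)
        motif = [cols[r] for r in range(RECEPTOR_ANCHOR, RECEPTOR_ANCHOR + 4)]
        flank = [cols[r] for r in range(60, 100)]
        assert prof.information[motif].mean() > prof.information[flank].mean()


class TestSelectMotifWindows:
    def test_receptor_fixture_recovers_yfhf(self):
        prots = simulate_homolog_proteins(20, "receptor", identity=0.7, seed=1)
        msa = align_homologs(prots, 0)
        prof = column_information(msa)
        (top,) = select_motif_windows(prof, 4, 1, columns=reference_columns(msa))
        assert top.pattern == "YFHF"

    def test_synthase_fixture_recovers_etxrq(self):
        prots = simulate_homolog_proteins(
            40, "synthase", {"ETLRQ": 1 / 3, "ETIRQ": 1 / 3, "ETVRQ": 1 / 3},
            identity=0.7, seed=1)
        msa = align_homologs(prots, 0)
        prof = column_information(msa)
        (top,) = select_motif_windows(prof, 5, 1, columns=reference_columns(msa))
        assert top.pattern == "ETxRQ"

    def test_planted_window_ranked_first(self):
        # one invariant 4-residue block inside otherwise random proteins
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        prots = []
        for _ in range(15):
            p = "M" + "".join(rng.choice(aas, size=59))
            prots.append(p[:25] + "WCWH" + p[29:])
        msa = align_homologs(prots, 0)
        prof = column_information(msa)
        (top,) = select_motif_windows(prof, 4, 1, columns=reference_columns(msa))
        assert top.pattern == "WCWH"

    def test_top_k_must_be_positive(self):
        prots = simulate_homolog_proteins(5, "receptor", seed=0)
        prof = column_information(align_homologs(prots, 0))
        with pytest.raises(ValueError):
            select_motif_windows(prof, 4, 0)


class TestMotifCounting:
    def test_wildcard_matching(self):
        counts = count_motif_patterns(["YFHF", "YFHY", "YHHF"], ["YFHx"])
        assert counts["YFHx"] == 2

    def test_specific_pattern_never_exceeds_generalization(self):
        variants = ["YFHF", "YFHY", "YHHF", "HFHF", "YFHF"]
        counts = count_motif_patterns(variants, ["YFHF", "YFHx", "YxHF", "xFHF"])
        for gen in ("YFHx", "YxHF", "xFHF"):
            assert counts["YFHF"] <= counts[gen]

    @given(st.lists(st.text(alphabet="YFH", min_size=4, max_size=4), max_size=30),
           st.sets(st.integers(min_value=0, max_value=3), max_size=3))
    def test_subsumption_property(self, variants, wild_positions):
        base = "YFHF"
        gen = "".join("x" if i in wild_positions else c for i, c in enumerate(base))
        counts = count_motif_patterns(variants, [base])
        if any(c != "x" for c in gen):
            gen_counts = count_motif_patterns(variants, [gen])
            assert counts[base] <= gen_counts[gen]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            count_motif_patterns(["YFHFX"], ["YFHx"])

    def test_window_variants_read_from_alignment(self):
        prots = simulate_homolog_proteins(
            20, "receptor", {"YFHF": 0.8, "YHHF": 0.2}, identity=0.8, seed=9)
        msa = align_homologs(prots, 0)
        cols = reference_columns(msa)
        window = [cols[r] for r in range(RECEPTOR_ANCHOR, RECEPTOR_ANCHOR + 4)]
        variants = extract_window_variants(msa, window)
        assert set(variants) <= {"YFHF", "YHHF"}


class TestEstimateAmplifiable:
    def test_zero_matches(self):
        out = estimate_amplifiable(["YHHF"] * 3, ["ESVRQ"] * 3, "YFHx", "ETxRx")
        assert out == {"n_pairs": 3, "n_amplifiable": 0, "percent": 0.0}

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="index-paired"):
            estimate_amplifiable(["YFHF"], [], "YFHx", "ETxRx")

    def test_percent_one_decimal_rounding(self):
        rec = ["YFHF"] * 680 + ["YHHF"] * 305
        syn = ["ETLRQ"] * 680 + ["ESVRQ"] * 305
        out = estimate_amplifiable(rec, syn, "YFHx", "ETxRx")
        assert out["percent"] == 69.0
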