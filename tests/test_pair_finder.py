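import numpy as np
import pytest
from Bio.Align import substitution_matrices

from gblscreen.genome_io import CdsFeature, GenomeRecord, revcomp
from gblscreen.pair_finder import (
    NonDivergentError,
    classify_orientation,
    find_homologs,
    gap_between,
    intergenic_sequence,
    orientation_census,
    pair_colocated,
)
from gblscreen.synth_fixtures import PlantSpec, generate_pair_locus

from conftest import smith_waterman_affine

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _random_proteome(rng, n, length, contig="c"):
    feats = []
    for i in range(n):
        prot = "".join(rng.choice(list(AAS), size=length))
        feats.append(CdsFeature(contig, 1000 * i, 1000 * i + 3 * (length + 1), "+",
                                f"dec{i}", prot))
    return feats


class TestFindHomologs:
    def test_self_hit_tops_with_identity_one(self, queries):
        rq, _ = queries
        rng = np.random.default_rng(0)
        proteome = _random_proteome(rng, 10, 200)
        proteome.append(CdsFeature("c", 50000, 50000 + 3 * (len(rq) + 1), "+", "self", rq))
        hits = find_homologs(proteome, rq)
        assert hits[0].feature.locus_tag == "self"
        assert hits[0].identity == 1.0

    def test_random_decoys_yield_no_hits(self, queries):
        rq, _ = queries
        rng = np.random.default_rng(1)
        proteome = _random_proteome(rng, 100, 200)
        assert find_homologs(proteome, rq, evalue_max=0.02) == []

    def test_diverged_variant_recovered(self, codon_table):
        # homologue at ~60% identity must still be found
        spec = PlantSpec(identity=0.6, seed=13)
        genome, _ = generate_pair_locus(spec, codon_table)
        from gblscreen.synth_fixtures import reference_proteins
        rq, sq = reference_proteins()
        rec_hits = find_homologs(genome.proteome(), rq)
        assert any("receptor" in h.feature.locus_tag for h in rec_hits)
        top = rec_hits[0]
        assert 0.45 <= top.identity <= 0.8
        assert top.expectation < 0.02

    def test_scores_match_smith_waterman_oracle(self, queries):
        rq, _ = queries
        query = rq[:120]
        rng = np.random.default_rng(2)
        matrix = substitution_matrices.load("BLOSUM62")
        proteome = _random_proteome(rng, 8, 120)
        # add two mutated copies of the query so real hits exist
        for k, ident in enumerate((0.8, 0.5)):
            prot = list(query)
            idx = rng.choice(len(prot), size=int((1 - ident) * len(prot)), replace=False)
            for i in idx:
                prot[i] = AAS[rng.integers(20)]
            proteome.append(CdsFeature("c", 100000 + 1000 * k,
                                       100000 + 1000 * k + 3 * (len(prot) + 1), "+",
                                       f"hom{k}", "".join(prot)))
        hits = find_homologs(proteome, query, evalue_max=1e6)
        by_tag = {h.feature.locus_tag: h.score for h in hits}
        for feat in proteome:
            oracle = smith_waterman_affine(query, feat.protein, matrix)
            assert by_tag[feat.locus_tag] == pytest.approx(oracle)

    def test_invalid_query_rejected(self):
        feats = [CdsFeature("c", 0, 63, "+", "x", "A" * 20)]
        with pytest.raises(ValueError, match="non-amino-acid"):
            find_homologs(feats, "ACDEFGHIKLMNPQRSTVWY1")


def _hit(feat):
    from gblscreen.pair_finder import HomologHit
    return HomologHit("q", feat, 100.0, 1e-30, 1.0)


def _feature(contig, start, end, strand, tag="f"):
    return CdsFeature(contig, start, end, strand, tag, "M" + "A" * ((end - start) // 3 - 2))


class TestPairColocated:
    @pytest.mark.parametrize("gap,n_expected", [(599, 1), (600, 1), (601, 0)])
    def test_gap_cutoff_boundary(self, gap, n_expected):
        a = _feature("c", 0, 900, "-", "syn")
        b = _feature("c", 900 + gap, 1800 + gap, "+", "rec")
        pairs = pair_colocated([_hit(a)], [_hit(b)], max_intergenic=600)
        assert len(pairs) == n_expected

    def test_three_synthases_one_receptor(self):
        rec = _feature("c", 5000, 5900, "+", "rec")
        syns = [_feature("c", 3800, 4700, "-", f"s{i}") for i in range(1)] + \
               [_feature("c", 6000 + 150 * i, 6900 + 150 * i, "+", f"t{i}")
                for i in range(2)]
        pairs = pair_colocated([_hit(s) for s in syns], [_hit(rec)])
        assert len(pairs) == 3

    def test_different_contigs_never_pair(self):
        a = _feature("c1", 0, 900, "-")
        b = _feature("c2", 1000, 1900, "+")
        assert pair_colocated([_hit(a)], [_hit(b)]) == []

    def test_overlapping_cds_gap_zero(self):
        a = _feature("c", 0, 900, "+", "a")
        b = _feature("c", 880, 1780, "+", "b")
        (pair,) = pair_colocated([_hit(a)], [_hit(b)])
        assert pair.gap == 0
        assert gap_between(a, b) == 0


class TestOrientation:
    @pytest.mark.parametrize("left_strand,right_strand,expected", [
        ("-", "+", "divergent"),  # back-to-back, 5' ends flank the gap
        ("+", "-", "convergent"),
        ("+", "+", "tandem"),
        ("-", "-", "tandem"),
    ])
    def test_classes(self, left_strand, right_strand, expected):
        left = _feature("c", 0, 900, left_strand)
        right = _feature("c", 1100, 2000, right_strand)
        assert classify_orientation(left, right) == expected
        # argument order must not matter
        assert classify_orientation(right, left) == expected

    def test_large_overlap_is_ambiguous(self):
        a = _feature("c", 0, 900, "-")
        b = _feature("c", 860, 1760, "+")
        assert classify_orientation(a, b) == "ambiguous"

    def test_invariant_under_contig_revcomp(self):
        rng = np.random.default_rng(3)
        contig_len = 10000
        for _ in range(50):
            s1, e1 = sorted(rng.choice(contig_len, size=2, replace=False))
            while e1 - s1 < 6 or (e1 - s1) % 3:
                s1, e1 = sorted(rng.choice(contig_len, size=2, replace=False))
            gap = int(rng.integers(31, 500))
            length2 = 3 * int(rng.integers(2, 300))
            s2 = e1 + gap
            e2 = s2 + length2
            if e2 > contig_len:
                continue
            st1, st2 = rng.choice(list("+-"), size=2)
            a = _feature("c", int(s1), int(e1), st1)
            b = _feature("c", s2, e2, st2)
            flip = {"+": "-", "-": "+"}
            a2 = _feature("c", contig_len - e1, contig_len - int(s1), flip[st1])
            b2 = _feature("c", contig_len - e2, contig_len - s2, flip[st2])
            assert classify_orientation(a, b) == classify_orientation(a2, b2)


class TestCensusAndIntergenic:
    def test_census_counts_planted_mix(self):
        from gblscreen.synth_fixtures import generate_cohort
        records, truth = generate_cohort(
            20, {"divergent": 0.7, "convergent": 0.2, "tandem": 0.1}, seed=4)
        from gblscreen.pair_finder import GenePair, HomologHit
        pairs = []
        for rec in records:
            r, s = rec.features
            pairs += pair_colocated([_hit(s)], [_hit(r)],
                                    genomes={rec.contig_id: rec})
        census = orientation_census(pairs)
        expected = truth["orientation"].value_counts().to_dict()
        for k in ("divergent", "convergent", "tandem"):
            assert census[k] == expected.get(k, 0)
        assert sum(census.values()) == len(pairs)

    def test_empty_census(self):
        assert orientation_census([]) == {
            "divergent": 0, "convergent": 0, "tandem": 0, "ambiguous": 0}

    def test_intergenic_sequence_matches_planted_gap(self, demo_locus):
        genome, truth = demo_locus
        r, s = genome.features
        (pair,) = pair_colocated([_hit(s)], [_hit(r)], genomes={genome.contig_id: genome})
        seq = intergenic_sequence(pair, genome)
        assert len(seq) == truth.gap == 180
        assert seq == genome.sequence[truth.intergenic_start:truth.intergenic_end]

    def test_intergenic_requires_divergent(self, codon_table):
        genome, _ = generate_pair_locus(PlantSpec(orientation="tandem", seed=5), codon_table)
        r, s = genome.features
        (pair,) = pair_colocated([_hit(s)], [_hit(r)])
        with pytest.raises(NonDivergentError):
            intergenic_sequence(pair, genome)

    def test_reported_gaps_never_exceed_cutoff(self):
        from gblscreen.synth_fixtures import generate_cohort
        records, _ = generate_cohort(15, seed=6, gap_range=(120, 900))
        for rec in records:
            r, s = rec.features
            for pair in pair_colocated([_hit(s)], [_hit(r)], max_intergenic=600):
                assert pair.gap <= 600
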