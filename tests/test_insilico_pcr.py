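import numpy as np
import pytest

from gblscreen.genome_io import expand_degenerate, revcomp
from gblscreen.insilico_pcr import (
    PrimeClass,
    classify_priming,
    match_primer,
    predict_amplicons,
)
from gblscreen.synth_fixtures import PlantSpec, generate_pair_locus


def _random_template(rng, n, gc=0.7):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def brute_force_matches(primer_seq: str, template: str) -> set[tuple[int, str]]:
    """Oracle: exact-search every concrete expansion on both strands."""
    out = set()
    for variant in expand_degenerate(primer_seq):
        for probe, strand in ((variant, "+"), (revcomp(variant), "-")):
            start = template.find(probe)
            while start != -1:
                out.add((start, strand))
                start = template.find(probe, start + 1)
    return out


class TestMatchPrimer:
    def test_planted_exact_site(self, primers):
        rng = np.random.default_rng(0)
        site = sorted(expand_degenerate(primers["scb_F"].sequence))[0]
        tmpl = _random_template(rng, 400) + site + _random_template(rng, 400)
        matches = match_primer(primers["scb_F"], tmpl)
        assert [(m.start, m.strand, m.mismatches) for m in matches] == [(400, "+", 0)]

    def test_three_prime_mismatch_kills_priming(self, primers):
        rng = np.random.default_rng(1)
        site = sorted(expand_degenerate(primers["scb_F"].sequence))[0]
        # substitute the 3'-terminal base to a base outside the primer's set
        mutated = site[:-1] + ("G" if site[-1] != "G" else "C")
        tmpl = _random_template(rng, 300) + mutated + _random_template(rng, 300)
        assert match_primer(primers["scb_F"], tmpl, max_mismatch=2) == []

    def test_equivalent_to_expansion_oracle(self, primers):
        rng = np.random.default_rng(2)
        primer = primers["scb_R"]
        for _ in range(10):
            tmpl = _random_template(rng, 10000)
            got = {(m.start, m.strand) for m in match_primer(primer, tmpl)}
            assert got == brute_force_matches(primer.sequence, tmpl)

    def test_mismatch_count_monotone(self, primers):
        rng = np.random.default_rng(3)
        tmpl = _random_template(rng, 20000)
        counts = [len(match_primer(primers["scb_F"], tmpl, max_mismatch=k,
                                   three_prime_exact=3))
                  for k in range(5)]
        assert counts == sorted(counts)

    def test_template_n_never_matches(self, primers):
        site = sorted(expand_degenerate(primers["scb_F"].sequence))[0]
        tmpl = "A" * 50 + site[:10] + "N" + site[11:] + "A" * 50
        assert match_primer(primers["scb_F"], tmpl, max_mismatch=0) == []

    def test_primer_longer_than_template(self, primers):
        assert match_primer(primers["scb_F"], "ACGT") == []


class TestPredictAmplicons:
    def test_divergent_locus_single_product(self, primers, demo_locus):
        genome, truth = demo_locus
        amps = predict_amplicons(primers["scb_F"], primers["scb_R"], genome.sequence)
        assert len(amps) == 1
        assert amps[0].length == truth.expected_amplicon
        # outer-edge to outer-edge definition
        assert amps[0].start == truth.fwd_site[0]
        assert amps[0].end == truth.rev_site[1]

    def test_symmetric_in_primer_labels(self, primers, demo_locus):
        genome, _ = demo_locus
        a = predict_amplicons(primers["scb_F"], primers["scb_R"], genome.sequence)
        b = predict_amplicons(primers["scb_R"], primers["scb_F"], genome.sequence)
        assert [(x.start, x.end) for x in a] == [(x.start, x.end) for x in b]

    def test_single_site_no_product(self, primers):
        rng = np.random.default_rng(4)
        site = sorted(expand_degenerate(primers["scb_F"].sequence))[0]
        tmpl = _random_template(rng, 300) + site + _random_template(rng, 300)
        assert predict_amplicons(primers["scb_F"], primers["scb_R"], tmpl) == []

    def test_outward_facing_sites_no_product(self, primers):
        rng = np.random.default_rng(5)
        f = sorted(expand_degenerate(primers["scb_F"].sequence))[0]
        r = sorted(expand_degenerate(primers["scb_R"].sequence))[0]
        # reverse site footprint left of forward site: primers extend apart
        tmpl = (_random_template(rng, 200) + revcomp(r)
                + _random_template(rng, 300) + f + _random_template(rng, 200))
        assert predict_amplicons(primers["scb_F"], primers["scb_R"], tmpl,
                                 min_size=100, max_size=3000) == []

    def test_size_window_filters(self, primers, demo_locus):
        genome, truth = demo_locus
        assert predict_amplicons(primers["scb_F"], primers["scb_R"], genome.sequence,
                                 max_size=truth.expected_amplicon - 1) == []


class TestClassifyPriming:
    @pytest.mark.parametrize("variant,primer_name,expected", [
        ("YFHF", "scb_F", PrimeClass.WILL_PRIME),
        ("YFHx", "scb_F", PrimeClass.WILL_LIKELY_PRIME),
        ("YxHF", "scb_F", PrimeClass.MIGHT_NOT_PRIME),
        ("xFHF", "scb_F", PrimeClass.MIGHT_NOT_PRIME),
        ("YHHF", "scb_F", PrimeClass.WILL_NOT_PRIME),
        ("HHHF", "scb_F", PrimeClass.WILL_NOT_PRIME),
        ("YFHY", "scb_F", PrimeClass.WILL_LIKELY_PRIME),
        ("ETxRQ", "scb_R", PrimeClass.WILL_LIKELY_PRIME),
        ("ETxRx", "scb_R", PrimeClass.WILL_LIKELY_PRIME),
        ("ESxRQ", "scb_R", PrimeClass.MIGHT_NOT_PRIME),
        ("ETLRQ", "scb_R", PrimeClass.WILL_PRIME),
        ("ETIRQ", "scb_R", PrimeClass.WILL_PRIME),
        ("ETVRQ", "scb_R", PrimeClass.WILL_PRIME),
        ("EAVRQ", "scb_R", PrimeClass.MIGHT_NOT_PRIME),
        ("ESVRQ", "scb_R", PrimeClass.MIGHT_NOT_PRIME),
    ])
    def test_variant_classes(self, variant, primer_name, expected, primers, codon_table):
        primer = primers[primer_name]
        got = classify_priming(variant, primer.motif_pattern, primer, codon_table)
        assert got == expected

    def test_classes_totally_ordered(self):
        assert (PrimeClass.WILL_PRIME < PrimeClass.WILL_LIKELY_PRIME
                < PrimeClass.MIGHT_NOT_PRIME < PrimeClass.WILL_NOT_PRIME)

    def test_length_mismatch_rejected(self, primers, codon_table):
        with pytest.raises(ValueError, match="length"):
            classify_priming("YFH", "YFHF", primers["scb_F"], codon_table)


class TestMismatchLoci:
    @pytest.mark.parametrize("receptor,synthase", [
        ("HHHF", "EAIRQ"),  # both anchors diverged at the primer 3' region
        ("YHHF", "ESVRQ"),
    ])
    def test_diverged_motifs_block_amplification(self, receptor, synthase,
                                                 primers, codon_table):
        genome, truth = generate_pair_locus(
            PlantSpec(gap=200, receptor_variant=receptor, synthase_variant=synthase,
                      seed=11), codon_table)
        amps = predict_amplicons(primers["scb_F"], primers["scb_R"], genome.sequence,
                                 max_mismatch=0)
        assert amps == []
        assert truth.expected_amplicon is None
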