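import math

import numpy as np
import pytest

from splicevar.genomic_context import GeneModels, GenomeSequence, TranscriptModel, Variant, resolve_context
from splicevar.splice_sites import (
    ACCEPTOR_LEN,
    DONOR_LEN,
    PwmScorer,
    delta_natural_site,
    load_pwm_scorer,
    load_table_scorer,
    max_cryptic_site_score,
    natural_site_strength,
    train_pwm_scorer,
    train_scorers_from_annotation,
)
from tests_helpers import ConstScorer, CountScorer, middle_exon_context


class TestPwmTraining:
    def test_consensus_maximizes_score(self, rng):
        site = "CAGGTAAGT"
        pwm = train_pwm_scorer([site] * 3, "donor")
        best = pwm.score(site)
        # per-position argmax must be the consensus base
        for i, b in enumerate(site):
            assert "ACGT"[int(np.argmax(pwm.matrix[i]))] == b
        for _ in range(200):
            w = "".join("ACGT"[i] for i in rng.integers(0, 4, size=9))
            assert pwm.score(w) <= best + 1e-12

    def test_uniform_training_scores_zero(self):
        sites = ["A" * 9, "C" * 9, "G" * 9, "T" * 9]
        pwm = train_pwm_scorer(sites, "donor")
        assert pwm.score("CAGGTAAGT") == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_sequence_pwm(self):
        s1, s2 = "CAGGTAAGT", "AAGGTGAGT"
        pwm = train_pwm_scorer([s1, s2], "donor", pseudocount=1.0)
        # hand arithmetic: position 0 sees C and A -> p(C)=2/6, p(A)=2/6,
        # p(G)=p(T)=1/6; log2(p/0.25) summed over "CAGGTAAGT"
        def p(pos, base):
            count = sum(1 for s in (s1, s2) if s[pos] == base) + 1.0
            return count / 6.0

        expected = sum(math.log2(p(i, b) / 0.25) for i, b in enumerate(s1))
        assert pwm.score(s1) == pytest.approx(expected, abs=1e-12)

    def test_additivity(self):
        pwm = train_pwm_scorer(["CAGGTAAGT", "AAGGTGAGT"], "donor")
        # score difference between windows differing at one position equals
        # the matrix-entry difference at that position
        w1, w2 = "CAGGTAAGT", "CAGGTAAGA"
        d = pwm.matrix[8, 0] - pwm.matrix[8, 3]  # A vs T at position 8
        assert pwm.score(w2) - pwm.score(w1) == pytest.approx(d)

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            train_pwm_scorer(["CAGGTAAGT", "CAGGT"], "donor")

    def test_tsv_round_trip(self, tmp_path):
        pwm = train_pwm_scorer(["CAGGTAAGT", "AAGGTGAGT"], "donor")
        pwm.save(tmp_path / "pwm.tsv")
        again = load_pwm_scorer(tmp_path / "pwm.tsv", "donor")
        assert again.score("CAGGTAAGT") == pytest.approx(pwm.score("CAGGTAAGT"))


class TestTableScorer:
    def test_lookup_and_length_check(self, tmp_path):
        (tmp_path / "t.tsv").write_text("window\tscore\nCAGGTAAGT\t8.2\n")
        sc = load_table_scorer(tmp_path / "t.tsv", "donor")
        assert sc.window_length == 9
        assert sc.score("CAGGTAAGT") == 8.2
        with pytest.raises(KeyError):
            sc.score("AAAAAAAAA")


class TestNaturalSite:
    def test_mock_scorer_counts_window_content(self, toy_locus):
        ctx = middle_exon_context(toy_locus)
        donor = CountScorer("G", DONOR_LEN)
        acceptor = CountScorer("G", ACCEPTOR_LEN)
        s = natural_site_strength(ctx, donor, acceptor)
        dw = ctx.exon_seq[-3:] + ctx.downstream_intron_seq[:6]
        aw = ctx.upstream_intron_seq[-20:] + ctx.exon_seq[:3]
        assert s.five_prime == dw.count("G")
        assert s.three_prime == aw.count("G")

    def test_first_exon_acceptor_absent(self, toy_locus):
        genome, models = toy_locus
        s1 = models.transcripts["txA"].exons[0][0]
        ref = genome.base("chrT", s1 + 3)
        alt = "A" if ref != "A" else "G"
        ctx = resolve_context(Variant("chrT", s1 + 3, ref, alt), models, genome)
        s = natural_site_strength(ctx, CountScorer("G", 9), CountScorer("G", 23))
        assert s.three_prime is None and "acceptor" in s.three_prime_absent
        assert s.five_prime is not None


class TestDeltaNaturalSite:
    def test_variant_outside_windows_zero(self, toy_locus):
        ctx = middle_exon_context(toy_locus, offset=10)
        assert ctx.exon_len - ctx.offset > 3 and ctx.offset > 2
        d = delta_natural_site(ctx, CountScorer("G", 9), CountScorer("G", 23))
        assert d.value == 0.0 and not d.in_donor and not d.in_acceptor

    def test_g_loss_in_donor_window(self, toy_locus):
        genome, models = toy_locus
        s2, e2 = models.transcripts["txA"].exons[1]
        pos = e2 - 1  # toy exon ends ...CAG: last base is G
        ctx = resolve_context(Variant("chrT", pos, "G", "A"), models, genome)
        d = delta_natural_site(ctx, CountScorer("G", 9), CountScorer("G", 23))
        assert d.value == -1.0 and d.in_donor

    def test_direction_depends_on_scorer(self, toy_locus):
        genome, models = toy_locus
        s2, e2 = models.transcripts["txA"].exons[1]
        ctx = resolve_context(Variant("chrT", e2 - 1, "G", "C"), models, genome)
        assert delta_natural_site(ctx, CountScorer("G", 9), CountScorer("G", 23)).value == -1.0
        assert delta_natural_site(ctx, CountScorer("C", 9), CountScorer("C", 23)).value == +1.0

    def test_antisymmetric_under_allele_swap(self, toy_locus):
        genome, models = toy_locus
        s2, e2 = models.transcripts["txA"].exons[1]
        ctx = resolve_context(Variant("chrT", e2 - 1, "G", "A"), models, genome)
        pwm_d = train_pwm_scorer(["CAGGTAAGT", "AAGGTGAGT", "CAGGTAAGA"], "donor")
        pwm_a = train_pwm_scorer(["T" * 20 + "GCA", "C" * 20 + "GTT"], "acceptor")
        fwd = delta_natural_site(ctx, pwm_d, pwm_a).value
        # swapping the alleles (mutant genome, ref<->alt) negates the delta
        mut_seq = list(genome.contigs["chrT"])
        mut_seq[e2 - 1] = "A"
        mut_genome = GenomeSequence({"chrT": "".join(mut_seq)})
        ctx_rev = resolve_context(Variant("chrT", e2 - 1, "A", "G"), models, mut_genome)
        rev = delta_natural_site(ctx_rev, pwm_d, pwm_a).value
        assert fwd == pytest.approx(-rev)


def brute_force_cryptic(ctx, donor, acceptor):
    """Independent enumerator: scan every window containing the variant on
    the mutant region, skipping windows whose implied junction sits on an
    annotated junction of the target exon."""
    seq, off, a, b = ctx.mutant_region()
    junctions = set()
    if ctx.has_upstream:
        junctions.add(a)
    if ctx.has_downstream:
        junctions.add(b)
    best = -np.inf
    for scorer, exonic in ((donor, 3), (acceptor, 20)):
        L = scorer.window_length
        for s in range(0, len(seq) - L + 1):
            if not (s <= off < s + L):
                continue
            if s + exonic in junctions:
                continue
            best = max(best, scorer.score(seq[s : s + L]))
    return best


class TestCrypticScan:
    def test_constant_scorer_returns_constant(self, toy_locus):
        ctx = middle_exon_context(toy_locus)
        assert max_cryptic_site_score(ctx, ConstScorer(3.5, 9), ConstScorer(3.5, 23)) == 3.5

    def test_matches_brute_force_enumerator_on_random_loci(self, small_world):
        """Oracle equivalence on many fixture variants with a mock scorer."""
        from splicevar.fixtures import variants_from_frame
        from splicevar.genomic_context import resolve_context

        world = small_world
        genome = GenomeSequence(world.contigs)
        donor, acceptor = CountScorer("G", 9), CountScorer("T", 23)
        frame = world.labeled.copy()
        frame["pos"] = frame["pos0"] + 1
        n = 0
        for v in variants_from_frame(frame):
            ctx = resolve_context(v, world.models, genome)
            got = max_cryptic_site_score(ctx, donor, acceptor)
            assert got == brute_force_cryptic(ctx, donor, acceptor)
            n += 1
        assert n >= 100

    def test_natural_window_excluded(self):
        # one 10-base exon with flanks; scorer prefers G-rich windows. The
        # donor window of the exon itself must not be counted.
        exon = "AAAAAAAAAG"
        up = "T" * 30
        down = "GGGGGG" + "T" * 24
        seq = up + exon + down
        genome = GenomeSequence({"c": seq})
        models = GeneModels()
        models.add(
            TranscriptModel(
                "t", "g", "c", "+", ((len(up), len(up) + 10), (len(seq) - 4, len(seq)))
            )
        )
        v = Variant("c", len(up) + 9, "G", "C")
        ctx = resolve_context(v, models, genome)
        donor = CountScorer("G", 9)
        acceptor = CountScorer("G", 23)
        got = max_cryptic_site_score(ctx, donor, acceptor)
        assert got == brute_force_cryptic(ctx, donor, acceptor)
        # natural donor junction window would score 5 Gs (GGGGGG after C at
        # the mutated last base): ensure exclusion logic was exercised
        natural_start = len(ctx.upstream_intron_seq) + ctx.exon_len - 3
        seq_m, off, a, b = ctx.mutant_region()
        natural_window = seq_m[natural_start : natural_start + 9]
        assert donor.score(natural_window) >= got


class TestAnnotationTrainedScorers:
    def test_junction_windows_reflect_consensus(self, toy_locus):
        genome, models = toy_locus
        donor, acceptor = train_scorers_from_annotation(genome, models)
        assert donor.window_length == DONOR_LEN
        assert acceptor.window_length == ACCEPTOR_LEN
        # the toy introns all start GTAAGT: consensus window scores high
        ctx = middle_exon_context(toy_locus)
        dw = ctx.exon_seq[-3:] + ctx.downstream_intron_seq[:6]
        assert donor.score(dw) > 0

    def test_strand_invariance_of_natural_scores(self, toy_locus):
        from splicevar.genomic_context import reverse_complement

        genome, models = toy_locus
        seq = genome.contigs["chrT"]
        L = len(seq)
        tx = models.transcripts["txA"]
        mirror = GenomeSequence({"chrM": reverse_complement(seq)})
        m_models = GeneModels()
        m_models.add(
            TranscriptModel(
                "txA", "g", "chrM", "-",
                tuple(sorted((L - e, L - s) for s, e in tx.exons)),
            )
        )
        p_models = GeneModels()
        p_models.add(TranscriptModel("txA", "g", "chrT", "+", tx.exons))
        donor, acceptor = train_scorers_from_annotation(genome, p_models)
        donor_m, acceptor_m = train_scorers_from_annotation(mirror, m_models)
        assert np.allclose(donor.matrix, donor_m.matrix)
        s2, _ = tx.exons[1]
        pos = s2 + 7
        ref = genome.base("chrT", pos)
        alt = "A" if ref != "A" else "G"
        ctx_p = resolve_context(Variant("chrT", pos, ref, alt), p_models, genome)
        ctx_m = resolve_context(
            Variant("chrM", L - 1 - pos, reverse_complement(ref), reverse_complement(alt)),
            m_models, mirror,
        )
        sp = natural_site_strength(ctx_p, donor, acceptor)
        sm = natural_site_strength(ctx_m, donor_m, acceptor_m)
        assert sp.five_prime == pytest.approx(sm.five_prime)
        assert sp.three_prime == pytest.approx(sm.three_prime)
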