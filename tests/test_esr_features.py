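import math

import numpy as np
import pytest

from splicevar.esr_features import (
    EVENT_TYPES,
    TRANSITION_NAMES,
    HexamerError,
    HexamerSet,
    build_esr_hs_tables,
    classify_hexamer,
    classify_hexamer_full,
    esr_change_profile,
    esr_density,
    esr_hs,
    esr_transition_events,
    load_esr_hs_tables,
    load_hexamer_sets,
    region_density,
    variant_esr_hs_features,
    wt_esr_overlap_counts,
)


def write_motifs(path, motifs):
    path.write_text("".join(m + "\n" for m in motifs))
    return str(path)


class TestLoaders:
    def test_counts_and_dedup(self, tmp_path):
        ese = write_motifs(tmp_path / "ese.txt", ["AAAAAA", "CCCCCC", "aaaaaa"])
        ess = write_motifs(tmp_path / "ess.txt", ["GGGGGG", "UUUUUU"])
        sets = load_hexamer_sets(ese, ess)
        assert len(sets.ese) == 2  # duplicate collapsed, case-insensitive
        assert "TTTTTT" in sets.ess  # U mapped to T

    def test_wrong_length_rejected(self, tmp_path):
        bad = write_motifs(tmp_path / "ese.txt", ["GGGGG"])
        ok = write_motifs(tmp_path / "ess.txt", ["CCCCCC"])
        with pytest.raises(HexamerError, match="not a hexamer"):
            load_hexamer_sets(bad, ok)

    def test_collision_policies(self, tmp_path):
        a = write_motifs(tmp_path / "a.txt", ["AAAAAA", "CCCCCC"])
        b = write_motifs(tmp_path / "b.txt", ["AAAAAA", "GGGGGG"])
        with pytest.raises(HexamerError, match="both"):
            load_hexamer_sets(a, b)
        sets = load_hexamer_sets(a, b, collision="prefer-ese")
        assert "AAAAAA" in sets.ese and "AAAAAA" not in sets.ess
        sets = load_hexamer_sets(a, b, collision="drop")
        assert "AAAAAA" not in sets.ese and "AAAAAA" not in sets.ess


class TestClassify:
    def test_membership(self, simple_hexamers):
        assert classify_hexamer("AAAAAA", simple_hexamers) == "ESE"
        assert classify_hexamer("CCCCCC", simple_hexamers) == "ESS"
        assert classify_hexamer("TTTTTT", simple_hexamers) == "neutral"

    def test_n_masked(self, simple_hexamers):
        assert classify_hexamer_full("AANAAA", simple_hexamers) == ("neutral", True)

    def test_invalid_alphabet(self, simple_hexamers):
        with pytest.raises(HexamerError):
            classify_hexamer("AAXAAA", simple_hexamers)


class TestChangeProfile:
    def test_all_windows_lose_ese(self, simple_hexamers):
        # 16xA, interior offset: all 6 windows are AAAAAA -> ESE loss
        p = esr_change_profile("A" * 16, 7, "C", simple_hexamers)
        assert p.counts["ese_loss"] == 6
        assert p.n_windows == 6
        assert sum(v for k, v in p.counts.items() if k != "ese_loss") == 0

    def test_empty_sets_all_neutral(self):
        empty = HexamerSet(frozenset(), frozenset())
        p = esr_change_profile("A" * 16, 7, "C", empty)
        assert p.counts["neutral_neutral"] == 6

    def test_start_boundary_window_count(self, simple_hexamers):
        p = esr_change_profile("A" * 16, 1, "C", simple_hexamers)
        assert p.n_windows == 2

    def test_ref_mismatch(self, simple_hexamers):
        with pytest.raises(ValueError, match="mismatch"):
            esr_change_profile("A" * 16, 7, "C", simple_hexamers, ref_base="G")

    def test_window_count_matches_enumeration(self, rng):
        """Profile total equals a brute-force window enumerator on random
        sequences at random offsets."""
        bases = "ACGT"
        for _ in range(300):
            n = int(rng.integers(6, 40))
            seq = "".join(bases[i] for i in rng.integers(0, 4, size=n))
            off = int(rng.integers(0, n))
            alt = bases[int(rng.integers(0, 4))]
            if alt == seq[off]:
                continue
            sets = HexamerSet(
                frozenset({seq[max(0, off - 3) : max(0, off - 3) + 6]} if n >= 6 else set()),
                frozenset(),
            ) if len(seq[max(0, off - 3) : max(0, off - 3) + 6]) == 6 else HexamerSet(
                frozenset(), frozenset()
            )
            p = esr_change_profile(seq, off, alt, sets)
            brute = sum(
                1
                for s in range(0, n - 5)
                if s <= off < s + 6
            )
            assert p.n_windows == brute

    def test_same_base_is_diagonal(self, simple_hexamers):
        # a substitution to the same base keeps every window's class
        p = esr_change_profile("A" * 16, 7, "A", simple_hexamers)
        assert p.counts["ese_ese"] == 6


class TestOverlapCounts:
    def test_interior_full_overlap(self, simple_hexamers):
        assert wt_esr_overlap_counts("A" * 16, 7, simple_hexamers) == (6, 0)

    def test_empty_sets(self):
        empty = HexamerSet(frozenset(), frozenset())
        assert wt_esr_overlap_counts("A" * 16, 7, empty) == (0, 0)

    def test_offset_zero_single_window(self, simple_hexamers):
        in_ese, in_ess = wt_esr_overlap_counts("A" * 16, 0, simple_hexamers)
        assert in_ese == 1


def manual_tables(s_d, s_n, h_d, h_n, hexamer="AAAAAA", t="ESEloss"):
    """Construct tables directly with prescribed S/H entries for one cell."""
    from splicevar.esr_features import EsrHexamerTables

    universes = {tt: ("AAAAAA",) if tt.startswith("ESE") else ("CCCCCC",)
                 for tt in EVENT_TYPES}
    s_tables = {}
    h_tables = {}
    for tt, u in universes.items():
        k = u[0]
        s_tables[tt] = {"disease": {k: 1.0}, "neutral": {k: 1.0}}
        h_tables[(tt, k)] = {
            "disease": np.full(6, 1 / 6),
            "neutral": np.full(6, 1 / 6),
        }
    s_tables[t] = {"disease": {hexamer: s_d}, "neutral": {hexamer: s_n}}
    h_tables[(t, hexamer)] = {"disease": np.array(h_d), "neutral": np.array(h_n)}
    return EsrHexamerTables(universes, s_tables, h_tables, pseudocount=1.0)


class TestEsrHsTables:
    def test_zero_events_uniform(self, simple_hexamers):
        two = HexamerSet(frozenset({"AAAAAA", "CCCCCC"}), frozenset({"GGGGGG"}))
        t = build_esr_hs_tables([], [], two)
        assert t.s_tables["ESEloss"]["disease"]["AAAAAA"] == pytest.approx(0.5)
        assert t.h_tables[("ESEloss", "AAAAAA")]["disease"] == pytest.approx(
            np.full(6, 1 / 6)
        )

    def test_hand_normalization(self):
        sets = HexamerSet(frozenset({"AAAAAA", "AAAAAC"}), frozenset({"CCCCCC"}))
        events = [("ESEloss", "AAAAAA", 0)] * 3 + [("ESEloss", "AAAAAC", 1)]
        t = build_esr_hs_tables(events, [], sets)
        # raw 3 and 1 plus pseudocount 1 -> 4/6 and 2/6
        assert t.s_tables["ESEloss"]["disease"]["AAAAAA"] == pytest.approx(4 / 6)
        assert t.s_tables["ESEloss"]["disease"]["AAAAAC"] == pytest.approx(2 / 6)

    def test_normalization_invariants(self, small_world):
        """Sum_k S = 1 and sum_j H = 1 to 1e-9 after arbitrary input."""
        rng = np.random.default_rng(1)
        sets = small_world.hexamers
        ese = sorted(sets.ese)
        ess = sorted(sets.ess)
        events = []
        for _ in range(200):
            t = EVENT_TYPES[int(rng.integers(4))]
            pool = ese if t.startswith("ESE") else ess
            events.append((t, pool[int(rng.integers(len(pool)))], int(rng.integers(6))))
        tables = build_esr_hs_tables(events[:120], events[120:], sets)
        for t in EVENT_TYPES:
            for corpus in ("disease", "neutral"):
                assert sum(tables.s_tables[t][corpus].values()) == pytest.approx(
                    1.0, abs=1e-9
                )
                for k in tables.universes[t]:
                    assert tables.h_tables[(t, k)][corpus].sum() == pytest.approx(
                        1.0, abs=1e-9
                    )

    def test_tsv_round_trip(self, tmp_path, simple_hexamers):
        events = [("ESEloss", "AAAAAA", 2)] * 4
        t = build_esr_hs_tables(events, [("ESEloss", "AAAAAA", 3)], simple_hexamers)
        path = tmp_path / "tables.tsv"
        t.save(path)
        t2 = load_esr_hs_tables(path, simple_hexamers)
        for tt in EVENT_TYPES:
            for k in t.universes[tt]:
                for j in range(6):
                    assert esr_hs(t2, tt, k, j) == pytest.approx(esr_hs(t, tt, k, j))


class TestEsrHsScore:
    def test_identical_corpora_zero(self, simple_hexamers):
        events = [("ESEloss", "AAAAAA", 2), ("ESSgain", "CCCCCC", 4)]
        t = build_esr_hs_tables(events, list(events), simple_hexamers)
        for tt, k in (("ESEloss", "AAAAAA"), ("ESSgain", "CCCCCC")):
            for j in range(6):
                assert esr_hs(t, tt, k, j) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        # S ratio 2, H ratio 3 -> 1 + log2(3)
        t = manual_tables(0.5, 0.25, [1 / 3] * 3 + [1 / 9] * 3, [1 / 9] * 3 + [1 / 3] * 3)
        assert esr_hs(t, "ESEloss", "AAAAAA", 0) == pytest.approx(
            1 + math.log2(3), abs=1e-9
        )

    def test_corpus_swap_negates(self, simple_hexamers, rng):
        ev_a = [("ESEloss", "AAAAAA", int(rng.integers(6))) for _ in range(9)]
        ev_b = [("ESEloss", "AAAAAA", int(rng.integers(6))) for _ in range(4)]
        t1 = build_esr_hs_tables(ev_a, ev_b, simple_hexamers)
        t2 = build_esr_hs_tables(ev_b, ev_a, simple_hexamers)
        for j in range(6):
            assert esr_hs(t1, "ESEloss", "AAAAAA", j) == pytest.approx(
                -esr_hs(t2, "ESEloss", "AAAAAA", j)
            )

    def test_unknown_hexamer_is_error(self, simple_hexamers):
        t = build_esr_hs_tables([], [], simple_hexamers)
        with pytest.raises(KeyError):
            esr_hs(t, "ESEloss", "GGGGGG", 0)


class TestVariantEsrHs:
    def test_no_transitions_all_zero(self):
        empty = HexamerSet(frozenset(), frozenset())
        t = manual_tables(0.5, 0.25, [1 / 6] * 6, [1 / 6] * 6)
        feats = variant_esr_hs_features("ACGTACGTACGTACGT", 7, "A", empty, t)
        assert all(v == 0.0 for v in feats.values())

    def test_single_window_score(self, simple_hexamers):
        # sequence where exactly one window is the ESE hexamer
        seq = "GGGGG" + "AAAAAA" + "GGGGG"
        t = manual_tables(0.5, 0.25, [1 / 3] * 6, [1 / 9] * 6)
        feats = variant_esr_hs_features(seq, 7, "C", simple_hexamers, t)
        assert feats["esrhs_ese_loss"] == pytest.approx(1 + math.log2(3))

    def test_max_rule_over_windows(self, simple_hexamers):
        # two overlapping ESE windows lost by one substitution: AAAAAAA
        # yields windows at offsets 0 and 1; give them different H scores
        seq = "AAAAAAA" + "GGGGGGGGG"
        h_d = [0.5, 0.25, 1 / 24, 1 / 24, 1 / 24, 1 / 8]
        t = manual_tables(0.25, 0.25, h_d, [1 / 6] * 6)
        feats = variant_esr_hs_features(seq, 1, "C", simple_hexamers, t)
        # windows: start 0 (j=1, log2(.25/(1/6))) and start 1 (j=0, log2(.5/(1/6)))
        assert feats["esrhs_ese_loss"] == pytest.approx(math.log2(0.5 * 6))
        feats_sum = variant_esr_hs_features(seq, 1, "C", simple_hexamers, t, agg="sum")
        assert feats_sum["esrhs_ese_loss"] == pytest.approx(
            math.log2(0.25 * 6) + math.log2(0.5 * 6)
        )


class TestDensity:
    def test_no_hits_zero(self, simple_hexamers):
        assert region_density("G" * 30, simple_hexamers, "ESE") == (0.0, True)

    def test_poly_a_region_density_one(self, simple_hexamers):
        d, ok = region_density("A" * 50, simple_hexamers, "ESE")
        assert ok and d == 1.0  # 45 of 45 windows

    def test_short_region_flagged(self, simple_hexamers):
        assert region_density("AAAA", simple_hexamers, "ESE") == (0.0, False)

    def test_short_exon_uses_full_length(self, toy_locus, simple_hexamers):
        from tests_helpers import middle_exon_context

        ctx = middle_exon_context(toy_locus)
        assert ctx.exon_len < 100
        prof = esr_density(ctx, simple_hexamers)
        assert prof.ese_density_start == prof.ese_density_end

    def test_density_matches_brute_force(self, small_world, rng):
        sets = small_world.hexamers
        bases = "ACGT"
        for _ in range(300):
            n = int(rng.integers(6, 120))
            region = "".join(bases[i] for i in rng.integers(0, 4, size=n))
            d, ok = region_density(region, sets, "ESE")
            brute = [region[s : s + 6] in sets.ese for s in range(n - 5)]
            assert ok and d == pytest.approx(sum(brute) / len(brute))
            assert 0.0 <= d <= 1.0


def test_transition_name_catalog_is_complete():
    """The change profile tracks exactly the nine ESE/ESS/neutral pairs."""
    assert len(TRANSITION_NAMES) == 9
    assert set(TRANSITION_NAMES) == {
        "ese_loss", "ese_ese", "ese_gain", "ese_to_ess", "neutral_neutral",
        "ess_ess", "ess_gain", "ess_loss", "ess_to_ese",
    }


def test_dual_transition_events(simple_hexamers):
    """ESE->ESS realizes both an ESE loss and an ESS gain."""
    seq = "GGGGG" + "AAAAAA" + "GGGGG"
    # mutate the run so the window becomes CCCCCC? single substitution cannot;
    # use a catalog where the mutant hexamer is an ESS
    sets = HexamerSet(frozenset({"AAAAAA"}), frozenset({"AACAAA"}))
    events = esr_transition_events(seq, 7, "C", sets)
    types = {t for t, _, _ in events}
    assert "ESEloss" in types and "ESSgain" in types
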