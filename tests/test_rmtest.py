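"""Substitution calling, masking, repositioning and the RM test."""

import dataclasses
import itertools

import numpy as np
import pytest

from trxflex import (
    EvolutionScenario,
    call_substitutions,
    evolve_pair,
    mask_nonsynonymous,
    observed_impact,
    random_cds,
    reposition_events,
    rm_test,
    summarize_selection,
)
from trxflex.rmtest import PairFilteredError, RMTestResult


class TestCallSubstitutions:
    def test_single_synonymous_transition(self):
        events = call_substitutions("AAA", "AAG", max_mismatch=1.0)
        assert len(events) == 1
        ev = events[0]
        assert (ev.position, ev.from_base, ev.to_base) == (2, "A", "G")
        assert ev.effect == "synonymous" and ev.kind == "transition"

    def test_single_nonsynonymous_transversion(self):
        (ev,) = call_substitutions("AAA", "ATA", max_mismatch=1.0)
        assert ev.effect == "non-synonymous" and ev.kind == "transversion"
        assert ev.pos_in_codon == 1

    def test_multi_hit_codon_single_site_rule(self, code):
        """TTA→CTG: each site judged alone against the ancestral codon."""
        events = call_substitutions("TTA", "CTG", max_mismatch=1.0)
        assert len(events) == 2
        assert all(ev.effect == "synonymous" for ev in events)
        assert all(ev.kind == "transition" for ev in events)
        # independent genetic-code check of the single-site rule
        assert code.translate("CTA") == code.translate("TTA")
        assert code.translate("TTG") == code.translate("TTA")

    def test_mismatch_filter(self):
        with pytest.raises(PairFilteredError):
            call_substitutions("AAAAAAAAA", "CCCAAAAAA")

    def test_unequal_lengths(self):
        with pytest.raises(ValueError):
            call_substitutions("AAAAAA", "AAA")


class TestMasking:
    def test_single_nonsyn_masked(self, scale):
        events = call_substitutions("AAA", "ATA", max_mismatch=1.0)
        masked = mask_nonsynonymous("AAA", "ATA", events)
        assert masked == "ATA"
        assert observed_impact("ATA", masked, scale) == 0.0

    def test_syn_kept_nonsyn_masked(self):
        events = call_substitutions("AAAAAA", "ATAAAG", max_mismatch=1.0)
        assert mask_nonsynonymous("AAAAAA", "ATAAAG", events) == "ATAAAA"

    def test_masked_translation_matches_extant(self, rng, code):
        """After masking, only synonymous contrasts remain."""
        for i in range(20):
            anc = random_cds(60, gc3_target=0.5, seed=int(rng.integers(2**31)))
            desc, events = evolve_pair(
                anc,
                EvolutionScenario(n_syn=4, n_nonsyn=3, seed=int(rng.integers(2**31))),
            )
            masked = mask_nonsynonymous(anc, desc, events)
            codon_hits = {}
            for ev in events:
                codon_hits.setdefault(ev.codon_index, []).append(ev)
            if all(len(v) == 1 for v in codon_hits.values()):
                assert code.translate(masked) == code.translate(desc.seq)


class TestObservedImpact:
    def test_identical_sequences(self, scale):
        assert observed_impact("ACGACG", "ACGACG", scale) == 0.0

    def test_uniform_scale_kills_contrast(self, uniform_scale):
        assert observed_impact("AAAA", "AAAG", uniform_scale) == 0.0

    def test_two_explicit_summations(self, scale):
        a, b = "AAAAAA", "AAAAGA"
        ta = np.mean([scale.values[a[i : i + 2]] for i in range(5)])
        tb = np.mean([scale.values[b[i : i + 2]] for i in range(5)])
        assert observed_impact(b, a, scale) == pytest.approx(abs(ta - tb))


def _oracle_candidates(masked, ev, window_bp, code):
    """Independent enumeration of legal target sites for one event."""
    half = window_bp // 2
    out = []
    for p in range(max(0, ev.position - half), min(len(masked), ev.position + half + 1)):
        if masked[p] != ev.from_base:
            continue
        ci, pc = divmod(p, 3)
        codon = masked[3 * ci : 3 * ci + 3]
        mutated = codon[:pc] + ev.to_base + codon[pc + 1 :]
        if code.translate(mutated) == code.translate(codon):
            out.append(p)
    return out


class TestReposition:
    def test_no_alternative_site_stays_put(self, code):
        anc = "TGGTGGAAATGGTGG"
        ext = anc[:8] + "G" + anc[9:]
        events = call_substitutions(anc, ext)
        assert _oracle_candidates(anc, events[0], 200, code) == [8]
        assert reposition_events(anc, events, rng=0) == ext

    def test_composition_preserved(self, rng):
        for i in range(10):
            anc = random_cds(50, gc3_target=0.5, seed=int(rng.integers(2**31)))
            desc, events = evolve_pair(
                anc, EvolutionScenario(n_syn=5, seed=int(rng.integers(2**31)))
            )
            rep = reposition_events(anc.seq, events, rng=int(rng.integers(2**31)))
            assert sorted(rep) == sorted(desc.seq)

    def test_exhaustive_enumeration_toy(self, code):
        """All distinct replicates of a 2-event toy match brute force."""
        anc = "AAAGGTAAAGGC"  # Lys Gly Lys Gly
        ext = "AAGGGTAAAGGT"  # syn events at pos 2 (A→G) and pos 11 (C→T)
        events = call_substitutions(anc, ext)
        assert [ev.effect for ev in events] == ["synonymous"] * 2
        cands = [_oracle_candidates(anc, ev, 200, code) for ev in events]
        expected = set()
        for t1, t2 in itertools.product(*cands):
            if t1 == t2:
                continue
            rep = list(anc)
            rep[t1] = events[0].to_base
            rep[t2] = events[1].to_base
            expected.add("".join(rep))
        seen = {
            reposition_events(anc, events, rng=i) for i in range(400)
        }
        assert seen == expected

    def test_same_base_policy_widens_candidates(self, code):
        """The literal same-base policy admits non-synonymous contexts."""
        anc = "AAAGGTATAGGC"
        ext = "AAGGGTATAGGC"
        events = call_substitutions(anc, ext)
        syn = set()
        literal = set()
        for i in range(300):
            syn.add(reposition_events(anc, events, rng=i))
            literal.add(
                reposition_events(anc, events, rng=i, candidate_policy="same_base")
            )
        assert syn <= literal and len(literal) > len(syn)


class TestRMTest:
    def test_no_synonymous_events_untestable(self, scale):
        res = rm_test("AAA", "ATA", scale, n_replicates=50, rng_seed=1, max_mismatch=1.0)
        assert res.call == "untestable"
        assert res.dtrx_obs == 0.0 and res.omega_gc3 is None

    def test_point_mass_null_untestable(self, scale):
        """A single candidate site forces an identity null."""
        anc = "TGGTGGAAATGGTGG"
        ext = anc[:8] + "G" + anc[9:]
        res = rm_test(anc, ext, scale, n_replicates=100, rng_seed=2)
        assert res.call == "untestable"
        assert res.p_lower == res.p_upper == 1.0
        assert res.omega_gc3 == pytest.approx(1.0)

    def test_seed_determinism(self, scale, rng):
        anc = random_cds(80, gc3_target=0.5, seed=7)
        desc, _ = evolve_pair(anc, EvolutionScenario(n_syn=6, seed=8))
        r1 = rm_test(anc, desc, scale, n_replicates=100, rng_seed=99)
        r2 = rm_test(anc, desc, scale, n_replicates=100, rng_seed=99)
        assert dataclasses.asdict(r1) == dataclasses.asdict(r2)
        r3 = rm_test(anc, desc, scale, n_replicates=100, rng_seed=100)
        assert dataclasses.asdict(r3) != dataclasses.asdict(r1)

    def test_result_fields_coherent(self, scale, rng):
        anc = random_cds(100, gc3_target=0.4, seed=3)
        desc, events = evolve_pair(
            anc, EvolutionScenario(n_syn=5, n_nonsyn=2, seed=4)
        )
        res = rm_test(anc, desc, scale, n_replicates=200, rng_seed=5)
        assert res.n_syn_events == 5 and res.n_nonsyn_events == 2
        assert 0 < res.p_lower <= 1 and 0 < res.p_upper <= 1
        assert res.omega_gc3 >= 0
        assert res.neutral_q025 <= res.neutral_q975


class TestSummarize:
    @staticmethod
    def _result(call):
        return RMTestResult(
            gene_id="g", n_syn_events=1, n_nonsyn_events=0, dtrx_obs=0.1,
            neutral_mean=0.1, neutral_sd=0.01, neutral_q025=0.05,
            neutral_q975=0.2, p_lower=0.5, p_upper=0.5, omega_gc3=1.0,
            call=call, n_replicates=10, seed=0,
        )

    def test_fractions(self):
        results = (
            [self._result("conserved")] * 3
            + [self._result("adaptive")]
            + [self._result("neutral")] * 6
        )
        s = summarize_selection(results)
        assert s == {"conserved": 0.3, "adaptive": 0.1, "tested": 10}

    def test_all_neutral(self):
        s = summarize_selection([self._result("neutral")] * 4)
        assert s["conserved"] == 0 and s["adaptive"] == 0 and s["tested"] == 4

    def test_untestable_excluded_and_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_selection([self._result("untestable")])
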