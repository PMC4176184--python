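"""Per-class dTRX impacts, NG86 dN/dS, variance F tests."""

import itertools
import math

import numpy as np
import pytest

from trxflex import (
    EvolutionScenario,
    call_substitutions,
    class_impacts,
    evolve_pair,
    impact_table,
    ng86_dnds,
    random_cds,
    trx_track,
    variance_f_test,
)


class TestClassImpacts:
    def test_identical_pair_all_zero(self, scale):
        seq = "ATGAAAGGG"
        vals = class_impacts(seq, seq, [], scale)
        assert all(v == 0.0 for v in vals.values())

    def test_uniform_scale_all_zero(self, uniform_scale):
        anc = random_cds(30, gc3_target=0.5, seed=1)
        desc, events = evolve_pair(anc, EvolutionScenario(n_syn=3, n_nonsyn=2, seed=2))
        vals = class_impacts(anc, desc, events, uniform_scale)
        assert all(v == pytest.approx(0.0) for v in vals.values())

    def test_single_class_hand_computation(self, scale):
        """One synonymous transition: direct per-codon difference sum."""
        anc = random_cds(10, gc3_target=0.5, seed=3)
        desc, events = evolve_pair(anc, EvolutionScenario(n_syn=1, seed=4))
        (ev,) = events
        vals = class_impacts(anc, desc, events, scale)
        variant = anc.seq[: ev.position] + ev.to_base + anc.seq[ev.position + 1 :]
        expected = (trx_track(anc.seq, scale) - trx_track(variant, scale)).sum() / 10
        key = "dtrx_syn_ts" if ev.kind == "transition" else "dtrx_syn_tv"
        assert vals[key] == pytest.approx(expected)
        assert all(v == 0.0 for k, v in vals.items() if k != key)


# -------------------------------------------------- independent NG86 oracle


def _oracle_ng86(a, e, code):
    """Brute-force NG86, structured independently of the implementation."""

    def syn_sites_of(codon):
        total = 0.0
        for pos in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if (
                    code.codon_to_aa[alt] == code.codon_to_aa[codon]
                ):
                    syn += 1
            total += syn / 3
        return total

    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, ce = a[i : i + 3], e[i : i + 3]
        S += (syn_sites_of(ca) + syn_sites_of(ce)) / 2
        N += 3 - (syn_sites_of(ca) + syn_sites_of(ce)) / 2
        positions = [k for k in range(3) if ca[k] != ce[k]]
        if not positions:
            continue
        paths = []
        blocked = []
        for perm in itertools.permutations(positions):
            cur, sd, nd, bad = ca, 0, 0, False
            for pos in perm:
                nxt = cur[:pos] + ce[pos] + cur[pos + 1 :]
                if code.codon_to_aa[nxt] == code.codon_to_aa[cur]:
                    sd += 1
                else:
                    nd += 1
                if code.codon_to_aa[nxt] == "*" and nxt != ce:
                    bad = True
                cur = nxt
            (blocked if bad else paths).append((sd, nd))
        use = paths if paths else blocked
        Sd += sum(p[0] for p in use) / len(use)
        Nd += sum(p[1] for p in use) / len(use)

    def jc(p):
        return -0.75 * math.log(1 - 4 * p / 3)

    return jc(Nd / N), jc(Sd / S)


class TestNG86:
    def test_identical_pair(self):
        dn, ds, omega = ng86_dnds("ATGAAAGGG", "ATGAAAGGG")
        assert dn == 0.0 and ds == 0.0 and omega is None

    def test_single_synonymous_difference(self):
        dn, ds, omega = ng86_dnds("ATGGGCGGAACC", "ATGGGCGGAACA")
        assert dn == 0.0 and ds > 0.0 and omega == 0.0

    def test_jc_domain_violation_signalled(self):
        # one codon, one synonymous difference: pS = 3 is uncorrectable
        with pytest.raises(ValueError, match="Jukes-Cantor"):
            ng86_dnds("AAA", "AAG")

    def test_oracle_equivalence_random_pairs(self, rng, code):
        """100 random short pairs agree with brute force to 1e-12."""
        checked = 0
        while checked < 100:
            anc = random_cds(10, gc3_target=float(rng.uniform(0.2, 0.8)),
                             seed=int(rng.integers(2**31)))
            desc, _ = evolve_pair(
                anc,
                EvolutionScenario(
                    n_syn=int(rng.integers(0, 3)),
                    n_nonsyn=int(rng.integers(0, 3)),
                    seed=int(rng.integers(2**31)),
                ),
            )
            try:
                dn, ds, _ = ng86_dnds(anc, desc)
            except ValueError:
                continue
            odn, ods = _oracle_ng86(anc.seq, desc.seq, code)
            assert dn == pytest.approx(odn, abs=1e-12)
            assert ds == pytest.approx(ods, abs=1e-12)
            checked += 1

    def test_agrees_with_biopython(self, rng):
        """Cross-library check against Bio.codonalign's NG86."""
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        checked = 0
        while checked < 20:
            anc = random_cds(30, gc3_target=0.5, seed=int(rng.integers(2**31)))
            desc, _ = evolve_pair(
                anc,
                EvolutionScenario(n_syn=2, n_nonsyn=2, seed=int(rng.integers(2**31))),
            )
            try:
                dn, ds, _ = ng86_dnds(anc, desc)
            except ValueError:
                continue
            bdn, bds = cal_dn_ds(CodonSeq(anc.seq), CodonSeq(desc.seq), method="NG86")
            assert dn == pytest.approx(bdn, abs=1e-6)
            assert ds == pytest.approx(bds, abs=1e-6)
            checked += 1

    def test_symmetry(self, rng):
        for _ in range(10):
            anc = random_cds(20, gc3_target=0.5, seed=int(rng.integers(2**31)))
            desc, _ = evolve_pair(
                anc, EvolutionScenario(n_syn=2, n_nonsyn=2, seed=int(rng.integers(2**31)))
            )
            f = ng86_dnds(anc, desc)
            b = ng86_dnds(desc, anc)
            assert f[0] == pytest.approx(b[0]) and f[1] == pytest.approx(b[1])


class TestVarianceFTest:
    def test_equal_distributions_f_near_one(self, rng):
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        f, p, n1, n2 = variance_f_test(x, y)
        assert f == pytest.approx(1.0, abs=0.15)
        assert p > 0.05

    def test_fourfold_variance_recovered(self, rng):
        x = rng.normal(scale=2.0, size=200)
        y = rng.normal(scale=1.0, size=200)
        f, p, _, _ = variance_f_test(x, y)
        assert 2.5 < f < 6.0
        assert p < 1e-6

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            variance_f_test([1.0, 2.0, 3.0], [1.0])


class TestImpactTable:
    def test_empty_panel_warns(self, scale):
        anc = "A" * 30
        ext = "C" * 9 + "A" * 21  # 30% mismatch: filtered
        with pytest.warns(UserWarning) as caught:
            tab = impact_table([(anc, ext)], scale)
        messages = [str(w.message) for w in caught]
        assert any("no pairs passed" in m for m in messages)
        assert tab.empty

    def test_single_pair_consistent_with_components(self, scale):
        anc = random_cds(50, gc3_target=0.5, seed=11, id="g1")
        desc, events = evolve_pair(anc, EvolutionScenario(n_syn=3, n_nonsyn=1, seed=12))
        tab = impact_table([(anc, desc)], scale)
        assert len(tab) == 1
        row = tab.iloc[0]
        vals = class_impacts(anc, desc, call_substitutions(anc, desc), scale)
        for key in ("dtrx_syn_ts", "dtrx_syn_tv", "dtrx_nonsyn_ts", "dtrx_nonsyn_tv"):
            assert row[key] == pytest.approx(vals[key])
        dn, ds, omega = ng86_dnds(anc, desc)
        assert row.dn == pytest.approx(dn) and row.ds == pytest.approx(ds)

    def test_filtered_pair_absent_from_table(self, scale):
        good = random_cds(50, gc3_target=0.5, seed=13, id="ok")
        gd, _ = evolve_pair(good, EvolutionScenario(n_syn=2, seed=14))
        bad_anc = "AAA" * 20
        bad_ext = "CCC" * 10 + "AAA" * 10
        with pytest.warns(UserWarning, match="mismatch filter"):
            tab = impact_table([(good, gd), (bad_anc, bad_ext)], scale)
        assert list(tab.gene_id) == ["ok"]
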