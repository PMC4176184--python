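"""The repositioned-mutation (RM) test of selection on DNA flexibility.

Simulates ancestor→descendant pairs under three regimes — neutral
(uniform placement of synonymous substitutions), flexibility-conserving
(events at sites of minimal TRX impact) and flexibility-altering
(maximal impact) — and shows how the test's calls and the selection
strength ω_GC3 respond.  ω_GC3 < 1 means the observed impact is smaller
than the neutral expectation (conservation); > 1 means larger.
"""

import numpy as np

import trxflex as tx

scale = tx.load_trx_scale("canonical")
root = np.random.default_rng(7)

print(f"{'placement':<12}{'conserved':>10}{'adaptive':>9}{'neutral':>8}{'mean w':>8}")
for placement in ("uniform", "flex_min", "flex_max"):
    calls = {"conserved": 0, "adaptive": 0, "neutral": 0}
    omegas = []
    for _ in range(40):
        ancestor = tx.random_cds(
            250, gc3_target=0.5, seed=int(root.integers(2**31))
        )
        descendant, _ = tx.evolve_pair(
            ancestor,
            tx.EvolutionScenario(
                n_syn=8, n_nonsyn=2, placement=placement,
                seed=int(root.integers(2**31)),
            ),
            scale=scale,
        )
        result = tx.rm_test(
            ancestor, descendant, scale,
            n_replicates=500, rng_seed=int(root.integers(2**31)),
        )
        if result.call in calls:
            calls[result.call] += 1
        if result.omega_gc3 is not None:
            omegas.append(result.omega_gc3)
    print(
        f"{placement:<12}{calls['conserved']:>10}{calls['adaptive']:>9}"
        f"{calls['neutral']:>8}{np.mean(omegas):>8.2f}"
    )

print(
    "\nUnder neutrality roughly 5% of genes are flagged (half per tail);"
    "\nflex_min inflates conserved calls with w << 1, flex_max inflates"
    "\nadaptive calls with w > 1."
)
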