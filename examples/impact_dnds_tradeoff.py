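"""Mutational impacts on flexibility (dTRX) versus protein-level dN/dS.

Builds a panel where protein-conserved genes (few non-synonymous events,
drift-scale synonymous placement) coexist with fast-evolving genes (many
non-synonymous events, flexibility-inert synonymous placement), then
compares the variance of the synonymous dTRX between the dN/dS < 1 and
dN/dS >= 1 groups with an F test.  F > 1 reproduces the empirical
pattern that synonymous flexibility impacts are widely dispersed in
protein-conserved genes and collapse toward zero in fast-evolving ones.
"""

import numpy as np

import trxflex as tx

scale = tx.load_trx_scale("canonical")
root = np.random.default_rng(11)

pairs = []
for i in range(120):
    anc = tx.random_cds(200, gc3_target=float(root.uniform(0.3, 0.7)),
                        seed=int(root.integers(2**31)), id=f"cons{i}")
    desc, _ = tx.evolve_pair(
        anc, tx.EvolutionScenario(n_syn=6, n_nonsyn=2,
                                  seed=int(root.integers(2**31))))
    pairs.append((anc, desc))
for i in range(30):
    anc = tx.random_cds(200, gc3_target=float(root.uniform(0.3, 0.7)),
                        seed=int(root.integers(2**31)), id=f"fast{i}")
    desc, _ = tx.evolve_pair(
        anc, tx.EvolutionScenario(n_syn=4, n_nonsyn=20, placement="flex_min",
                                  seed=int(root.integers(2**31))), scale=scale)
    pairs.append((anc, desc))

table = tx.impact_table(pairs, scale)
groups = table.groupby("group")["dtrx_syn"]
print(table.group.value_counts().to_string())
print("\nsynonymous dTRX by group (flexibility-score units per codon):")
print(groups.agg(["mean", "std"]).round(4).to_string())

conserved = table.loc[table.group == "conserved", "dtrx_syn"]
adaptive = table.loc[table.group == "adaptive", "dtrx_syn"]
f, p, n1, n2 = tx.variance_f_test(conserved, adaptive)
print(f"\nF = var(conserved)/var(adaptive) = {f:.2f}  (p = {p:.2g}, "
      f"n = {n1}/{n2})")
print("F > 1: conserved-protein genes carry the dispersed synonymous")
print("flexibility impacts; fast-evolving genes' impacts sit near zero.")
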