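# trxflex

Toolkit for quantifying the **intrinsic backbone flexibility of coding
DNA** and asking whether natural selection acts on it through synonymous
codon choice.

DNA's sugar-phosphate backbone switches between two conformational
substates (BI/BII); how often a given linkage switches is set by its
dinucleotide step, with G/C-containing steps far more flexible than
A/T-rich ones.  Because most synonymous variation lives at third codon
positions (GC3), synonymous codon choice tunes the flexibility of a
coding region without touching the protein.  `trxflex` provides the
statistics a molecular-evolution study of this layer needs:

* **TRX scoring** — per-sequence flexibility
  `TRX_seq = Σ TRX[MN] / (L−1)` over the L−1 dinucleotide linkages, and
  per-codon scores `TRX_cdn` (sum of the codon's two internal and two
  external linkages), using the experimental dinucleotide scale
  (% time in BII; scale midpoint 20.625).
* **Codon bias** — the entropy statistic `bias = 1 − Ew`, where Ew is
  the codon-count-weighted mean of per-family relative entropies
  `H_a / log2 k_a` of synonym usage.
* **The repositioned-mutation (RM) test** — for an ancestor/descendant
  pair, the observed synonymous flexibility impact
  `dTRX_syn = |TRX^extant − TRX^ancestral_masked|` is compared with a
  null built by repositioning the same substitutions to equivalent
  sites within local 200 bp windows (base composition held fixed,
  dinucleotide composition free).  Empirical two-tail p-values flag
  flexibility-conserving and flexibility-altering genes, and
  `ω_GC3 = dTRX_obs / mean(dTRX_neutral)` measures the strength of
  selection.
* **Protein-space envelopes** — per-codon min/max flexibility
  achievable by synonymous recoding, the mean ± 95% CI over 500
  synonymous randomizations, and the normalised deviation
  `devTRX_cdn = |TRX_cdn^real − TRX_cdn^syn| / |TRX_cdn^min − TRX_cdn^max|`.
* **Mutational-impact classes and dN/dS** — signed per-class impacts
  `dTRX = Σ (TRX_cdn^anc − TRX_cdn^ext)/n` for syn/non-syn ×
  transition/transversion, Nei–Gojobori dN/dS with Jukes–Cantor
  correction, and F tests of dTRX variance between ω < 1 and ω ≥ 1
  gene groups.
* **Genome-level trends** — unweighted genome summaries, GC→TRX
  correlation, and bias~TRX regressions fit separately below/above the
  scale midpoint (entropy bias is direction-blind, so the relation is
  V-shaped).
* **A synthetic-evolution generator** — in-frame CDS with controlled
  GC3 and amino-acid usage, ancestor→descendant pairs with specified
  synonymous/non-synonymous event counts, Ts:Tv odds and placement
  policy (neutral-uniform, flexibility-conserving, flexibility-
  altering), and multi-genome panels spanning a GC gradient — the
  package's null and power harness.

The package consumes plain FASTA of in-frame CDS; paired
ancestor/descendant inputs stand in for ancestral-reconstruction
pipelines (tree building and reconstruction are out of scope).

## Worked example

```python
import trxflex as tx

scale = tx.load_trx_scale("canonical")   # 16 steps, mean 20.625

# three synthetic genes across the GC3 range
for name, gc3 in [("at_rich", 0.05), ("balanced", 0.50), ("gc_rich", 0.95)]:
    g = tx.random_cds(300, gc3_target=gc3, seed=42, id=name)
    print(name, round(tx.trx_sequence(g, scale), 3),
          round(tx.entropy_bias(tx.codon_counts(g)), 3))
```

prints

```
at_rich 15.8 0.618
balanced 19.801 0.053
gc_rich 24.291 0.694
```

— flexibility (TRX) rises with GC3 while bias is high at *both*
extremes, the V-shaped pattern that motivates the midpoint-split
regression.  Running the RM test on simulated pairs
(`examples/rm_selection_test.py`, 40 genes per regime, 500 replicates):

```
placement     conserved adaptive neutral  mean w
uniform               0        1      39    1.07
flex_min             33        0       7    0.05
flex_max              7       11      22    1.26
```

Neutral placement is flagged at roughly the nominal 5% rate with
ω_GC3 ≈ 1; placement biased toward minimal flexibility impact is called
conserved with ω ≪ 1, and maximal-impact placement inflates the
adaptive tail with ω > 1.

The `examples/` directory holds one short script per capability
(scoring/bias, the RM test, envelopes and devTRX, dTRX–dN/dS tradeoffs,
genome-panel trends); each prints its numbers with a line on what they
mean.  A thin CLI mirrors the library:

```bash
trxflex simulate pair --n-genes 10 --out-prefix sim
trxflex rmtest --ancestors sim.ancestors.fasta --extants sim.extants.fasta \
               --reps 1000 --window 200 --seed 1 --out rm.tsv
trxflex envelope --cds sim.extants.fasta --out env.tsv --plot env.png
```

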