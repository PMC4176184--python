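# Methods

## Intrinsic flexibility scoring (TRX)

Every dinucleotide step is assigned a TRX score: the percentage of time
its sugar-phosphate linkage resides in the less stable BII backbone
conformation in solution, as measured by NMR meta-analysis (the
experimental TRX scale of Heddi and colleagues).  Higher values mean
more frequent BI↔BII switching, i.e. a more flexible backbone.  The
scale is shipped as a versioned 10-row TSV (`trxflex/data/trx_scale.tsv`)
and expanded to 16 entries by complementary-step symmetry
(`TRX[MN] = TRX[revcomp(MN)]`); a load-time gate requires the mean over
all 16 dinucleotides to equal 20.625 to 1e-9, which pins both the
transcription of the experimental numbers and the symmetry-weighting
convention (degenerate pairs counted twice, self-complementary steps
once).  G/C-containing steps are the flexible ones (CA/TG, CC/GG ≈ 42,
CG = 43), A/T-rich steps the stiff ones (AT = 0, AA/TT = 5), which is
why sequence flexibility tracks GC content so tightly.

For a sequence of length L the score is the mean over its L−1
overlapping linkages:

    TRX_seq = Σ_i TRX[s_i s_{i+1}] / (L − 1).

The per-codon score TRX_cdn is the **sum** of up to four linkage values:
the two internal linkages plus the two external linkages joining the
codon to its neighbours.  Terminal codons simply omit the missing
external linkage — no padding or renormalisation.  The choice matters
only at the two sequence ends and keeps the contract simple; an
alternative (rescaling 3-linkage codons by 4/3) would make terminal
codons incomparable across genes with different terminal bases.

Ambiguity codes are rejected at construction rather than guessed at:
an N scored as any concrete base silently shifts scores.

## Entropy-based codon bias (1 − Ew)

For each amino-acid family with k ≥ 2 synonyms, the relative entropy of
the observed synonym proportions is E_a = H_a / log2(k_a) with
H_a = −Σ p_i log2 p_i (base 2, so each E_a ∈ [0,1]); Ew is the
codon-count-weighted mean of E_a over the degenerate families present
in the gene, and bias = 1 − Ew.  Met, Trp and stops carry no choice and
are excluded; the six-fold families (Leu, Ser, Arg) are treated as
single k = 6 families; zero-count synonyms contribute 0·log 0 ≡ 0; a
family absent from the gene drops out of the weighted sum.  Bias is 1
when exactly one synonym per amino acid is used and 0 under perfectly
even usage, and is undefined (an error, not 0) for a gene containing no
degenerate-family codons.  Note that bias is direction-blind: AT3-skewed
and GC3-skewed genes can have identical bias, which is why genome-level
bias~flexibility trends are fit separately on each side of the scale
midpoint.

## The repositioned-mutation (RM) test

Substitutions between an ancestor and a descendant (equal-length,
in-frame; pairs with > 20% mismatching bases are discarded) are
classified synonymous/non-synonymous by substituting the single site
into the *ancestral* codon with the other two bases held fixed — a
deterministic, order-free rule that also makes simulated ground truth
round-trip exactly through calling — and transition/transversion from
the base pair.  Non-synonymous sites are masked by writing the
descendant base into the ancestor, so the remaining contrast isolates
synonymous changes:

    dTRX_obs = | TRX(descendant) − TRX(masked ancestor) |.

The null distribution repositions each synonymous event, independently
and without replacement across events, to a uniformly chosen site
within a 200 bp window centred on its original position, and records
the same contrast against the masked ancestor.  Two design points
deserve emphasis:

* **Null contrast.**  Defining the neutral impact as
  |TRX(descendant) − TRX(replicate)| (the "extant-vs-random" contrast)
  is degenerate: the identity repositioning then yields 0 while
  dTRX_obs does not, so observed and null are not exchangeable.  The
  default therefore contrasts every replicate against the masked
  ancestor, exactly as the observed statistic does; the extant-vs-
  random form remains available (`strict_extant_contrast=True`) for
  comparison.
* **Candidate sites.**  Repositioning targets are sites that carry the
  same masked-ancestral base *and* at which writing the event's new
  base is synonymous.  Restricting to same-base sites keeps
  mononucleotide composition fixed; restricting further to synonymous
  sites makes the candidate class exactly the class of sites neutral
  synonymous substitutions occupy, so a uniformly placed synonymous
  substitution is exchangeable with its repositioned copies by
  construction.  With candidates drawn from *all* same-base sites
  (available as `candidate_policy="same_base"`), the null acquires
  dinucleotide contexts that synonymous sites never occupy and the
  test's p-values drift measurably from uniform (KS p < 0.002 at 8
  events per 200-codon gene in our calibration runs).

With n replicates the empirical tail probabilities use the add-one
correction p = (r+1)/(n+1), avoiding p = 0 from finite resampling.  A
gene is called *conserved* if p_lower ≤ α/2, *adaptive* if
p_upper ≤ α/2 (α = 0.05 by default, i.e. 2.5% per tail), *untestable*
if it has no synonymous events or the null is a point mass (every
candidate assignment is forced), otherwise *neutral*.  The strength of
selection is

    ω_GC3 = dTRX_obs / mean(dTRX_neutral),

< 1 for flexibility conservation, > 1 for flexibility alteration.
Replicate i draws from a deterministic child stream of the test's seed,
so identical seeds give bit-identical results.

Defaults follow the study conditions: 1000 replicates, 200 bp windows,
α = 0.05.  The calibration and power suites run at 200 replicates to
keep the full test suite in minutes; the add-one p-value correction
makes the smaller replicate count conservative rather than anti-
conservative.

## Synonymous protein-space envelope and devTRX

For a fixed protein, the package computes per-codon tracks of the
observed TRX_cdn, the minimum/maximum achievable by synonymous recoding,
and the mean ± 95% CI over 500 uniform synonymous randomizations.  The
min/max sequences are built greedily left-to-right, each codon choosing
the synonym optimising its TRX_cdn given the already-chosen left
neighbour and the original right neighbour, ties broken by
lexicographic codon order.  Greedy recoding is the shipped default
because it mirrors the published construction; an exact dynamic program
over codon identities (transition cost = junction linkage + internal
linkages) is provided both as a strict mode and as the oracle the tests
use — greedy min is provably ≥ the DP min, and on random short genes
the DP matches exhaustive enumeration exactly.

The deviation statistic per codon is

    devTRX_cdn = |TRX_cdn^real − TRX_cdn^syn| / |TRX_cdn^min − TRX_cdn^max|,

with the numerator's reference being the randomization mean and the
denominator read from the greedy min/max tracks.  Codons whose min and
max coincide have no synonymous freedom and get devTRX = 0.  Because
min/max are whole-sequence optima read locally, devTRX can exceed 1 in
rare configurations; values are reported as computed, not clipped.  The
gene-level statistic is the unweighted mean over codons.

Tracks are smoothed with a centred moving average truncated (not
padded) at the edges; the 73 bp display window maps to round(73/3) = 24
codons on codon-level tracks.  Two CI bands are reported: the raw
per-codon percentile band, and a band obtained by smoothing each
randomized track *before* taking percentiles.  The former describes
single-codon variability and is wide; the latter shrinks with the
window and is the band a regionally extreme gene actually escapes —
region flags use it.

## Per-class impacts, dN/dS, and the variance F test

Substitutions are split into the four classes syn/non-syn ×
transition/transversion.  For class c the ancestor-only-with-class-c
variant is built and

    dTRX_c = Σ_codons (TRX_cdn^ancestral − TRX_cdn^variant_c) / n_codons,

kept signed (positive = flexibility lost).  dN/dS uses Nei–Gojobori
(1986) counting: per-codon synonymous site fractions averaged between
the two sequences, differences averaged over equally weighted
mutational pathways that avoid stop codons, and Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3); p ≥ 0.75 is uncorrectable and raises; ω is
reported as missing when dS = 0.  NG86 with equal path weighting is the
least-parameterised standard estimator; the choice is recorded here
because the original analysis does not name its estimator.  Genes are
grouped as functionally conserved (ω < 1) versus adaptively
evolving/drifting (ω ≥ 1) and an F test compares dTRX variances,
F = var(conserved)/var(adaptive) with a two-sided p — F is reported in
both directions (synonymous classes land above 1, non-synonymous below)
so no folding is applied.

## Synthetic evolution generator

The generator stands in for curated whole-genome alignments plus
ancestral reconstructions, and its defaults define the conditions the
test suites run under.

* `random_cds(n, gc3_target, usage_weights)` draws amino acids
  (uniform or weighted), then the third-position class (G/C vs A/T) as
  a Bernoulli draw at the GC3 target, then a uniform synonym within the
  class.  Families lacking a class (Met/Trp) clamp.
* `evolve_pair` plants a specified number of synonymous and
  non-synonymous single-base events at distinct positions, with
  transition:transversion odds 2:1 by default.  Eligibility and labels
  are judged against the ancestral codon, the same rule substitution
  calling uses.  Uniform synonymous placement is two-stage: change
  types are drawn from the Ts:Tv-weighted pool of (site, change)
  options, then positions are re-assigned by the same random-order,
  without-replacement uniform scheme the RM repositioning uses — so
  the RM test's null holds for uniform pairs by construction (one-stage
  joint sampling leaves a small conditional non-uniformity of position
  given change type, detectable as KS p ≈ 0.006 at 8 events/gene).
  `flex_min`/`flex_max` placement ranks the options by per-event
  |ΔTRX| and samples ranks with a truncated geometric preference
  (strength 0.5 by default), emulating selection that conserves or
  alters backbone dynamics.  Non-synonymous events avoid creating stop
  codons.
* `genome_panel` produces genomes with evenly spaced overall-GC
  targets.  Each genome couples an exponentially tilted amino-acid
  usage (solving a 1-D root for the first-two-position GC level) with a
  GC3 target spanning nearly [0,1] across the panel, mimicking how real
  clades reach extreme compositions through both amino-acid usage and
  synonymous choice.  Default panel: 24 genomes over GC 0.15–0.72,
  emulating a clade set that ranges from an AT-extreme endosymbiont to
  high-GC taxa.

What the generator does **not** emulate: phylogenetic structure (pairs
only, no trees), indels, context-dependent mutation bias, regional
composition heterogeneity within a gene, and any direct coupling of
codon usage to expression.  Calibration and power results on synthetic
pairs therefore certify the statistical machinery — exchangeability
under the null, sensitivity to impact-biased placement — not the
realism of any biological inference on real alignments.

## Genome-level trends

Genome summaries are unweighted means of per-gene statistics
(length-weighted aggregation is available by flag).  Because bias is
direction-blind, bias~TRX is fit as two separate OLS regressions for
genomes below/above the scale midpoint 20.625; GC→TRX dependence is a
single Pearson correlation.  On the default synthetic panel the GC→TRX
correlation exceeds 0.999 and the two bias~TRX slopes are negative
below and positive above the midpoint.

## Numerical and interface conventions

Positions are 0-based internally and 1-based in all user-facing tables.
Inputs are assumed coding-strand CDS.  Every stochastic routine takes a
single seed; replicate streams are spawned deterministically from it,
and output tables carry the tool version, a configuration hash and the
seed in their headers.  Problem sizes used by the shipped suites: 500
genes × 200 replicates for calibration, 150 genes per placement policy
for power, a 24-genome × ~100 kb panel for composition trends, and
exhaustive enumeration on genes of ≤ 6 codons for envelope optimality.

## Known limitations

* TRX is a lookup score; no structural prediction (groove geometry,
  roll/twist) is attempted, and methylation effects on backbone
  dynamics are out of scope.
* The RM test treats each ancestor/descendant pair independently; it
  does not model shared ancestry between pairs from one alignment.
* Greedy min/max envelopes are not guaranteed per-codon optima of any
  global criterion; the DP mode gives exact whole-sequence optima, and
  per-codon reads of either can cross in rare configurations.
* dN/dS is a counting estimator; no ML codon models are provided, so ω
  near saturation or with very few events is noisy.
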