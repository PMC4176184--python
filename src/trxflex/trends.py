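"""Genome-level aggregation and midpoint-inflected regressions.

Genome summaries average per-gene statistics (codon bias, GC, GC3, TRX)
without length weighting.  Because entropy-based codon bias is blind to
the *direction* of bias, its relation to mean flexibility is V-shaped
around the TRX scale midpoint (20.625, the mean of the canonical scale):
genomes are split at the midpoint and each side gets its own ordinary
least-squares fit of mean bias on mean TRX.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .codonstats import codon_counts, entropy_bias, gc3_content, gc_content
from .rmtest import RMTestResult, summarize_selection
from .scale import CANONICAL_MIDPOINT, TRXScale, trx_sequence


@dataclass
class GenomeSummary:
    genome_id: str
    mean_gc: float
    mean_gc3: float
    mean_bias: float
    mean_trx: float
    n_genes: int
    frac_conserved: float = float("nan")
    frac_adaptive: float = float("nan")


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def summarize_genome(
    genes: Sequence,
    scale: TRXScale,
    rm_results: Optional[Sequence[RMTestResult]] = None,
    genome_id: str = "",
    length_weighted: bool = False,
) -> GenomeSummary:
    """Unweighted per-gene means of GC, GC3, bias and TRX for one genome.

    ``length_weighted=True`` weights each gene by its length instead.
    """
    if not genes:
        raise ValueError("empty gene set")
    gc = np.array([gc_content(g) for g in genes])
    gc3 = np.array([gc3_content(g) for g in genes])
    bias = np.array([entropy_bias(codon_counts(g)) for g in genes])
    trx = np.array([trx_sequence(g, scale) for g in genes])
    if length_weighted:
        w = np.array([len(g.seq) for g in genes], dtype=float)
        w /= w.sum()
    else:
        w = np.full(len(genes), 1.0 / len(genes))
    frac_c = frac_a = float("nan")
    if rm_results:
        summary = summarize_selection(rm_results)
        frac_c, frac_a = summary["conserved"], summary["adaptive"]
    return GenomeSummary(
        genome_id=genome_id,
        mean_gc=float(gc @ w),
        mean_gc3=float(gc3 @ w),
        mean_bias=float(bias @ w),
        mean_trx=float(trx @ w),
        n_genes=len(genes),
        frac_conserved=frac_c,
        frac_adaptive=frac_a,
    )


def inflected_regression(
    summaries: Sequence[GenomeSummary],
    midpoint: float = CANONICAL_MIDPOINT,
    x_field: str = "mean_trx",
    y_field: str = "mean_bias",
) -> Dict[str, Optional[RegressionFit]]:
    """Separate OLS fits of y on x for genomes below/above the midpoint.

    A side with fewer than 3 genomes is reported as None.
    """
    out: Dict[str, Optional[RegressionFit]] = {}
    x_all = np.array([getattr(s, x_field) for s in summaries])
    y_all = np.array([getattr(s, y_field) for s in summaries])
    for side, mask in (("below", x_all < midpoint), ("above", x_all >= midpoint)):
        if mask.sum() < 3:
            out[side] = None
            continue
        res = stats.linregress(x_all[mask], y_all[mask])
        out[side] = RegressionFit(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r=float(res.rvalue),
            p=float(res.pvalue),
            n=int(mask.sum()),
        )
    return out


def correlate_summaries(
    summaries: Sequence[GenomeSummary], x_field: str, y_field: str
) -> Dict[str, float]:
    """Pearson correlation of two summary fields across genomes."""
    if len(summaries) < 3:
        raise ValueError("need at least 3 summaries")
    x = np.array([getattr(s, x_field) for s in summaries])
    y = np.array([getattr(s, y_field) for s in summaries])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant field; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(summaries)}
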