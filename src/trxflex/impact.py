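"""Per-class mutational impacts on flexibility, dN/dS, and variance F tests.

Substitutions between an ancestor/descendant pair are partitioned into
four classes — synonymous/non-synonymous × transition/transversion —
and each class's average impact on codon flexibility is

    dTRX_c = Σ_codons (TRX_cdn^ancestral − TRX_cdn^variant_c) / n_codons

where variant_c is the ancestor with only the class-c events applied.
The sign is kept as written (positive = flexibility lost in the
descendant).  dN/dS is estimated by Nei–Gojobori (1986) pathway counting
with Jukes–Cantor correction; genes are grouped as functionally
conserved (dN/dS < 1) versus adaptively evolving/drifting (dN/dS ≥ 1),
and an F test compares the variance of dTRX between the groups.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import GeneticCode, get_code
from .rmtest import (
    MAX_MISMATCH_FRACTION,
    PairFilteredError,
    SubstitutionEvent,
    call_substitutions,
)
from .scale import TRXScale, trx_track

CLASSES = (
    ("synonymous", "transition", "dtrx_syn_ts"),
    ("synonymous", "transversion", "dtrx_syn_tv"),
    ("non-synonymous", "transition", "dtrx_nonsyn_ts"),
    ("non-synonymous", "transversion", "dtrx_nonsyn_tv"),
)


@dataclass
class ImpactRecord:
    gene_id: str
    n_codons: int
    dtrx_syn_ts: float
    dtrx_syn_tv: float
    dtrx_nonsyn_ts: float
    dtrx_nonsyn_tv: float
    n_events: Dict[str, int]
    dn: float
    ds: float
    omega: Optional[float]
    group: Optional[str]  # "conserved" (dN/dS<1) | "adaptive" (dN/dS>=1)
    filtered: bool = False


def class_impacts(
    ancestor, extant, events: Sequence[SubstitutionEvent], scale: TRXScale
) -> Dict[str, float]:
    """Signed per-class dTRX values (flexibility-score units per codon)."""
    a = ancestor.seq if hasattr(ancestor, "seq") else str(ancestor).upper()
    anc_track = trx_track(a, scale)
    n_codons = anc_track.size
    out = {}
    for effect, kind, name in CLASSES:
        sel = [ev for ev in events if ev.effect == effect and ev.kind == kind]
        if not sel:
            out[name] = 0.0
            continue
        variant = list(a)
        for ev in sel:
            variant[ev.position] = ev.to_base
        var_track = trx_track("".join(variant), scale)
        out[name] = float((anc_track - var_track).sum() / n_codons)
    return out


# ---------------------------------------------------------------- NG86


def _syn_fraction(codon: str, pos: int, code: GeneticCode) -> float:
    """Fraction of the 3 possible changes at this position that are
    synonymous.  Changes creating a stop codon count as non-synonymous."""
    aa = code.codon_to_aa[codon]
    n_syn = 0
    for b in "ACGT":
        if b == codon[pos]:
            continue
        mutated = codon[:pos] + b + codon[pos + 1 :]
        if code.codon_to_aa[mutated] == aa:
            n_syn += 1
    return n_syn / 3.0


def _codon_sites(codon: str, code: GeneticCode) -> Tuple[float, float]:
    """(synonymous, non-synonymous) site counts of one codon."""
    s = sum(_syn_fraction(codon, p, code) for p in range(3))
    return s, 3.0 - s


def _pathway_differences(
    c1: str, c2: str, code: GeneticCode
) -> Tuple[float, float]:
    """(syn, non-syn) differences between two codons, averaged over all
    mutational pathways that avoid stop codons.

    Each of the k! orderings of the k differing positions is one
    pathway; a step is synonymous if it leaves the amino acid unchanged.
    Pathways passing through a stop codon are excluded; if every pathway
    is excluded (only possible when one endpoint is itself a stop) all
    pathways are used.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    fallback = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code.codon_to_aa[nxt] == code.codon_to_aa[cur]:
                sd += 1
            else:
                nd += 1
            if code.codon_to_aa[nxt] == "*" and nxt != c2:
                through_stop = True
            cur = nxt
        fallback.append((sd, nd))
        if not through_stop:
            results.append((sd, nd))
    use = results or fallback
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = −(3/4)·ln(1 − 4p/3)."""
    if p >= 0.75:
        raise ValueError(f"proportion {p} is outside the Jukes-Cantor domain")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_dnds(
    ancestor, extant, code: GeneticCode | None = None
) -> Tuple[float, float, Optional[float]]:
    """Nei–Gojobori (1986) dN, dS and omega for an in-frame pair.

    Site counts are averaged between the two sequences; differences are
    averaged over equally weighted mutational pathways; both proportions
    are Jukes–Cantor corrected.  omega is None when dS = 0.
    """
    code = code or get_code()
    a = ancestor.seq if hasattr(ancestor, "seq") else str(ancestor).upper()
    e = extant.seq if hasattr(extant, "seq") else str(extant).upper()
    if len(a) != len(e) or len(a) % 3:
        raise ValueError("pair must be equal-length and in frame")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, ce = a[i : i + 3], e[i : i + 3]
        sa, na = _codon_sites(ca, code)
        se, ne = _codon_sites(ce, code)
        S += (sa + se) / 2
        N += (na + ne) / 2
        sd, nd = _pathway_differences(ca, ce, code)
        Sd += sd
        Nd += nd
    ds = jukes_cantor(Sd / S) if S > 0 else 0.0
    dn = jukes_cantor(Nd / N) if N > 0 else 0.0
    omega = dn / ds if ds > 0 else None
    return dn, ds, omega


def variance_f_test(
    dtrx_conserved: Sequence[float], dtrx_adaptive: Sequence[float]
) -> Tuple[float, float, int, int]:
    """F test of equal dTRX variance between gene groups.

    Returns (F, two-sided p, n_conserved, n_adaptive) with
    F = var(conserved)/var(adaptive); F > 1 means the functionally
    conserved group is more variable.
    """
    x = np.asarray(dtrx_conserved, dtype=float)
    y = np.asarray(dtrx_adaptive, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 observations")
    f = float(x.var(ddof=1) / y.var(ddof=1))
    dist = stats.f(x.size - 1, y.size - 1)
    p = 2 * min(dist.cdf(f), dist.sf(f))
    return f, float(min(p, 1.0)), x.size, y.size


def impact_record(
    ancestor, extant, scale: TRXScale, code: GeneticCode | None = None
) -> ImpactRecord:
    """All per-gene impact statistics for one passing pair."""
    code = code or get_code()
    gene_id = getattr(extant, "id", None) or getattr(ancestor, "id", "") or ""
    events = call_substitutions(ancestor, extant, code=code)
    impacts = class_impacts(ancestor, extant, events, scale)
    dn, ds, omega = ng86_dnds(ancestor, extant, code=code)
    n_events = {
        name: sum(1 for ev in events if ev.effect == eff and ev.kind == kind)
        for eff, kind, name in CLASSES
    }
    group = None
    if omega is not None:
        group = "conserved" if omega < 1 else "adaptive"
    a = ancestor.seq if hasattr(ancestor, "seq") else str(ancestor)
    return ImpactRecord(
        gene_id=gene_id,
        n_codons=len(a) // 3,
        n_events=n_events,
        dn=dn,
        ds=ds,
        omega=omega,
        group=group,
        **impacts,
    )


def impact_table(
    pairs: Sequence[Tuple[object, object]],
    scale: TRXScale,
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """One row per gene over a panel of (ancestor, extant) pairs.

    Pairs failing the 20% base-mismatch filter are skipped with a
    warning and appear in no row.
    """
    rows: List[dict] = []
    n_filtered = 0
    for anc, ext in pairs:
        try:
            rec = impact_record(anc, ext, scale, code=code)
        except PairFilteredError:
            n_filtered += 1
            continue
        rows.append(
            {
                "gene_id": rec.gene_id,
                "n_codons": rec.n_codons,
                "dn": rec.dn,
                "ds": rec.ds,
                "omega": np.nan if rec.omega is None else rec.omega,
                "dtrx_syn_ts": rec.dtrx_syn_ts,
                "dtrx_syn_tv": rec.dtrx_syn_tv,
                "dtrx_nonsyn_ts": rec.dtrx_nonsyn_ts,
                "dtrx_nonsyn_tv": rec.dtrx_nonsyn_tv,
                "dtrx_syn": rec.dtrx_syn_ts + rec.dtrx_syn_tv,
                "dtrx_nonsyn": rec.dtrx_nonsyn_ts + rec.dtrx_nonsyn_tv,
                "group": rec.group,
            }
        )
    if n_filtered:
        warnings.warn(
            f"{n_filtered} pair(s) exceeded the "
            f"{MAX_MISMATCH_FRACTION:.0%} mismatch filter and were skipped",
            stacklevel=2,
        )
    if not rows:
        warnings.warn("no pairs passed the filter; empty table", stacklevel=2)
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "n_codons",
            "dn",
            "ds",
            "omega",
            "dtrx_syn_ts",
            "dtrx_syn_tv",
            "dtrx_nonsyn_ts",
            "dtrx_nonsyn_tv",
            "dtrx_syn",
            "dtrx_nonsyn",
            "group",
        ],
    )
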