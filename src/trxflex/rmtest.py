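"""The repositioned-mutation (RM) test of selection on DNA flexibility.

Given an ancestor/descendant pair of in-frame coding sequences, the test
asks whether the observed synonymous substitutions changed the
sequence's intrinsic flexibility (TRX score) more or less than the same
substitutions would have under drift.  The null distribution is built by
randomly repositioning each synonymous event to another site carrying
the same ancestral base within a local window (200 bp by default), so
mononucleotide composition is held fixed while dinucleotide composition
— hence TRX — is free to vary.

Procedure:

1. Call substitutions between ancestor and descendant; classify each as
   synonymous/non-synonymous (by substituting that single site into the
   ancestral codon) and transition/transversion.
2. Mask non-synonymous events by writing the descendant base into the
   ancestor, leaving a pair that differs only at synonymous sites.
3. The observed impact is dTRX_obs = |TRX(descendant) − TRX(masked
   ancestor)|.
4. Each of ``n_replicates`` neutral replicates repositions every
   synonymous event to a uniformly chosen same-base site within its
   window and records the same contrast against the masked ancestor.
5. Empirical tail probabilities use the add-one correction
   (r+1)/(n+1); a gene is called ``conserved`` (flexibility-preserving,
   lower tail) or ``adaptive`` (flexibility-altering, upper tail) at
   alpha/2 per tail.  ω_GC3 = dTRX_obs / mean(dTRX_neutral) summarises
   the strength of selection (<1 conserving, >1 altering).

A ``strict_extant_contrast`` mode is provided in which the neutral
impact is computed as |TRX(descendant) − TRX(replicate)| instead; under
identity repositioning that contrast is zero while the observed impact
is not, which makes observed and null incomparable, so the masked-
ancestor contrast is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence

import numpy as np

from .genetics import BASES, CodingSequence, GeneticCode, decode, encode, get_code, is_transition
from .scale import TRXScale

DEFAULT_WINDOW_BP = 200
DEFAULT_REPLICATES = 1000
DEFAULT_ALPHA = 0.05
MAX_MISMATCH_FRACTION = 0.20


class PairFilteredError(ValueError):
    """Raised when a pair exceeds the base-mismatch filter (default 20%)."""


@dataclass(frozen=True)
class SubstitutionEvent:
    """One inferred single-base substitution."""

    position: int  # 0-based nucleotide index
    from_base: str
    to_base: str
    codon_index: int
    pos_in_codon: int  # 0/1/2
    effect: Literal["synonymous", "non-synonymous"]
    kind: Literal["transition", "transversion"]


@dataclass
class RMTestResult:
    gene_id: str
    n_syn_events: int
    n_nonsyn_events: int
    dtrx_obs: float
    neutral_mean: float
    neutral_sd: float
    neutral_q025: float
    neutral_q975: float
    p_lower: float
    p_upper: float
    omega_gc3: Optional[float]
    call: Literal["conserved", "adaptive", "neutral", "untestable"]
    n_replicates: int
    seed: Optional[int]


def call_substitutions(
    ancestor,
    extant,
    code: GeneticCode | None = None,
    max_mismatch: float = MAX_MISMATCH_FRACTION,
) -> List[SubstitutionEvent]:
    """List all single-base substitutions between an in-frame pair.

    A site's synonymous/non-synonymous status is judged by substituting
    only that site into the *ancestral* codon, holding the other two
    ancestral bases fixed — deterministic and independent of the order
    multiple hits within a codon are considered.
    """
    code = code or get_code()
    a = ancestor.seq if hasattr(ancestor, "seq") else str(ancestor).upper()
    e = extant.seq if hasattr(extant, "seq") else str(extant).upper()
    if len(a) != len(e):
        raise ValueError(f"length mismatch: {len(a)} vs {len(e)}")
    if len(a) % 3:
        raise ValueError(f"length {len(a)} is not a multiple of 3")
    diff = [i for i in range(len(a)) if a[i] != e[i]]
    if len(diff) / len(a) > max_mismatch:
        raise PairFilteredError(
            f"mismatch fraction {len(diff) / len(a):.3f} exceeds {max_mismatch}"
        )
    events = []
    for pos in diff:
        ci, pc = divmod(pos, 3)
        codon = a[3 * ci : 3 * ci + 3]
        syn = code.is_synonymous_change(codon, pc, e[pos])
        events.append(
            SubstitutionEvent(
                position=pos,
                from_base=a[pos],
                to_base=e[pos],
                codon_index=ci,
                pos_in_codon=pc,
                effect="synonymous" if syn else "non-synonymous",
                kind="transition" if is_transition(a[pos], e[pos]) else "transversion",
            )
        )
    return events


def mask_nonsynonymous(ancestor, extant, events: Sequence[SubstitutionEvent]) -> str:
    """Write the extant base into the ancestor at every non-synonymous site.

    The returned masked ancestor differs from the extant sequence only at
    synonymous event positions, so the subsequent TRX contrast isolates
    the synonymous substitutions.
    """
    a = list(ancestor.seq if hasattr(ancestor, "seq") else str(ancestor).upper())
    e = extant.seq if hasattr(extant, "seq") else str(extant).upper()
    if len(a) != len(e):
        raise ValueError("length mismatch")
    for ev in events:
        if a[ev.position] != ev.from_base or e[ev.position] != ev.to_base:
            raise ValueError(f"event at {ev.position} does not match the pair")
        if ev.effect == "non-synonymous":
            a[ev.position] = ev.to_base
    return "".join(a)


def observed_impact(extant, masked_ancestor, scale: TRXScale) -> float:
    """dTRX_obs = |TRX(extant) − TRX(masked ancestor)|."""
    from .scale import trx_sequence

    return abs(trx_sequence(extant, scale) - trx_sequence(masked_ancestor, scale))


def _candidate_sites(
    codes: np.ndarray,
    events: Sequence[SubstitutionEvent],
    window_bp: int,
    candidate_policy: str = "synonymous",
    code: GeneticCode | None = None,
) -> List[np.ndarray]:
    """Per-event candidate target positions within ±window_bp/2.

    ``synonymous`` (default): same masked-ancestral base *and* writing the
    event's to-base there is synonymous — exactly the site class neutral
    synonymous substitutions occupy, so uniform neutral evolution matches
    the repositioning distribution by construction.  ``same_base``: any
    site with the same masked-ancestral base, which holds mononucleotide
    composition fixed but mixes synonymous and non-synonymous contexts.
    The original position always qualifies under both policies.
    """
    code = code or get_code()
    half = window_bp // 2
    seq = decode(codes)
    out = []
    for ev in events:
        lo, hi = max(0, ev.position - half), min(codes.size, ev.position + half + 1)
        local = np.nonzero(codes[lo:hi] == BASES.index(ev.from_base))[0] + lo
        if candidate_policy == "synonymous":
            keep = []
            for p in local:
                ci, pc = divmod(int(p), 3)
                codon = seq[3 * ci : 3 * ci + 3]
                if code.is_synonymous_change(codon, pc, ev.to_base):
                    keep.append(int(p))
            if ev.position not in keep:
                keep.append(ev.position)
            local = np.array(sorted(keep), dtype=int)
        elif candidate_policy != "same_base":
            raise ValueError(f"unknown candidate policy {candidate_policy!r}")
        out.append(local)
    return out


def _assign_targets(
    candidates: List[np.ndarray],
    events: Sequence[SubstitutionEvent],
    rng: np.random.Generator,
) -> List[int]:
    """Choose one target site per event, without replacement.

    Events are visited in random order; each draws uniformly among its
    candidate sites not yet claimed by an earlier event.  If every
    candidate is claimed (possible only when another event landed on this
    event's own site), the event falls back to its original position.
    """
    order = rng.permutation(len(candidates))
    taken: set = set()
    targets = [0] * len(candidates)
    for i in order:
        cand = candidates[i]
        if taken:
            cand = cand[~np.isin(cand, list(taken))]
        if cand.size == 0:
            target = events[i].position
        else:
            target = int(cand[rng.integers(cand.size)])
        taken.add(target)
        targets[i] = target
    return targets


def reposition_events(
    masked_ancestor,
    syn_events: Sequence[SubstitutionEvent],
    window_bp: int = DEFAULT_WINDOW_BP,
    rng: np.random.Generator | int | None = None,
    candidate_policy: str = "synonymous",
    code: GeneticCode | None = None,
) -> str:
    """One neutral replicate: synonymous events moved to candidate sites."""
    rng = np.random.default_rng(rng)
    codes = encode(
        masked_ancestor.seq
        if hasattr(masked_ancestor, "seq")
        else str(masked_ancestor).upper()
    )
    candidates = _candidate_sites(
        codes, syn_events, window_bp, candidate_policy, code
    )
    targets = _assign_targets(candidates, syn_events, rng)
    out = codes.copy()
    for ev, t in zip(syn_events, targets):
        out[t] = BASES.index(ev.to_base)
    return decode(out)


def _delta_linkage_sum(
    base_codes: np.ndarray,
    base_linkage: np.ndarray,
    matrix: np.ndarray,
    positions: np.ndarray,
    new_codes: np.ndarray,
) -> float:
    """Change in the total linkage sum when ``positions`` take ``new_codes``."""
    work = base_codes.copy()
    work[positions] = new_codes
    links = np.unique(
        np.clip(
            np.concatenate([positions - 1, positions]), 0, base_codes.size - 2
        )
    )
    new_vals = matrix[work[links], work[links + 1]]
    return float(new_vals.sum() - base_linkage[links].sum())


def rm_test(
    ancestor,
    extant,
    scale: TRXScale,
    n_replicates: int = DEFAULT_REPLICATES,
    window_bp: int = DEFAULT_WINDOW_BP,
    alpha: float = DEFAULT_ALPHA,
    rng_seed: int | None = 0,
    code: GeneticCode | None = None,
    strict_extant_contrast: bool = False,
    candidate_policy: str = "synonymous",
    max_mismatch: float = MAX_MISMATCH_FRACTION,
) -> RMTestResult:
    """Run the RM test on one ancestor/descendant pair.

    Identical ``rng_seed`` values give bit-identical results; replicate i
    draws from a deterministic child stream of the seed.
    """
    gene_id = getattr(extant, "id", None) or getattr(ancestor, "id", "") or ""
    events = call_substitutions(ancestor, extant, code=code, max_mismatch=max_mismatch)
    syn_events = [ev for ev in events if ev.effect == "synonymous"]
    n_nonsyn = len(events) - len(syn_events)
    masked = mask_nonsynonymous(ancestor, extant, events)
    masked_codes = encode(masked)
    L = masked_codes.size
    matrix = scale.matrix
    base_linkage = matrix[masked_codes[:-1], masked_codes[1:]]
    base_sum = float(base_linkage.sum())

    ext_codes = encode(extant.seq if hasattr(extant, "seq") else str(extant).upper())
    obs_positions = np.array([ev.position for ev in syn_events], dtype=int)
    obs_new = ext_codes[obs_positions] if obs_positions.size else obs_positions
    if obs_positions.size:
        obs_delta = _delta_linkage_sum(
            masked_codes, base_linkage, matrix, obs_positions, obs_new
        )
    else:
        obs_delta = 0.0
    dtrx_obs = abs(obs_delta) / (L - 1)

    if not syn_events:
        return RMTestResult(
            gene_id=gene_id,
            n_syn_events=0,
            n_nonsyn_events=n_nonsyn,
            dtrx_obs=0.0,
            neutral_mean=float("nan"),
            neutral_sd=float("nan"),
            neutral_q025=float("nan"),
            neutral_q975=float("nan"),
            p_lower=1.0,
            p_upper=1.0,
            omega_gc3=None,
            call="untestable",
            n_replicates=n_replicates,
            seed=rng_seed,
        )
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    candidates = _candidate_sites(
        masked_codes, syn_events, window_bp, candidate_policy, code
    )
    to_codes = np.array([BASES.index(ev.to_base) for ev in syn_events], dtype=np.uint8)

    ss = np.random.SeedSequence(rng_seed)
    child_rngs = [np.random.default_rng(s) for s in ss.spawn(n_replicates)]
    neutral = np.empty(n_replicates)
    for i, crng in enumerate(child_rngs):
        targets = np.array(
            _assign_targets(candidates, syn_events, crng), dtype=int
        )
        delta = _delta_linkage_sum(
            masked_codes, base_linkage, matrix, targets, to_codes
        )
        if strict_extant_contrast:
            # |TRX(extant) − TRX(replicate)| as printed; see module docstring
            neutral[i] = abs(obs_delta - delta) / (L - 1)
        else:
            neutral[i] = abs(delta) / (L - 1)

    n = n_replicates
    p_lower = (int(np.sum(neutral <= dtrx_obs + 1e-15)) + 1) / (n + 1)
    p_upper = (int(np.sum(neutral >= dtrx_obs - 1e-15)) + 1) / (n + 1)
    neutral_mean = float(neutral.mean())
    omega = dtrx_obs / neutral_mean if neutral_mean > 0 else None

    if np.ptp(neutral) == 0.0:
        call = "untestable"
    elif p_lower <= alpha / 2:
        call = "conserved"
    elif p_upper <= alpha / 2:
        call = "adaptive"
    else:
        call = "neutral"

    return RMTestResult(
        gene_id=gene_id,
        n_syn_events=len(syn_events),
        n_nonsyn_events=n_nonsyn,
        dtrx_obs=dtrx_obs,
        neutral_mean=neutral_mean,
        neutral_sd=float(neutral.std(ddof=1)) if n > 1 else 0.0,
        neutral_q025=float(np.quantile(neutral, 0.025)),
        neutral_q975=float(np.quantile(neutral, 0.975)),
        p_lower=p_lower,
        p_upper=p_upper,
        omega_gc3=omega,
        call=call,
        n_replicates=n,
        seed=rng_seed,
    )


def summarize_selection(results: Sequence[RMTestResult]) -> Dict[str, float]:
    """Genome-level fractions of testable genes called conserved/adaptive."""
    testable = [r for r in results if r.call != "untestable"]
    if not testable:
        raise ValueError("no testable results to summarise")
    n = len(testable)
    return {
        "conserved": sum(r.call == "conserved" for r in testable) / n,
        "adaptive": sum(r.call == "adaptive" for r in testable) / n,
        "tested": n,
    }
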