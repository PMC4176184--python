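"""Synthetic coding sequences, ancestor→descendant pairs, genome panels.

This generator stands in for curated whole-genome alignments and their
ancestral reconstructions.  It produces:

* in-frame CDS with controllable amino-acid usage and third-position
  GC (GC3), the main composition knobs behind intrinsic flexibility;
* ancestor→descendant pairs carrying specified numbers of synonymous
  and non-synonymous single-base substitutions at a specified Ts:Tv
  odds ratio, placed either uniformly over eligible sites (a neutral
  null for the repositioned-mutation test, by construction) or biased
  toward sites of minimal/maximal flexibility impact (``flex_min`` /
  ``flex_max``) to emulate selection on backbone dynamics;
* multi-genome panels spanning an evenly spaced GC gradient, emulating
  prokaryote clades from AT-extreme endosymbionts to high-GC taxa.

Events are planted at distinct positions and labelled by substituting
the single site into the *ancestral* codon — the same rule substitution
calling uses — so planted events round-trip exactly through calling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .genetics import (
    BASES,
    CodingSequence,
    GeneticCode,
    get_code,
    is_transition,
)
from .rmtest import SubstitutionEvent
from .scale import TRXScale, load_trx_scale

Placement = Literal["uniform", "flex_min", "flex_max"]


@dataclass(frozen=True)
class EvolutionScenario:
    """Substitution counts and placement policy for one simulated pair."""

    n_syn: int = 0
    n_nonsyn: int = 0
    tstv: float = 2.0  # transition:transversion odds per available change
    placement: Placement = "uniform"
    seed: Optional[int] = None
    # geometric rank-preference strength for flex-biased placement;
    # higher = stronger bias toward the extreme-ranked options
    bias_strength: float = 0.5

    def __post_init__(self):
        if self.n_syn < 0 or self.n_nonsyn < 0:
            raise ValueError("event counts must be >= 0")
        if self.tstv <= 0:
            raise ValueError("tstv must be > 0")
        if not 0 < self.bias_strength < 1:
            raise ValueError("bias_strength must be in (0, 1)")


# ---------------------------------------------------------------- CDS


def _third_position_classes(code: GeneticCode) -> Dict[str, Tuple[list, list]]:
    """Per amino acid: synonym lists with S (G/C) vs W (A/T) third base."""
    out = {}
    for aa, codons in code.aa_to_codons.items():
        if aa == "*":
            continue
        strong = [c for c in codons if c[2] in "GC"]
        weak = [c for c in codons if c[2] in "AT"]
        out[aa] = (strong, weak)
    return out


def random_cds(
    n_codons: int,
    gc3_target: float = 0.5,
    usage_weights: Optional[Dict[str, float]] = None,
    seed: int | np.random.Generator | None = None,
    code: GeneticCode | None = None,
    id: str = "synthetic",
) -> CodingSequence:
    """Random in-frame CDS hitting a GC3 target.

    Amino acids are drawn uniformly (or by ``usage_weights``) over the 20
    residues; each codon's third-position class (G/C vs A/T) is then a
    Bernoulli draw at ``gc3_target``, with a uniform choice among the
    synonyms of that class.  Families lacking one class (Met, Trp always
    end in G) are clamped to the available class, so extreme targets are
    only approachable, not exact; the realised GC3 stays within binomial
    error of the attainable mean.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if not 0 <= gc3_target <= 1:
        raise ValueError("gc3_target must be in [0, 1]")
    code = code or get_code()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = _third_position_classes(code)
    aas = sorted(classes)
    if usage_weights:
        w = np.array([usage_weights.get(aa, 0.0) for aa in aas], dtype=float)
        if w.sum() <= 0:
            raise ValueError("usage_weights sum to zero")
        w = w / w.sum()
    else:
        w = np.full(len(aas), 1.0 / len(aas))
    aa_idx = rng.choice(len(aas), size=n_codons, p=w)
    want_strong = rng.random(n_codons) < gc3_target
    clamped = 0
    codons: List[str] = []
    for i in range(n_codons):
        strong, weak = classes[aas[aa_idx[i]]]
        pool = strong if want_strong[i] else weak
        if not pool:
            pool = weak or strong
            clamped += 1
        codons.append(pool[rng.integers(len(pool))])
    if clamped and gc3_target in (0.0, 1.0):
        warnings.warn(
            f"{clamped} codon(s) clamped: family lacks a "
            f"{'G/C' if gc3_target == 1.0 else 'A/T'}-ending synonym",
            stacklevel=2,
        )
    return CodingSequence(id=id, seq="".join(codons))


# ---------------------------------------------------------------- pairs


def _eligible_changes(
    seq: str, code: GeneticCode, effect: str
) -> List[Tuple[int, str, str]]:
    """(position, from_base, to_base) options producing the given effect.

    Non-synonymous options exclude changes creating a stop codon, so
    simulated descendants stay translatable.
    """
    out = []
    for ci in range(len(seq) // 3):
        codon = seq[3 * ci : 3 * ci + 3]
        if code.codon_to_aa[codon] == "*":
            continue
        for pc in range(3):
            for b in BASES:
                if b == codon[pc]:
                    continue
                mutated = codon[:pc] + b + codon[pc + 1 :]
                syn = code.codon_to_aa[mutated] == code.codon_to_aa[codon]
                if effect == "synonymous" and syn:
                    out.append((3 * ci + pc, codon[pc], b))
                elif (
                    effect == "non-synonymous"
                    and not syn
                    and code.codon_to_aa[mutated] != "*"
                ):
                    out.append((3 * ci + pc, codon[pc], b))
    return out


def _tstv_weights(options: Sequence[Tuple[int, str, str]], tstv: float) -> np.ndarray:
    w = np.array(
        [tstv if is_transition(f, t) else 1.0 for _, f, t in options], dtype=float
    )
    return w / w.sum()


def _abs_delta(seq: List[str], pos: int, new_base: str, scale: TRXScale) -> float:
    """|change in total linkage sum| for a single-base substitution."""
    old = new = 0.0
    for k in (pos - 1, pos):
        if 0 <= k < len(seq) - 1:
            left = seq[k] if k != pos else new_base
            right = seq[k + 1] if k + 1 != pos else new_base
            old += scale.values[seq[k] + seq[k + 1]]
            new += scale.values[left + right]
    return abs(new - old)


def _geometric_rank(n: int, p: float, rng: np.random.Generator) -> int:
    """Truncated geometric rank in [0, n): rank r with prob ∝ (1−p)^r."""
    probs = (1 - p) ** np.arange(n)
    probs /= probs.sum()
    return int(rng.choice(n, p=probs))


def evolve_pair(
    ancestor: CodingSequence,
    scenario: EvolutionScenario,
    scale: TRXScale | None = None,
    code: GeneticCode | None = None,
) -> Tuple[CodingSequence, List[SubstitutionEvent]]:
    """Plant the scenario's substitutions on an ancestor.

    Synonymous events go to synonymous-eligible sites: uniformly over
    (site, change) options weighted by the Ts:Tv odds for ``uniform``
    placement, or by a geometric preference over options ranked by
    per-event |ΔTRX| for ``flex_min``/``flex_max``.  Non-synonymous
    events are placed uniformly.  Each position carries at most one
    event; eligibility and effect labels are judged against the ancestor
    codon (single-site rule), so they are independent of planting order.
    Returns the descendant and the ground-truth event list (sorted by
    position).
    """
    code = code or get_code()
    scenario_rng = np.random.default_rng(scenario.seed)
    if scale is None and scenario.placement != "uniform":
        scale = load_trx_scale("canonical")
    # eligibility is judged once against the ancestor, the same single-site
    # rule substitution calling applies, so planted labels always round-trip
    syn_options = _eligible_changes(ancestor.seq, code, "synonymous")
    nonsyn_options = _eligible_changes(ancestor.seq, code, "non-synonymous")
    current = list(ancestor.seq)
    used_positions: set = set()
    events: List[SubstitutionEvent] = []

    def plant(effect: str, n_events: int, placement: Placement):
        pool = syn_options if effect == "synonymous" else nonsyn_options
        for _ in range(n_events):
            options = [opt for opt in pool if opt[0] not in used_positions]
            if not options:
                raise ValueError(f"insufficient eligible sites for {effect} events")
            if placement == "uniform" or effect == "non-synonymous":
                idx = scenario_rng.choice(
                    len(options), p=_tstv_weights(options, scenario.tstv)
                )
            else:
                deltas = [
                    _abs_delta(current, pos, b, scale) for pos, _, b in options
                ]
                order = np.lexsort((np.arange(len(options)), np.asarray(deltas)))
                if placement == "flex_max":
                    order = order[::-1]
                idx = order[
                    _geometric_rank(len(options), scenario.bias_strength, scenario_rng)
                ]
            pos, from_base, to_base = options[int(idx)]
            ci, pc = divmod(pos, 3)
            used_positions.add(pos)
            events.append(
                SubstitutionEvent(
                    position=pos,
                    from_base=from_base,
                    to_base=to_base,
                    codon_index=ci,
                    pos_in_codon=pc,
                    effect=effect,
                    kind="transition"
                    if is_transition(from_base, to_base)
                    else "transversion",
                )
            )
            current[pos] = to_base

    def reassign_uniform_positions():
        """Re-draw the synonymous events' positions uniformly per change type.

        Stage 1 (``plant``) chose (site, change) options jointly, which
        conditions positions on types in a subtly non-uniform way.  Under
        neutrality, position given change type must be uniform over that
        type's eligible sites — the exact distribution the RM test's
        repositioning samples — so positions are re-drawn here with the
        same random-order, without-replacement scheme.
        """
        site_lists = {}
        for pos, f, t in syn_options:
            site_lists.setdefault((f, t), []).append(pos)
        # small genes can exhaust a type's sites under an unlucky order;
        # re-draw the whole assignment rather than biasing any single event
        for attempt in range(100):
            order = scenario_rng.permutation(len(events))
            taken: set = set()
            new_pos = {}
            for i in order:
                ev = events[i]
                cand = [
                    p for p in site_lists[(ev.from_base, ev.to_base)] if p not in taken
                ]
                if cand:
                    p = int(cand[scenario_rng.integers(len(cand))])
                elif ev.position not in taken:
                    p = ev.position
                else:
                    break
                taken.add(p)
                new_pos[i] = p
            if len(new_pos) == len(events):
                break
        else:
            raise ValueError("could not assign distinct event positions")
        # two phases: reset every old site before writing any new one, so a
        # reset can never clobber another event's freshly written base
        for i in new_pos:
            ev = events[i]
            current[ev.position] = ev.from_base
            used_positions.discard(ev.position)
        for i, p in new_pos.items():
            ev = events[i]
            ci, pc = divmod(p, 3)
            events[i] = SubstitutionEvent(
                position=p,
                from_base=ev.from_base,
                to_base=ev.to_base,
                codon_index=ci,
                pos_in_codon=pc,
                effect=ev.effect,
                kind=ev.kind,
            )
            current[p] = ev.to_base
            used_positions.add(p)

    plant("synonymous", scenario.n_syn, scenario.placement)
    if scenario.placement == "uniform":
        reassign_uniform_positions()
    plant("non-synonymous", scenario.n_nonsyn, "uniform")
    descendant = CodingSequence(
        id=ancestor.id, seq="".join(current), description="descendant"
    )
    return descendant, sorted(events, key=lambda ev: ev.position)


# ---------------------------------------------------------------- panels


@dataclass
class SyntheticGenome:
    genome_id: str
    gc_target: float
    genes: List[CodingSequence]


def _aa_gc_propensity(code: GeneticCode) -> Dict[str, float]:
    """Mean GC fraction of the first two codon positions per amino acid."""
    out = {}
    for aa, codons in code.aa_to_codons.items():
        if aa == "*":
            continue
        out[aa] = float(
            np.mean([(c[0] in "GC") + (c[1] in "GC") for c in codons]) / 2
        )
    return out


def _tilted_weights(code: GeneticCode, gc12_target: float) -> Dict[str, float]:
    """Exponentially tilted amino-acid weights hitting a GC12 target."""
    prop = _aa_gc_propensity(code)
    aas = sorted(prop)
    g = np.array([prop[aa] for aa in aas])

    def mean_gc12(lam: float) -> float:
        w = np.exp(lam * g)
        return float((w * g).sum() / w.sum())

    lo, hi = -40.0, 40.0
    target = float(np.clip(gc12_target, mean_gc12(lo) + 1e-6, mean_gc12(hi) - 1e-6))
    lam = brentq(lambda x: mean_gc12(x) - target, lo, hi)
    w = np.exp(lam * g)
    return dict(zip(aas, w / w.sum()))


def genome_panel(
    n_genomes: int = 24,
    gc_range: Tuple[float, float] = (0.15, 0.72),
    genes_per_genome: int = 50,
    codons_per_gene: int = 300,
    seed: int | None = 0,
    code: GeneticCode | None = None,
) -> List[SyntheticGenome]:
    """Panel of synthetic genomes with evenly spaced overall-GC targets.

    Each genome couples an amino-acid usage tilt (first two codon
    positions) with a GC3 target so that total GC approaches its target;
    GC3 spans nearly its full range across the panel, as it does across
    real prokaryote clades.
    """
    if n_genomes < 3:
        raise ValueError("need at least 3 genomes")
    lo, hi = gc_range
    if not lo < hi:
        raise ValueError("degenerate GC range")
    code = code or get_code()
    targets = np.linspace(lo, hi, n_genomes)
    gc3_targets = np.clip(np.linspace(0.0, 1.0, n_genomes) * 1.3 - 0.15, 0.02, 0.98)
    root = np.random.default_rng(seed)
    genomes = []
    for g, (target, gc3) in enumerate(zip(targets, gc3_targets)):
        gc12 = (3 * target - gc3) / 2
        weights = _tilted_weights(code, gc12)
        rng = np.random.default_rng(root.integers(2**31))
        genes = [
            random_cds(
                codons_per_gene,
                gc3_target=float(gc3),
                usage_weights=weights,
                seed=rng,
                code=code,
                id=f"genome{g:02d}_gene{i:03d}",
            )
            for i in range(genes_per_genome)
        ]
        genomes.append(
            SyntheticGenome(
                genome_id=f"genome{g:02d}", gc_target=float(target), genes=genes
            )
        )
    return genomes
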