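"""Synonymous flexibility envelopes for a fixed protein, and devTRX.

For a coding sequence, the set of all synonymous recodings ("protein
space") spans a range of intrinsic flexibility.  This module computes,
per codon, the observed TRX_cdn score, the minimum and maximum scores
achievable by synonymous codon choice, and the mean ± 95% CI of the
score over uniform synonymous randomizations.  The deviation statistic

    devTRX_cdn = |TRX_cdn_real − TRX_cdn_syn| / |TRX_cdn_min − TRX_cdn_max|

normalises the gene's departure from its random-synonym expectation by
the local range available in protein space; the per-gene mean of
devTRX_cdn quantifies how extreme the gene's flexibility is for its
protein.

The min/max sequences are built greedily left-to-right (each codon picks
the synonym optimising its TRX_cdn given the already-chosen left
neighbour and the original right neighbour); an exact dynamic program
over codon choices is also provided and is guaranteed optimal for the
whole-sequence score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Tuple

import numpy as np

from .genetics import GeneticCode, get_code
from .scale import TRXScale, trx_track

Objective = Literal["min", "max"]


@dataclass
class FlexEnvelope:
    """Per-codon flexibility tracks for one gene (arrays of length n_codons)."""

    gene_id: str
    observed_trx: np.ndarray
    min_trx: np.ndarray
    max_trx: np.ndarray
    syn_mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    dev_trx: np.ndarray
    outside_ci: np.ndarray  # boolean: observed outside [ci_low, ci_high]
    gene_mean_dev: float
    smooth_window_codons: int
    # 95% CI of the *smoothed* randomized tracks (smooth first, then take
    # percentiles) — the band used for flagging regionally extreme genes;
    # the per-codon ci_low/ci_high band is much wider than any smoothed
    # track can escape
    ci_low_smoothed: np.ndarray | None = None
    ci_high_smoothed: np.ndarray | None = None
    outside_ci_smoothed: np.ndarray | None = None

    def smoothed(self, name: str) -> np.ndarray:
        """Centered moving average of a track over the codon window."""
        return smooth_track(getattr(self, name), self.smooth_window_codons)


def _codon_score(
    prev_last: str | None, codon: str, next_first: str | None, scale: TRXScale
) -> float:
    """TRX_cdn for a codon given its flanking bases (None at the ends)."""
    total = scale.values[codon[0] + codon[1]] + scale.values[codon[1] + codon[2]]
    if prev_last is not None:
        total += scale.values[prev_last + codon[0]]
    if next_first is not None:
        total += scale.values[codon[2] + next_first]
    return total


def envelope_greedy(
    seq, scale: TRXScale, objective: Objective, code: GeneticCode | None = None
) -> str:
    """Greedy synonymous recoding optimising each codon's TRX_cdn in turn.

    Left-to-right; the already-chosen left neighbour and the *original*
    right neighbour provide the external linkages.  Ties are broken by
    lexicographic codon order, so the output is deterministic.
    """
    code = code or get_code()
    s = seq.seq if hasattr(seq, "seq") else str(seq).upper()
    if len(s) % 3:
        raise ValueError(f"length {len(s)} is not a multiple of 3")
    n = len(s) // 3
    sign = 1.0 if objective == "min" else -1.0
    chosen = []
    for j in range(n):
        codon = s[3 * j : 3 * j + 3]
        prev_last = chosen[j - 1][2] if j > 0 else None
        next_first = s[3 * j + 3] if j < n - 1 else None
        best = min(
            sorted(code.synonyms(codon)),
            key=lambda c: (sign * _codon_score(prev_last, c, next_first, scale), c),
        )
        chosen.append(best)
    return "".join(chosen)


def envelope_exact(
    seq, scale: TRXScale, objective: Objective, code: GeneticCode | None = None
) -> str:
    """Synonymous recoding with exactly optimal whole-sequence TRX.

    Dynamic program over codons with the codon identity as state; the
    cost of a transition is the junction linkage between neighbouring
    codons plus the right codon's two internal linkages.  Among all
    optimal recodings the lexicographically smallest is returned.
    """
    code = code or get_code()
    s = seq.seq if hasattr(seq, "seq") else str(seq).upper()
    if len(s) % 3:
        raise ValueError(f"length {len(s)} is not a multiple of 3")
    n = len(s) // 3
    sign = 1.0 if objective == "min" else -1.0
    syn_sets = [sorted(code.synonyms(s[3 * j : 3 * j + 3])) for j in range(n)]

    def internal(c: str) -> float:
        return scale.values[c[0] + c[1]] + scale.values[c[1] + c[2]]

    # best[j][codon]: optimal signed cost of codons j..n-1 given codon at j
    best = [dict() for _ in range(n)]
    for c in syn_sets[-1]:
        best[-1][c] = sign * internal(c)
    for j in range(n - 2, -1, -1):
        nxt = syn_sets[j + 1]
        for c in syn_sets[j]:
            best[j][c] = sign * internal(c) + min(
                sign * scale.values[c[2] + c2[0]] + best[j + 1][c2] for c2 in nxt
            )
    chosen = [min(syn_sets[0], key=lambda c: (best[0][c], c))]
    for j in range(1, n):
        prev = chosen[-1]
        target = best[j - 1][prev] - sign * internal(prev)
        chosen.append(
            min(
                (
                    c
                    for c in syn_sets[j]
                    if abs(sign * scale.values[prev[2] + c[0]] + best[j][c] - target)
                    < 1e-9
                ),
                key=lambda c: c,
            )
        )
    return "".join(chosen)


def _randomization_tracks(
    seq, scale: TRXScale, n: int, rng_seed, code: GeneticCode
) -> np.ndarray:
    """(n, n_codons) matrix of TRX_cdn tracks over uniform synonymous
    recodings (every codon replaced by a uniformly chosen synonym)."""
    s = seq.seq if hasattr(seq, "seq") else str(seq).upper()
    if len(s) % 3:
        raise ValueError(f"length {len(s)} is not a multiple of 3")
    n_codons = len(s) // 3
    syn_sets = [code.synonyms(s[3 * j : 3 * j + 3]) for j in range(n_codons)]
    rng = np.random.default_rng(rng_seed)
    tracks = np.empty((n, n_codons))
    for i in range(n):
        variant = "".join(syns[rng.integers(len(syns))] for syns in syn_sets)
        tracks[i] = trx_track(variant, scale)
    return tracks


def synonymous_randomizations(
    seq,
    scale: TRXScale,
    n: int = 500,
    rng_seed: int | None = 0,
    code: GeneticCode | None = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-codon mean and percentile 95% CI of TRX_cdn over ``n`` uniform
    synonymous recodings (the protein is preserved)."""
    if n < 2:
        raise ValueError("need at least 2 randomizations")
    code = code or get_code()
    tracks = _randomization_tracks(seq, scale, n, rng_seed, code)
    return (
        tracks.mean(axis=0),
        np.quantile(tracks, 0.025, axis=0),
        np.quantile(tracks, 0.975, axis=0),
    )


def smooth_track(values, window: int) -> np.ndarray:
    """Centered moving average, truncated (not padded) at the edges.

    ``window`` is in the units of the track (bp for per-position tracks,
    codons for per-codon tracks; the bp default of 73 corresponds to a
    24-codon window, round(73/3)).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if window < 1:
        raise ValueError("window must be >= 1")
    kernel = np.ones(window)
    return np.convolve(x, kernel, mode="same") / np.convolve(
        np.ones_like(x), kernel, mode="same"
    )


def codon_window(smooth_bp: int = 73) -> int:
    """Codon-track window equivalent to a bp smoothing interval."""
    return max(1, round(smooth_bp / 3))


def dev_trx(
    seq,
    scale: TRXScale,
    n: int = 500,
    rng_seed: int | None = 0,
    smooth_bp: int = 73,
    code: GeneticCode | None = None,
    gene_id: str | None = None,
) -> FlexEnvelope:
    """Full flexibility envelope and devTRX_cdn for one gene.

    Codons where the greedy min and max coincide have no synonymous
    freedom locally; their devTRX is defined as 0.
    """
    if n < 2:
        raise ValueError("need at least 2 randomizations")
    code = code or get_code()
    gid = gene_id or getattr(seq, "id", "") or ""
    observed = trx_track(seq, scale)
    min_seq = envelope_greedy(seq, scale, "min", code=code)
    max_seq = envelope_greedy(seq, scale, "max", code=code)
    min_track = trx_track(min_seq, scale)
    max_track = trx_track(max_seq, scale)
    tracks = _randomization_tracks(seq, scale, n, rng_seed, code)
    syn_mean = tracks.mean(axis=0)
    ci_low = np.quantile(tracks, 0.025, axis=0)
    ci_high = np.quantile(tracks, 0.975, axis=0)
    window = codon_window(smooth_bp)
    smoothed_tracks = np.apply_along_axis(smooth_track, 1, tracks, window)
    ci_low_s = np.quantile(smoothed_tracks, 0.025, axis=0)
    ci_high_s = np.quantile(smoothed_tracks, 0.975, axis=0)
    observed_s = smooth_track(observed, window)
    denom = np.abs(min_track - max_track)
    numer = np.abs(observed - syn_mean)
    dev = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    outside = (observed < ci_low) | (observed > ci_high)
    outside_s = (observed_s < ci_low_s) | (observed_s > ci_high_s)
    return FlexEnvelope(
        gene_id=gid,
        observed_trx=observed,
        min_trx=min_track,
        max_trx=max_track,
        syn_mean=syn_mean,
        ci_low=ci_low,
        ci_high=ci_high,
        dev_trx=dev,
        outside_ci=outside,
        gene_mean_dev=float(dev.mean()),
        smooth_window_codons=window,
        ci_low_smoothed=ci_low_s,
        ci_high_smoothed=ci_high_s,
        outside_ci_smoothed=outside_s,
    )
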