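"""Codon counting, entropy-based codon usage bias, and GC/GC3 content.

Codon bias follows the weighted relative-entropy statistic Ew: for each
degenerate amino-acid family *a* with synonym proportions p_i, the
Shannon entropy H_a = −Σ p_i log2 p_i is scaled by its maximum
log2(k_a), and Ew is the codon-count-weighted mean of these relative
entropies over all degenerate families observed in the gene.  Bias is
reported as 1 − Ew, so 1 means a single synonym per amino acid is used
throughout and 0 means perfectly even synonym usage.  Met, Trp and stop
codons carry no synonymous choice and are excluded; six-fold families
(Leu, Ser, Arg) are treated as single families with k = 6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .genetics import GeneticCode, get_code


@dataclass
class CodonUsage:
    """Codon counts over the sense codons of a genetic code."""

    counts: Dict[str, int]
    total_codons: int
    table_id: int = 1

    @property
    def code(self) -> GeneticCode:
        return get_code(self.table_id)


def codon_counts(seq, code: GeneticCode | None = None) -> CodonUsage:
    """Tally codon usage of an in-frame CDS.

    A terminal stop codon is excluded from the tally; internal stop
    codons are counted (so frame statistics remain well defined) but a
    warning is emitted because they usually indicate a frame or
    annotation problem.
    """
    code = code or get_code()
    s = seq.seq if hasattr(seq, "seq") else str(seq).upper()
    if len(s) % 3:
        raise ValueError(f"length {len(s)} is not a multiple of 3")
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    if codons and code.codon_to_aa[codons[-1]] == "*":
        codons = codons[:-1]
    counts: Dict[str, int] = {}
    n_internal_stops = 0
    for c in codons:
        counts[c] = counts.get(c, 0) + 1
        if code.codon_to_aa[c] == "*":
            n_internal_stops += 1
    if n_internal_stops:
        warnings.warn(
            f"{n_internal_stops} internal stop codon(s) counted", stacklevel=2
        )
    return CodonUsage(counts=counts, total_codons=len(codons), table_id=code.table_id)


def entropy_bias(usage: CodonUsage) -> float:
    """Entropy-based codon bias 1 − Ew, in [0, 1].

    Ew = Σ_a w_a · H_a / log2(k_a), with weights w_a equal to the share
    of the gene's degenerate-family codons belonging to family *a*.
    Families with no counted codons drop out of the weighted sum; zero-
    count synonyms contribute 0 to H_a (0·log 0 ≡ 0).  A gene with no
    degenerate-family codons at all has no defined bias and raises.
    """
    code = usage.code
    family_weighted = 0.0
    n_degenerate = 0
    for aa, codons in code.degenerate_families.items():
        fam_counts = np.array([usage.counts.get(c, 0) for c in codons], dtype=float)
        total = fam_counts.sum()
        if total == 0:
            continue
        p = fam_counts[fam_counts > 0] / total
        h = float(-(p * np.log2(p)).sum())
        e = h / np.log2(len(codons))
        family_weighted += total * e
        n_degenerate += int(total)
    if n_degenerate == 0:
        raise ValueError("no codons from degenerate families; bias undefined")
    ew = family_weighted / n_degenerate
    return 1.0 - ew


def gc_content(seq) -> float:
    """Fraction of G+C over the whole sequence."""
    s = seq.seq if hasattr(seq, "seq") else str(seq).upper()
    if not s:
        raise ValueError("empty sequence")
    return (s.count("G") + s.count("C")) / len(s)


def gc3_content(seq) -> float:
    """Fraction of third codon positions occupied by G or C."""
    s = seq.seq if hasattr(seq, "seq") else str(seq).upper()
    if len(s) % 3:
        raise ValueError(f"length {len(s)} is not a multiple of 3")
    third = s[2::3]
    return gc_content(third)


def _centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated (not padded) at the edges."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if x.size == 0:
        raise ValueError("empty input")
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def gc_frame_tracks(seq, smooth_bp: int = 73) -> Dict[str, np.ndarray]:
    """Smoothed per-position GC indicator tracks.

    Returns centered moving averages (window ``smooth_bp``) of the G/C
    indicator for the whole sequence (``gc``), for each reading frame
    separately (``frame1``..``frame3``, evaluated at that frame's
    positions), and for third codon positions (``gc3``, alias of frame 3).
    """
    s = seq.seq if hasattr(seq, "seq") else str(seq).upper()
    if len(s) % 3:
        raise ValueError(f"length {len(s)} is not a multiple of 3")
    ind = np.array([1.0 if b in "GC" else 0.0 for b in s])
    # frame windows cover the same physical span, so divide the bp window by 3
    frame_window = max(1, round(smooth_bp / 3))
    tracks = {"gc": _centered_moving_average(ind, smooth_bp)}
    for frame in range(3):
        tracks[f"frame{frame + 1}"] = _centered_moving_average(
            ind[frame::3], frame_window
        )
    tracks["gc3"] = tracks["frame3"]
    return tracks
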