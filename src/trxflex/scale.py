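"""The TRX dinucleotide flexibility scale and sequence/codon scoring.

TRX assigns every dinucleotide step a score equal to the percentage of
time its sugar-phosphate linkage resides in the less stable BII backbone
conformation (from NMR meta-analysis); higher scores mean more BI↔BII
switching, i.e. higher intrinsic flexibility.  The scale is symmetric
under reverse complementation of the step (a linkage and its complement
are the same physical object), so the 16 dinucleotides carry at most 10
distinct values.  The canonical scale averages 20.625 over the 16
dinucleotides — this midpoint is used as a validation gate at load time
and as the inflection point of genome-level regressions.

A sequence score is the mean of its L−1 overlapping dinucleotide values.
A codon score (TRX_cdn) is the *sum* over the codon's two internal
linkages and its two external linkages to the neighbouring codons;
terminal codons simply omit the missing external linkage.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np

from .genetics import BASES, encode, revcomp

CANONICAL_MIDPOINT = 20.625
_MIDPOINT_TOL = 1e-9

_ALL_STEPS = tuple(a + b for a in BASES for b in BASES)


class ScaleError(ValueError):
    """Raised when a TRX scale file fails validation."""


@dataclass(frozen=True)
class TRXScale:
    """A 16-entry dinucleotide→flexibility lookup (percent time in BII)."""

    values: Mapping[str, float]
    source_label: str = ""

    def __post_init__(self):
        vals = dict(self.values)
        missing = [s for s in _ALL_STEPS if s not in vals]
        if missing or len(vals) != 16:
            raise ScaleError(f"scale must define all 16 steps; missing {missing}")
        for step, v in vals.items():
            if not np.isfinite(v) or v < 0:
                raise ScaleError(f"step {step}: value {v} is not finite and >= 0")
            rc = revcomp(step)
            if abs(vals[rc] - v) > 1e-12:
                raise ScaleError(
                    f"complementary steps {step}/{rc} differ: {v} vs {vals[rc]}"
                )
        matrix = np.zeros((4, 4))
        for step, v in vals.items():
            matrix[BASES.index(step[0]), BASES.index(step[1])] = float(v)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "_matrix", matrix)

    @property
    def matrix(self) -> np.ndarray:
        """4×4 lookup indexed by (first-base code, second-base code)."""
        return self._matrix

    @property
    def mean(self) -> float:
        """Mean score over all 16 dinucleotides."""
        return float(np.mean(list(self.values.values())))

    @property
    def min(self) -> float:
        return float(min(self.values.values()))

    @property
    def max(self) -> float:
        return float(max(self.values.values()))


def _parse_scale_lines(lines, source_label: str) -> TRXScale:
    rows: Dict[str, float] = {}
    for i, line in enumerate(lines):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if i == 0 and fields[0].lower() == "step":
            continue
        if len(fields) != 2:
            raise ScaleError(f"malformed scale line: {line!r}")
        step = fields[0].upper()
        if len(step) != 2 or any(b not in BASES for b in step):
            raise ScaleError(f"invalid dinucleotide step {fields[0]!r}")
        value = float(fields[1])
        for key in {step, revcomp(step)}:
            if key in rows and abs(rows[key] - value) > 1e-12:
                raise ScaleError(
                    f"step {key}: conflicting values {rows[key]} and {value}"
                )
            rows[key] = value
    if len(rows) != 16:
        missing = [s for s in _ALL_STEPS if s not in rows]
        raise ScaleError(f"scale incomplete; missing steps {missing}")
    return TRXScale(values=rows, source_label=source_label)


def load_trx_scale(source: str = "canonical") -> TRXScale:
    """Load a TRX scale from the built-in canonical table or a TSV file.

    Files are 2-column tab-delimited (``step<TAB>trx``) with 10 or 16
    rows; 10-row files are expanded by complementary-step symmetry.  The
    canonical scale must reproduce the 20.625 midpoint (mean over all 16
    dinucleotides) to 1e-9, which gates both the transcription of the
    experimental values and the symmetry-weighting convention.
    """
    if source == "canonical":
        text = (
            importlib.resources.files("trxflex")
            .joinpath("data/trx_scale.tsv")
            .read_text()
        )
        scale = _parse_scale_lines(text.splitlines(), source_label="canonical")
        if abs(scale.mean - CANONICAL_MIDPOINT) > _MIDPOINT_TOL:
            raise ScaleError(
                f"canonical scale failed midpoint gate: mean {scale.mean} "
                f"!= {CANONICAL_MIDPOINT}"
            )
        return scale
    with open(source) as fh:
        return _parse_scale_lines(fh.readlines(), source_label=str(source))


def _seq_codes(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    if hasattr(seq, "seq"):
        seq = seq.seq
    return encode(str(seq).upper())


def trx_sequence(seq, scale: TRXScale) -> float:
    """Sequence flexibility: mean TRX over the L−1 dinucleotide linkages."""
    codes = _seq_codes(seq)
    if codes.size < 2:
        raise ValueError("sequence must have length >= 2")
    vals = scale.matrix[codes[:-1], codes[1:]]
    return float(vals.mean())


def linkage_values(seq, scale: TRXScale) -> np.ndarray:
    """Per-linkage TRX values (length L−1)."""
    codes = _seq_codes(seq)
    return scale.matrix[codes[:-1], codes[1:]]


def trx_track(seq, scale: TRXScale) -> np.ndarray:
    """Per-codon TRX_cdn: sum of the ≤4 linkage values touching each codon.

    Codon j draws on linkages (3j−1, 3j, 3j+1, 3j+2); the first codon has
    no left external linkage and the last no right external linkage, and
    those are simply omitted from the sum (no padding or renormalisation).
    """
    codes = _seq_codes(seq)
    if codes.size % 3:
        raise ValueError(f"length {codes.size} is not a multiple of 3")
    n = codes.size // 3
    v = scale.matrix[codes[:-1], codes[1:]]
    vp = np.concatenate(([0.0], v, [0.0]))
    idx = 3 * np.arange(n)[:, None] + np.arange(4)[None, :]
    return vp[idx].sum(axis=1)


def trx_codon(seq, codon_index: int, scale: TRXScale) -> float:
    """TRX_cdn of a single codon (see :func:`trx_track`)."""
    codes = _seq_codes(seq)
    n = codes.size // 3
    if codes.size % 3:
        raise ValueError(f"length {codes.size} is not a multiple of 3")
    if not 0 <= codon_index < n:
        raise IndexError(f"codon index {codon_index} out of range [0, {n})")
    total = 0.0
    for k in range(3 * codon_index - 1, 3 * codon_index + 3):
        if 0 <= k < codes.size - 1:
            total += scale.matrix[codes[k], codes[k + 1]]
    return float(total)
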