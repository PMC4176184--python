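"""FASTA input, pairing, and tab-delimited output.

Coordinates are 0-based inside the package and 1-based in every
user-facing table (noted in table headers).  Inputs are assumed to be
coding-strand CDS; no strand inference is attempted.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path
from typing import Iterable, List, Mapping, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .genetics import CodingSequence


def read_fasta(path) -> List[CodingSequence]:
    """Read a FASTA file of coding sequences (uppercased, ACGT only)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    seen = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        out.append(
            CodingSequence(id=rec.id, seq=str(rec.seq), description=rec.description)
        )
    return out


def write_fasta(records: Iterable[CodingSequence], path) -> None:
    SeqIO.write(
        (
            SeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
            for r in records
        ),
        str(path),
        "fasta",
    )


def read_pairs(
    ancestors_path, extants_path
) -> List[Tuple[CodingSequence, CodingSequence]]:
    """Pair ancestor and extant records by exact FASTA id.

    Unpaired ids on either side are skipped with a warning naming the
    count; pairing is order-independent.
    """
    anc = {r.id: r for r in read_fasta(ancestors_path)}
    ext = {r.id: r for r in read_fasta(extants_path)}
    shared = [i for i in anc if i in ext]
    unpaired = (len(anc) - len(shared)) + (len(ext) - len(shared))
    if unpaired:
        warnings.warn(f"{unpaired} unpaired record id(s) skipped", stacklevel=2)
    if not shared:
        raise ValueError("no shared record ids between the two files")
    return [(anc[i], ext[i]) for i in shared]


def _config_hash(config: Mapping) -> str:
    text = ";".join(f"{k}={config[k]}" for k in sorted(config))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_table(
    frame: pd.DataFrame,
    path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> None:
    """Write a TSV with a '#'-prefixed provenance header.

    The header records the tool version, a hash of the run
    configuration, and the seed, so any output can be regenerated
    exactly.  Positions in tables are 1-based.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# trxflex {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash {_config_hash(config)}\n")
            for k in sorted(config):
                fh.write(f"# config {k}={config[k]}\n")
        if seed is not None:
            fh.write(f"# seed {seed}\n")
        fh.write("# coordinates: 1-based\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
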