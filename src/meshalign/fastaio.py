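"""FASTA reading/writing (plain and aligned) and run configuration."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .scoring import GAP

__all__ = ["read_fasta", "write_fasta", "write_fasta_aligned", "RunConfig"]


def read_fasta(path, alphabet: str | None = None, allow_gaps: bool = False):
    """Read a FASTA file into ``(ids, sequences)``.

    Sequences are upper-cased.  With ``alphabet`` given, any residue
    outside it (plus ``-`` when ``allow_gaps``) is an input error reported
    with its line number.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise InputError(f"{path}: duplicate record ids")
    seqs = [str(r.seq).upper() for r in records]
    if alphabet is not None:
        allowed = set(alphabet.upper()) | ({GAP} if allow_gaps else set())
        lineno = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(">"):
                    continue
                bad = set(line.upper()) - allowed
                if bad:
                    raise InputError(
                        f"{path}:{lineno}: residues {sorted(bad)} outside "
                        f"alphabet {alphabet!r}"
                    )
    return ids, seqs


def write_fasta(path, ids, seqs) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(ids, seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fasta_aligned(path, group) -> None:
    """Write an :class:`~meshalign.progressive.AlignedGroup` as aligned FASTA."""
    if len({len(r) for r in group.rows}) > 1:
        raise InputError("aligned rows must have equal length")
    write_fasta(path, group.ids, group.rows)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run, serialized into output logs."""

    mode: str = "nw"
    engine: str = "reference"
    match: int = 1
    mismatch: int = 0
    gap: int = -1
    gap_open: int | None = None
    matrix_file: str | None = None
    alphabet: str = "ACGT"
    seed: int = 0
    tie_policy: str = "diag-up-left"
    paper_literal_nj: bool = False

    def validate(self) -> "RunConfig":
        if self.mode not in ("nw", "sw", "lcs"):
            raise InputError(f"unknown mode {self.mode!r}")
        if self.engine not in ("mesh", "reference"):
            raise InputError(f"unknown engine {self.engine!r}")
        if self.gap_open is not None and self.gap - self.gap_open < 0:
            raise InputError("gap_open must be <= gap (opening at least as costly)")
        return self

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)
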