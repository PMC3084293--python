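"""Signature-Trp scan for EGF-like domains.

EGF modules carry six conserved cysteines (C1–C6).  In the neurexin
motif (neurexins, Caspr, Crumbs homologues, CELSRs) the loop between
C3 and C4 presents a tryptophan four residues after the third
cysteine; that "signature Trp" plugs into the neighbouring LNS domain
and locks the domain pair.  This module finds the six-cysteine
register in a sequence, asks whether the C3+4 position is a Trp, and
aggregates the fraction of signature-positive sequences over a FASTA
set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .errors import NrxGeomError

__all__ = [
    "MotifHit",
    "ScanSummary",
    "clean_sequence",
    "find_cysteine_register",
    "has_signature_trp",
    "scan_sequences",
    "scan_fasta",
]

SIGNATURE_OFFSET = 4  # residues downstream of the third conserved Cys


@dataclass
class MotifHit:
    sequence_id: str
    cys_positions: tuple[int, ...]  # positions of the six Cys (see `numbers`)
    signature_position: int | None
    has_signature: bool
    residue_at_signature: str | None
    register_ok: bool
    n_cys_total: int = 0


@dataclass
class ScanSummary:
    hits: list[MotifHit]
    n_sequences: int
    n_valid_register: int
    n_signature: int

    @property
    def fraction_of_valid(self) -> float:
        """Signature fraction over sequences with a clean 6-Cys register."""
        if self.n_valid_register == 0:
            return float("nan")
        return self.n_signature / self.n_valid_register

    @property
    def fraction_of_all(self) -> float:
        """Signature fraction over every input sequence."""
        if self.n_sequences == 0:
            return float("nan")
        return self.n_signature / self.n_sequences


def clean_sequence(seq: str) -> str:
    """Strip gaps ('-', '.') and lowercase insert-state characters.

    Alignment-format tolerance: Pfam-style alignments mark insert
    states in lowercase and gaps with '-'/'.'; both are removed before
    positional indexing so the register refers to match columns.
    """
    return "".join(c for c in seq if c.isupper())


def find_cysteine_register(seq: str, numbers: list[int] | None = None):
    """Positions of the first six cysteines.

    ``numbers`` optionally supplies per-residue labels (e.g. author
    residue numbers from a structure); otherwise 1-based indices are
    used.  Returns (positions, register_ok, n_cys_total); fewer than
    six cysteines is flagged, not raised.
    """
    if numbers is not None and len(numbers) != len(seq):
        raise NrxGeomError("numbers must label every residue of seq")
    cys_idx = [i for i, c in enumerate(seq) if c == "C"]
    label = (lambda i: numbers[i]) if numbers is not None else (lambda i: i + 1)
    positions = tuple(label(i) for i in cys_idx[:6])
    return positions, len(cys_idx) >= 6, len(cys_idx)


def has_signature_trp(
    seq: str, sequence_id: str = "", numbers: list[int] | None = None
) -> MotifHit:
    """Does the residue 4 positions after the third Cys read 'W'?

    Positions in the returned hit are 1-based indices, or the caller's
    ``numbers`` labels when given.
    """
    cys_idx = [i for i, c in enumerate(seq) if c == "C"]
    label = (lambda i: numbers[i]) if numbers is not None else (lambda i: i + 1)
    positions = tuple(label(i) for i in cys_idx[:6])
    n_cys = len(cys_idx)
    if n_cys < 6:
        return MotifHit(sequence_id, positions, None, False, None, False, n_cys)
    sig_idx = cys_idx[2] + SIGNATURE_OFFSET  # third Cys, counting itself as 0
    if sig_idx >= len(seq):
        return MotifHit(sequence_id, positions, None, False, None, False, n_cys)
    residue = seq[sig_idx]
    return MotifHit(
        sequence_id=sequence_id,
        cys_positions=positions,
        signature_position=label(sig_idx),
        has_signature=residue == "W",
        residue_at_signature=residue,
        register_ok=True,
        n_cys_total=n_cys,
    )


def scan_sequences(records: list[tuple[str, str]]) -> ScanSummary:
    """Scan (id, sequence) pairs; sequences are cleaned first."""
    hits = []
    for sid, seq in records:
        seq = clean_sequence(str(seq))
        if len(seq) < 20:
            hits.append(MotifHit(sid, (), None, False, None, False, seq.count("C")))
            continue
        hits.append(has_signature_trp(seq, sid))
    n_valid = sum(1 for h in hits if h.register_ok)
    n_sig = sum(1 for h in hits if h.has_signature)
    return ScanSummary(hits, len(hits), n_valid, n_sig)


def scan_fasta(path: str | Path) -> ScanSummary:
    """Scan every sequence of a FASTA file for the signature Trp."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise NrxGeomError(f"{path}: empty or unreadable FASTA")
    return scan_sequences(records)
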