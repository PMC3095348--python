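"""Sequence and table I/O plus the core sequence containers.

Protein FASTA parsing is delegated to Biopython; this module layers strict
validation on top of it: a closed amino-acid alphabet (the 20 standard
residues plus ``X`` for unknown), unique record identifiers, and uniform row
lengths for alignments.  Coordinates are 0-based half-open everywhere,
including in the tab-separated hit tables written here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from Bio import SeqIO

#: The 20 standard amino acids in alphabetical one-letter order.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Accepted residue alphabet: the 20 standard amino acids plus X (unknown).
#: Ambiguity codes B/Z/J and the rare U/O are rejected so that upstream data
#: problems surface as errors instead of silently degrading scan results.
ALPHABET = frozenset(AA20 + "X")

GAP = "-"

_WRAP = 60  # output line width for FASTA


class FastaError(ValueError):
    """Raised for malformed FASTA input (alphabet, duplicate ids, shape)."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    Parameters
    ----------
    id:
        Unique, non-empty token without whitespace.
    residues:
        Upper-case amino-acid string over :data:`ALPHABET`; never empty and
        never gapped.
    description:
        Free text after the first whitespace of the FASTA header.
    taxon:
        Optional taxon label used when the record feeds a phylogeny.
    """

    id: str
    residues: str
    description: str = ""
    taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FastaError(f"record id {self.id!r} is empty or contains whitespace")
        if not self.residues:
            raise FastaError(f"record {self.id!r} has an empty sequence")
        _check_alphabet(self.residues, self.id, allow_gap=False)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedBlock:
    """A rectangular multiple alignment: ordered ``(id, aligned residues)`` rows.

    Aligned residues may contain the gap character ``-``; all rows must have
    identical length and ids must be unique.
    """

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise FastaError("alignment has no rows")
        seen: set[str] = set()
        width = len(self.rows[0][1])
        for rid, res in self.rows:
            if rid in seen:
                raise FastaError(f"duplicate id {rid!r} in alignment")
            seen.add(rid)
            if len(res) != width:
                raise FastaError(
                    f"alignment row {rid!r} has length {len(res)}, expected {width}"
                )
            _check_alphabet(res, rid, allow_gap=True)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    def row(self, rid: str) -> str:
        for r, res in self.rows:
            if r == rid:
                return res
        raise KeyError(rid)

    def columns(self, cols: Sequence[int]) -> "AlignedBlock":
        """Sub-block restricted to the given columns, in the given order."""
        return AlignedBlock(
            tuple((rid, "".join(res[c] for c in cols)) for rid, res in self.rows)
        )


def _check_alphabet(residues: str, rid: str, *, allow_gap: bool) -> None:
    allowed = ALPHABET | {GAP} if allow_gap else ALPHABET
    for i, ch in enumerate(residues):
        if ch not in allowed:
            raise FastaError(
                f"invalid residue {ch!r} at position {i + 1} in sequence {rid!r}"
            )


def _as_handle(stream: IO[str] | str) -> IO[str]:
    return io.StringIO(stream) if isinstance(stream, str) else stream


def parse_fasta(stream: IO[str] | str) -> list[ProteinRecord]:
    """Parse protein FASTA into :class:`ProteinRecord` objects.

    Residues are upper-cased and ``*`` stop symbols are stripped from the
    sequence ends.  Duplicate ids and residues outside the accepted alphabet
    raise :class:`FastaError`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_as_handle(stream), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().strip("*")
        parts = rec.description.split(None, 1)
        description = parts[1] if len(parts) > 1 else ""
        records.append(ProteinRecord(id=rec.id, residues=residues, description=description))
    return records


def write_fasta(records: Iterable[ProteinRecord], stream: IO[str]) -> None:
    """Write records as FASTA, wrapping sequence lines at 60 columns."""
    for rec in records:
        header = f">{rec.id} {rec.description}".rstrip()
        stream.write(header + "\n")
        for i in range(0, len(rec.residues), _WRAP):
            stream.write(rec.residues[i : i + _WRAP] + "\n")


def parse_aligned_fasta(stream: IO[str] | str) -> AlignedBlock:
    """Parse gapped FASTA into an :class:`AlignedBlock` with uniform rows."""
    rows: list[tuple[str, str]] = []
    for rec in SeqIO.parse(_as_handle(stream), "fasta"):
        rows.append((rec.id, str(rec.seq).upper()))
    return AlignedBlock(tuple(rows))


def write_aligned_fasta(block: AlignedBlock, stream: IO[str]) -> None:
    for rid, res in block.rows:
        stream.write(f">{rid}\n")
        for i in range(0, len(res), _WRAP):
            stream.write(res[i : i + _WRAP] + "\n")


HITS_HEADER = ("seq_id", "domain_kind", "start", "end", "score")


def write_hits_table(hits: Iterable, stream: IO[str]) -> None:
    """Write domain hits as a TSV table sorted by ``(seq_id, start)``.

    Coordinates are 0-based half-open.  Scores are emitted with ``%g``
    formatting (mismatch counts print as integers, log-odds as floats).
    """
    stream.write("\t".join(HITS_HEADER) + "\n")
    for h in sorted(hits, key=lambda h: (h.seq_id, h.start, h.end)):
        kind = h.kind.value if hasattr(h.kind, "value") else str(h.kind)
        stream.write(f"{h.seq_id}\t{kind}\t{h.start}\t{h.end}\t{h.score:g}\n")
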