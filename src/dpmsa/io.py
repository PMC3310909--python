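"""FASTA and aligned-FASTA reading and writing.

A deliberately small reader so that malformed input is reported with line
numbers.  Sequences are upper-cased on input; ``.`` gaps are normalized to
``-``; in DNA mode U is mapped to T (RNA input then aligns as its DNA
equivalent).
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

from .profiles import AlignedGroup

__all__ = ["FastaRecord", "read_fasta", "write_fasta", "write_afa", "read_alignment"]

_WRAP = 60


class FastaRecord(NamedTuple):
    id: str
    seq: str


def read_fasta(path, *, to_dna: bool = True) -> list[FastaRecord]:
    """Parse FASTA preserving record order.

    Raises ``ValueError`` with a line number for data before the first
    header, empty records or duplicate ids; an empty file is an error.
    """
    records: list[FastaRecord] = []
    header: str | None = None
    header_line = 0
    parts: list[str] = []
    seen: set[str] = set()

    def flush() -> None:
        if header is None:
            return
        seq = "".join(parts)
        if not seq:
            raise ValueError(f"{path}: record {header!r} (line {header_line}) is empty")
        records.append(FastaRecord(header, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ValueError(f"{path}, line {lineno}: header has no id")
                if header in seen:
                    raise ValueError(f"{path}, line {lineno}: duplicate id {header!r}")
                seen.add(header)
                header_line = lineno
                parts = []
            else:
                if header is None:
                    raise ValueError(
                        f"{path}, line {lineno}: sequence data before first '>' header"
                    )
                seq = line.upper().replace(".", "-")
                if to_dna:
                    seq = seq.replace("U", "T")
                parts.append(seq)
    flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[FastaRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), _WRAP):
                fh.write(rec.seq[i : i + _WRAP] + "\n")


def write_afa(msa: AlignedGroup, path) -> None:
    """Write an alignment as 60-column wrapped aligned FASTA."""
    write_fasta([FastaRecord(i, r) for i, r in zip(msa.ids, msa.rows)], path)


def read_alignment(path, *, to_dna: bool = True) -> AlignedGroup:
    """Read aligned FASTA into an :class:`AlignedGroup`."""
    records = read_fasta(path, to_dna=to_dna)
    return AlignedGroup([r.seq for r in records], [r.id for r in records])
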