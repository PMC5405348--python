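"""Sequence I/O, translation and open-reading-frame extraction.

The screen operates on bacterial contigs, so translation uses NCBI genetic
code table 11 throughout. ORF calling is an exhaustive six-frame scan from a
start codon (ATG/GTG/TTG) to the next in-frame stop; predictions shorter than
``min_aa`` residues (default 100) are discarded as false positives. For each
(frame, stop codon) only the longest ORF is reported, mirroring the behaviour
of conventional prokaryotic gene callers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.Data import CodonTable

DNA_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: start codons used by the six-frame scan (the common bacterial trio)
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = frozenset(CodonTable.unambiguous_dna_by_id[11].stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaError(ValueError):
    """Malformed FASTA input (empty file, duplicate ids, bad characters)."""


@dataclasses.dataclass(frozen=True)
class NucleotideContig:
    """A DNA contig over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        _validate_alphabet(self.seq, DNA_ALPHABET, self.id)

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass(frozen=True)
class ProteinSequence:
    """A protein over the 20 standard residues; a trailing '*' is stripped."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq
        if seq.endswith("*"):
            seq = seq[:-1]
            object.__setattr__(self, "seq", seq)
        if not seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        _validate_alphabet(seq, AA_ALPHABET, self.id)

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass(frozen=True)
class OrfRecord:
    """A predicted ORF with forward-strand, 0-based half-open coordinates.

    The span includes the stop codon, hence ``protein`` has
    ``(end - start) / 3 - 1`` residues.
    """

    contig_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    frame: int
    protein: ProteinSequence

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError("ORF span not a multiple of 3")
        if not 0 <= self.start < self.end:
            raise ValueError("invalid ORF span")


def _validate_alphabet(seq: str, alphabet: set[str], rec_id: str) -> None:
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise FastaError(
                f"record {rec_id!r}: illegal character {ch!r} at position {pos}"
            )


def read_fasta(path: str | Path, mode: Literal["nucleotide", "protein"]):
    """Read a FASTA file as contigs or proteins.

    Headers are split at the first whitespace into id/description, sequences
    are uppercased, record order is preserved. Duplicate ids, illegal
    characters and empty files raise :class:`FastaError`.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if mode == "nucleotide":
            records.append(NucleotideContig(rec.id, seq))
        else:
            records.append(ProteinSequence(rec.id, seq))
    if not records:
        raise FastaError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[NucleotideContig | ProteinSequence],
                path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    _validate_alphabet(seq, DNA_ALPHABET, "<anonymous>")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, table: int = 11, start_as_met: bool = False) -> str:
    """Translate a DNA string under the given NCBI genetic code table.

    Internal stops are rendered '*'; a terminal stop is stripped. With
    ``start_as_met`` a leading alternative start codon of the table
    (e.g. GTG/TTG under table 11) is rendered as Met.
    """
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    aa = str(Seq(seq).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    if start_as_met and aa:
        codon_table = CodonTable.unambiguous_dna_by_id[table]
        if seq[:3] in codon_table.start_codons:
            aa = "M" + aa[1:]
    return aa


def find_orfs(contig: NucleotideContig, min_aa: int = 100,
              start_as_met: bool = True) -> list[OrfRecord]:
    """Six-frame exhaustive ORF scan with a minimum-length filter.

    An ORF runs from a start codon (ATG/GTG/TTG) to the next in-frame stop,
    stop included in the span; per (strand, frame, stop) only the longest ORF
    (earliest start) is kept. Coordinates are reported on the forward strand,
    0-based half-open, sorted by (start, strand).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    n = len(contig)
    out: list[OrfRecord] = []
    for strand, seq in (("+", contig.seq), ("-", reverse_complement(contig.seq))):
        for frame in range(3):
            start_pos: int | None = None
            for p in range(frame, n - 2, 3):
                codon = seq[p:p + 3]
                if codon in STOP_CODONS:
                    if start_pos is not None:
                        orf = seq[start_pos:p + 3]
                        aa = translate(orf, start_as_met=start_as_met)
                        if len(aa) >= min_aa and "*" not in aa:
                            s, e = start_pos, p + 3
                            if strand == "-":
                                s, e = n - e, n - start_pos
                            prot_id = f"{contig.id}|{s + 1}-{e}|{strand}"
                            out.append(OrfRecord(
                                contig.id, s, e, strand, frame,
                                ProteinSequence(prot_id, aa)))
                    start_pos = None
                elif start_pos is None and codon in START_CODONS:
                    start_pos = p
    out.sort(key=lambda o: (o.start, o.strand, o.end))
    return out


def orf_table(orfs: Iterable[OrfRecord]) -> list[dict]:
    """ORF records as rows with 1-based inclusive coordinates (GenBank style)."""
    return [
        {
            "contig_id": o.contig_id,
            "start_1based": o.start + 1,
            "end_1based": o.end,
            "strand": o.strand,
            "frame": o.frame,
            "aa_length": len(o.protein),
            "protein_id": o.protein.id,
        }
        for o in orfs
    ]
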