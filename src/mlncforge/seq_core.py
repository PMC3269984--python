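"""Sequence data model, FASTA I/O and elementary sequence operations.

Transcripts (unigenes: assembled contigs or singleton reads) are stored in
the DNA alphabet internally; RNA inputs such as mature miRNAs are
normalised on read (U -> T) and rendered back as RNA only in reports.
Coordinates are 0-based half-open internally and 1-based inclusive in
user-facing tabular reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


class FastaParseError(ValueError):
    """Raised for malformed FASTA records; message names the offending line."""


@dataclass
class Transcript:
    """A unigene: assembled contig or singleton read representing one gene.

    ``read_count`` carries the number of supporting 454 reads where known;
    synthetic transcripts use source='synthetic'.
    """

    id: str
    seq: str
    source: str = "contig"  # contig | singleton | synthetic
    read_count: int = 0
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = normalize_seq(self.seq)
        if self.source not in ("contig", "singleton", "synthetic"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OrfCall:
    """An open reading frame on either strand of a transcript.

    ``start``/``end`` are 0-based half-open on the forward strand.
    ``aa_length`` excludes the stop codon.  ``complete`` means the ORF has
    both a start codon and an in-frame stop inside the sequence; 3'-open
    partials (ATG to sequence end, no stop) are reported with
    complete=False because 454 unigenes are often truncated.
    """

    transcript_id: str
    strand: str  # '+' or '-'
    frame: int  # 0..2
    start: int
    end: int
    aa_length: int
    complete: bool

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("need 0 <= start < end")
        if self.complete and (self.end - self.start) % 3 != 0:
            raise ValueError("complete ORF span must be divisible by 3")


def normalize_seq(seq: str) -> str:
    """Upper-case, U->T; reject characters outside A/C/G/T/U/N."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_ALPHABET
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    s = normalize_seq(seq)
    return s.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T); N excluded from numerator and denominator."""
    s = normalize_seq(seq)
    counted = sum(s.count(b) for b in "ACGT")
    if counted == 0:
        raise ValueError("gc_fraction undefined: no unambiguous bases")
    return (s.count("G") + s.count("C")) / counted


def read_fasta(path: str | Path, source: str = "contig") -> list[Transcript]:
    """Read a FASTA file into Transcripts.

    The id is the header token before the first whitespace; the remainder is
    kept as ``description``.  Sequences are normalised (upper case, U->T).
    """
    path = Path(path)
    transcripts: list[Transcript] = []
    with open(path) as handle:
        first = handle.readline()
        if first and not first.startswith(">"):
            raise FastaParseError(f"{path}: line 1 is not a FASTA header")
        handle.seek(0)
        for header, seq in SimpleFastaParser(handle):
            if not seq:
                raise FastaParseError(f"{path}: empty sequence for record {header!r}")
            parts = header.split(None, 1)
            rec_id = parts[0]
            desc = parts[1] if len(parts) == 2 else ""
            transcripts.append(
                Transcript(id=rec_id, seq=seq, source=source, description=desc)
            )
    if not transcripts:
        logger.warning("no records in %s", path)
    ids = [t.id for t in transcripts]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FastaParseError(f"{path}: duplicate ids {dupes}")
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: str | Path, width: int = 60) -> None:
    """Write transcripts as FASTA, wrapped to ``width`` columns."""
    with open(path, "w") as handle:
        for t in transcripts:
            header = f">{t.id}"
            if t.description:
                header += f" {t.description}"
            handle.write(header + "\n")
            for i in range(0, len(t.seq), width):
                handle.write(t.seq[i : i + width] + "\n")


def _scan_frame(seq: str, frame: int) -> Iterator[tuple[int, int, bool]]:
    """Yield (start, end, complete) codon-coordinate ORFs in one frame.

    Coordinates are on ``seq`` directly.  A maximal ORF runs from the first
    ATG after the previous stop to the next in-frame stop (complete) or to
    the last full codon (3'-open partial).
    """
    n = len(seq)
    start: int | None = None
    i = frame
    while i + 3 <= n:
        codon = seq[i : i + 3]
        if start is None:
            if codon == START_CODON:
                start = i
        elif codon in STOP_CODONS:
            yield start, i + 3, True
            start = None
        i += 3
    if start is not None and i > start:
        yield start, i, False


def find_orfs(t: Transcript) -> list[OrfCall]:
    """All maximal ORFs on both strands in all three frames.

    Complete ORFs run ATG -> first in-frame stop; 3'-open partials (ATG to
    sequence end without a stop) are reported with complete=False.  Sorted
    by aa_length descending, then coordinates for determinism.
    """
    if t.length < 3:
        raise ValueError("transcript shorter than one codon")
    calls: list[OrfCall] = []
    n = t.length
    for strand, seq in (("+", t.seq), ("-", reverse_complement(t.seq))):
        for frame in range(3):
            for s, e, complete in _scan_frame(seq, frame):
                aa = (e - s) // 3 - 1 if complete else (e - s) // 3
                if aa <= 0:
                    continue
                if strand == "+":
                    fs, fe = s, e
                else:  # map back to forward-strand coordinates
                    fs, fe = n - e, n - s
                calls.append(
                    OrfCall(
                        transcript_id=t.id,
                        strand=strand,
                        frame=frame,
                        start=fs,
                        end=fe,
                        aa_length=aa,
                        complete=complete,
                    )
                )
    calls.sort(key=lambda c: (-c.aa_length, c.start, c.end, c.strand, c.frame))
    return calls


def max_orf_aa(orfs: Iterable[OrfCall], include_partials: bool = True) -> int:
    """Longest ORF length in amino acids (0 if none)."""
    lengths = [o.aa_length for o in orfs if o.complete or include_partials]
    return max(lengths, default=0)


def write_orf_report(orfs: Iterable[OrfCall], path: str | Path) -> None:
    """Tab-separated ORF report with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tstrand\tframe\tstart1\tend1\taa_length\tcomplete\n")
        for o in orfs:
            fh.write(
                f"{o.transcript_id}\t{o.strand}\t{o.frame}\t{o.start + 1}\t{o.end}"
                f"\t{o.aa_length}\t{str(o.complete).lower()}\n"
            )


def as_rna(seq: str) -> str:
    """Render an internally stored DNA sequence as RNA (T -> U)."""
    return normalize_seq(seq).replace("T", "U")
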