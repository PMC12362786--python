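"""Transcript models and coordinate arithmetic.

A :class:`TranscriptModel` is the coordinate frame every variant-level call
(consequence class, NMD escape, amino-acid position) is made in.  Genomic
coordinates are 0-based half-open internally; CDS and protein coordinates are
1-based, following the conventions of HGVS-style reporting.  Exons are stored
in ascending genomic order regardless of strand; transcription order is
derived from the strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .exceptions import InvalidInputError

Interval = tuple[int, int]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered exons, CDS bounds, optional coding sequence.

    Parameters
    ----------
    gene, transcript_id : str
        Gene symbol and transcript identifier.
    chrom : str
        Contig name.
    strand : str
        ``"+"`` or ``"-"``.
    exons : tuple of (start, end)
        Genomic exon intervals, 0-based half-open, ascending, non-overlapping.
    cds_start, cds_end : int
        Genomic CDS bounds (0-based half-open) spanning one or more exons.
    cds_sequence : str, optional
        Coding-strand CDS sequence (5'->3' in transcription direction).  When
        present its length must equal :attr:`cds_length`; it enables codon-level
        consequence resolution for SNVs.
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds_start: int
    cds_end: int
    cds_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvalidInputError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise InvalidInputError("transcript must have at least one exon")
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise InvalidInputError(f"empty or inverted exon ({start}, {end})")
            if start < prev_end:
                raise InvalidInputError("exons must be ascending and non-overlapping")
            prev_end = end
        if not (self.exons[0][0] <= self.cds_start < self.cds_end <= self.exons[-1][1]):
            raise InvalidInputError("CDS bounds must lie within the exon span")
        if self.cds_sequence is not None and len(self.cds_sequence) != self.cds_length:
            raise InvalidInputError(
                f"cds_sequence length {len(self.cds_sequence)} != cds_length {self.cds_length}"
            )

    # ------------------------------------------------------------------ spans
    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    # ---------------------------------------------------------- coding frame
    def coding_segments(self) -> list[Interval]:
        """Genomic CDS-exon intersections in *transcription* order."""
        segs = []
        for start, end in self.exons:
            s, e = max(start, self.cds_start), min(end, self.cds_end)
            if s < e:
                segs.append((s, e))
        if self.strand == "-":
            segs.reverse()
        return segs

    def coding_exon_lengths(self) -> list[int]:
        """Lengths (nt) of coding exon segments in transcription order."""
        return [e - s for s, e in self.coding_segments()]

    @property
    def cds_length(self) -> int:
        return sum(min(e, self.cds_end) - max(s, self.cds_start)
                   for s, e in self.exons
                   if max(s, self.cds_start) < min(e, self.cds_end))

    @property
    def protein_length(self) -> int:
        """Protein length in aa; CDS length / 3 (all codons counted)."""
        return self.cds_length // 3

    # ------------------------------------------------------------- coordinate
    def genomic_to_cds(self, pos0: int) -> Optional[int]:
        """Map a genomic position (0-based) to a 1-based CDS offset.

        Returns ``None`` when the position is not inside a coding segment.
        """
        offset = 0
        for s, e in self.coding_segments():
            if s <= pos0 < e:
                if self.strand == "+":
                    return offset + (pos0 - s) + 1
                return offset + (e - 1 - pos0) + 1
            offset += e - s
        return None

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Map a 1-based CDS offset to its genomic position (0-based)."""
        if not 1 <= cds_pos <= self.cds_length:
            raise InvalidInputError(f"cds_pos {cds_pos} outside [1, {self.cds_length}]")
        remaining = cds_pos - 1
        for s, e in self.coding_segments():
            seg_len = e - s
            if remaining < seg_len:
                return s + remaining if self.strand == "+" else e - 1 - remaining
            remaining -= seg_len
        raise AssertionError("unreachable")  # pragma: no cover

    def cds_exon_index(self, cds_pos: int) -> int:
        """0-based index (transcription order) of the coding exon holding cds_pos."""
        if not 1 <= cds_pos <= self.cds_length:
            raise InvalidInputError(f"cds_pos {cds_pos} outside [1, {self.cds_length}]")
        cum = 0
        for i, length in enumerate(self.coding_exon_lengths()):
            cum += length
            if cds_pos <= cum:
                return i
        raise AssertionError("unreachable")  # pragma: no cover

    def intron_offset(self, pos0: int) -> Optional[int]:
        """Distance (>=1, nt) from an intronic position to the nearest exon edge.

        Returns ``None`` when the position is exonic or outside the transcript.
        """
        if not (self.tx_start <= pos0 < self.tx_end):
            return None
        for i, (s, e) in enumerate(self.exons):
            if s <= pos0 < e:
                return None
            if i + 1 < len(self.exons) and e <= pos0 < self.exons[i + 1][0]:
                from_prev = pos0 - e + 1
                to_next = self.exons[i + 1][0] - pos0
                return min(from_prev, to_next)
        return None

    def is_exonic(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.exons)

    def utr_side(self, pos0: int) -> Optional[str]:
        """``"utr5"``/``"utr3"`` for exonic positions outside the CDS, else None."""
        if not self.is_exonic(pos0):
            return None
        if self.cds_start <= pos0 < self.cds_end:
            return None
        upstream = pos0 < self.cds_start
        if self.strand == "-":
            upstream = not upstream
        return "utr5" if upstream else "utr3"


def aa_from_cds(cds_pos: int) -> int:
    """First affected codon: aa = ceil(cds_pos / 3)."""
    if cds_pos < 1:
        raise InvalidInputError(f"cds_pos must be >= 1, got {cds_pos}")
    return math.ceil(cds_pos / 3)


def flip_strand(transcript: TranscriptModel, contig_length: int) -> TranscriptModel:
    """Mirror a transcript onto the opposite strand of a reversed contig.

    Used in tests to assert that coordinate-dependent calls are stable under
    strand flips.  The CDS sequence (transcription-direction) is unchanged.
    """
    new_exons = tuple(sorted((contig_length - e, contig_length - s)
                             for s, e in transcript.exons))
    return TranscriptModel(
        gene=transcript.gene,
        transcript_id=transcript.transcript_id,
        chrom=transcript.chrom,
        strand="-" if transcript.strand == "+" else "+",
        exons=new_exons,
        cds_start=contig_length - transcript.cds_end,
        cds_end=contig_length - transcript.cds_start,
        cds_sequence=transcript.cds_sequence,
    )
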