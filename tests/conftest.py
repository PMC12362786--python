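import numpy as np
import pytest

from deafscape.transcripts import TranscriptModel

_CODON_FILL = "GCTGATCGTAAGCTGATGGAACGTTTCCCAGGT"  # stop-free filler


def build_transcript(coding_lengths, strand="+", gene="G1", tx_id="T1",
                     chrom="chr_t", intron=500, utr5=60, utr3=90, start=1000,
                     with_sequence=True):
    """Transcript with the given coding exon lengths (transcription order)."""
    lengths = list(coding_lengths)
    if strand == "-":
        lengths = lengths[::-1]  # genomic ascending order
    coding = []
    pos = start
    for i, length in enumerate(lengths):
        coding.append((pos, pos + length))
        pos += length + (intron if i < len(lengths) - 1 else 0)
    cds_start, cds_end = coding[0][0], coding[-1][1]
    exons = [list(seg) for seg in coding]
    if strand == "+":
        exons[0][0] -= utr5
        exons[-1][1] += utr3
    else:
        exons[0][0] -= utr3
        exons[-1][1] += utr5
    seq = None
    if with_sequence:
        cds_len = sum(coding_lengths)
        body = (_CODON_FILL * (cds_len // len(_CODON_FILL) + 2))[: cds_len - 3]
        seq = "ATG" + body
    return TranscriptModel(gene=gene, transcript_id=tx_id, chrom=chrom,
                           strand=strand,
                           exons=tuple((s, e) for s, e in exons),
                           cds_start=cds_start, cds_end=cds_end,
                           cds_sequence=seq)


@pytest.fixture
def three_exon_transcript():
    """Coding exons of 300/150/90 nt: protein length 180 aa."""
    return build_transcript([300, 150, 90])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
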