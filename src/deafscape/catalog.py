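"""Variant catalog harmonization.

Consequence classification against a transcript model, normalization of
pathogenicity labels from heterogeneous sources (five-tier clinical dialects
and HGMD's DM/DM? scheme), consensus + conflict calling across sources,
frequency binning of the allele-count spectrum, and the frequency-driven
reclassification rules used to demote over-called pathogenic variants in
inheritance-aware fashion (MAF > 0.5% for recessive genes, > 0.1% for
dominant ones, plus a control-observation rule for dominant variants).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .exceptions import (
    InvalidInputError,
    MissingDataError,
    OutOfScopeError,
    UnknownDialectError,
)
from .transcripts import TranscriptModel, aa_from_cds

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class ConsequenceClass(str, Enum):
    """Functional consequence of a variant on one transcript."""

    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    START_LOSS = "start_loss"
    STOP_LOSS = "stop_loss"
    CANONICAL_SPLICE = "canonical_splice"
    SPLICE_REGION = "splice_region"
    UTR5 = "utr5"
    UTR3 = "utr3"
    UPSTREAM_DOWNSTREAM = "upstream_downstream"
    DEEP_INTRONIC = "deep_intronic"


class FrequencyBin(str, Enum):
    """Exhaustive, mutually exclusive allele-count/frequency strata."""

    ABSENT = "absent"
    SINGLETON = "singleton"
    DOUBLETON = "doubleton"
    TRIPLETON = "tripleton"
    QUADRUPLETON = "quadrupleton"
    RARE_POLYMORPHIC = "rare_polymorphic"
    COMMON = "common"


class ConflictClass(str, Enum):
    NONE = "none"
    PLP_VS_BLB = "plp_vs_blb"
    PLP_VS_VUS = "plp_vs_vus"


class ReclassDecision(str, Enum):
    TO_BLB_FREQUENCY = "to_BLB_frequency"
    TO_BLB_FREQUENCY_PLUS_PREDICTION = "to_BLB_frequency_plus_prediction"
    TO_BLB_IN_CONTROLS = "to_BLB_in_controls"
    UNCHANGED = "unchanged"
    NOT_APPLICABLE = "not_applicable"


@dataclass
class VariantRecord:
    """One variant: coordinates, consequence, source labels, frequencies.

    ``pos`` follows the VCF convention (1-based; for indels the position of
    the anchor base).  ``allele_count``/``allele_frequency`` are maps keyed by
    population name.  ``extra`` carries generator bookkeeping (e.g. the latent
    truth class of a synthetic variant) and is never consulted by analyses.
    """

    gene: str
    transcript_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Optional[ConsequenceClass] = None
    cds_pos: Optional[int] = None
    aa_pos: Optional[int] = None
    source_labels: dict = field(default_factory=dict)
    allele_count: dict = field(default_factory=dict)
    allele_frequency: dict = field(default_factory=dict)
    inheritance: Optional[str] = None  # AD, AR, AD/AR, XL, MT
    extra: dict = field(default_factory=dict)

    def max_maf(self) -> Optional[float]:
        if not self.allele_frequency:
            return None
        return max(self.allele_frequency.values())


@dataclass
class ConsensusResult:
    normalized_labels: dict
    consensus: str  # one of {"P/LP", "VUS", "B/LB", "unclassified"}
    agreement_count: int
    conflict_class: ConflictClass


@dataclass
class ReclassResult:
    decision: ReclassDecision
    reason: str


# --------------------------------------------------------------------------
# consequence classification
# --------------------------------------------------------------------------

def classify_consequence(
    variant: VariantRecord,
    transcript: TranscriptModel,
    flank: int = 1000,
) -> ConsequenceClass:
    """Assign exactly one consequence class to a variant on a transcript.

    Intronic positions 1-2 nt from an exon edge are canonical splice sites,
    3-8 nt are splice regions, deeper positions deep-intronic.  Coding SNVs
    are resolved at codon level using the transcript CDS sequence; coding
    indels by length modulo 3.  Positions beyond ``flank`` nt of the
    transcript raise :class:`OutOfScopeError`.
    """
    if variant.gene != transcript.gene:
        raise InvalidInputError(
            f"variant gene {variant.gene} != transcript gene {transcript.gene}")
    pos0 = variant.pos - 1
    if pos0 < transcript.tx_start - flank or pos0 >= transcript.tx_end + flank:
        raise OutOfScopeError(
            f"position {variant.pos} outside transcript +/- {flank} nt")
    if pos0 < transcript.tx_start or pos0 >= transcript.tx_end:
        return ConsequenceClass.UPSTREAM_DOWNSTREAM

    offset = transcript.intron_offset(pos0)
    if offset is not None:
        if offset <= 2:
            return ConsequenceClass.CANONICAL_SPLICE
        if offset <= 8:
            return ConsequenceClass.SPLICE_REGION
        return ConsequenceClass.DEEP_INTRONIC

    utr = transcript.utr_side(pos0)
    if utr == "utr5":
        return ConsequenceClass.UTR5
    if utr == "utr3":
        return ConsequenceClass.UTR3

    # coding
    if len(variant.ref) != len(variant.alt):
        delta = abs(len(variant.ref) - len(variant.alt))
        if delta % 3 == 0:
            return ConsequenceClass.INFRAME_INDEL
        return ConsequenceClass.FRAMESHIFT
    if len(variant.ref) != 1:
        # MNV: treat as in-frame substitution of >1 nt; resolve like missense
        # by first changed codon when sequence available.
        raise InvalidInputError("multi-nucleotide substitutions are not supported")
    return _classify_coding_snv(variant, transcript, pos0)


def _classify_coding_snv(
    variant: VariantRecord, transcript: TranscriptModel, pos0: int
) -> ConsequenceClass:
    if transcript.cds_sequence is None:
        raise MissingDataError(
            "codon-level classification requires a transcript CDS sequence")
    cds_pos = transcript.genomic_to_cds(pos0)
    assert cds_pos is not None
    ref_base, alt_base = variant.ref.upper(), variant.alt.upper()
    if transcript.strand == "-":
        ref_base, alt_base = COMPLEMENT[ref_base], COMPLEMENT[alt_base]
    seq = transcript.cds_sequence.upper()
    if seq[cds_pos - 1] != ref_base:
        raise InvalidInputError(
            f"ref allele {variant.ref} does not match CDS base at cds_pos {cds_pos}")
    codon_idx = (cds_pos - 1) // 3
    codon = seq[codon_idx * 3: codon_idx * 3 + 3]
    within = (cds_pos - 1) % 3
    new_codon = codon[:within] + alt_base + codon[within + 1:]
    old_aa = str(Seq(codon).translate())
    new_aa = str(Seq(new_codon).translate())
    if new_aa == old_aa:
        return ConsequenceClass.SYNONYMOUS
    if old_aa == "*":
        return ConsequenceClass.STOP_LOSS
    if new_aa == "*":
        return ConsequenceClass.STOP_GAIN
    if codon_idx == 0 and old_aa == "M":
        return ConsequenceClass.START_LOSS
    return ConsequenceClass.MISSENSE


# --------------------------------------------------------------------------
# pathogenicity label normalization / consensus
# --------------------------------------------------------------------------

_FIVE_TIER = {
    "pathogenic": "P",
    "likely pathogenic": "LP",
    "likely_pathogenic": "LP",
    "uncertain significance": "VUS",
    "uncertain_significance": "VUS",
    "vus": "VUS",
    "likely benign": "LB",
    "likely_benign": "LB",
    "benign": "B",
    "p": "P",
    "lp": "LP",
    "lb": "LB",
    "b": "B",
}

_HGMD = {"dm": "P", "dm?": "LP"}

#: source -> raw-label mapping; five-tier sources share one dialect.
DIALECTS: dict[str, Mapping[str, str]] = {
    "CDGC": _FIVE_TIER,
    "ClinVar": _FIVE_TIER,
    "DVD": _FIVE_TIER,
    "HGMD": _HGMD,
}

PLP = {"P", "LP"}
BLB = {"B", "LB"}


def normalize_source_label(source: str, raw_label: str) -> str:
    """Map a source-specific raw label onto {P, LP, VUS, LB, B, unclassified}."""
    if source not in DIALECTS:
        raise UnknownDialectError(source)
    if raw_label is None:
        return "unclassified"
    key = raw_label.strip().lower()
    return DIALECTS[source].get(key, "unclassified")


def consensus_and_conflict(source_labels: Mapping[str, str]) -> ConsensusResult:
    """Form a cross-source consensus and flag medically significant conflicts.

    Sources spanning P/LP and B/LB are the severe conflict class; P/LP vs VUS
    the milder one (the consensus is then still reported as the P/LP stratum,
    with the conflict recorded separately).  Order of sources never matters.
    """
    if not source_labels:
        raise MissingDataError("no source labels to form a consensus from")
    normalized = {src: normalize_source_label(src, lab)
                  for src, lab in source_labels.items()}
    strata = set(normalized.values())
    has_plp = bool(strata & PLP)
    has_blb = bool(strata & BLB)
    has_vus = "VUS" in strata

    if has_plp and has_blb:
        conflict = ConflictClass.PLP_VS_BLB
        consensus = "VUS"
    elif has_plp and has_vus:
        conflict = ConflictClass.PLP_VS_VUS
        consensus = "P/LP"
    else:
        conflict = ConflictClass.NONE
        if has_plp:
            consensus = "P/LP"
        elif has_vus:
            consensus = "VUS"
        elif has_blb:
            consensus = "B/LB"
        else:
            consensus = "unclassified"

    stratum = {"P/LP": PLP, "B/LB": BLB, "VUS": {"VUS"},
               "unclassified": {"unclassified"}}[consensus]
    agreement = sum(1 for lab in normalized.values() if lab in stratum)
    return ConsensusResult(normalized, consensus, agreement, conflict)


# --------------------------------------------------------------------------
# frequency rules
# --------------------------------------------------------------------------

def frequency_bin(allele_count: int, maf: float,
                  rare_maf: float = 0.0002) -> FrequencyBin:
    """Bin a variant by allele count and minor allele frequency.

    AC 0 -> absent; AC 1..4 -> singleton..quadrupleton; AC > 4 with
    MAF < ``rare_maf`` -> rare_polymorphic; anything else -> common.
    """
    if allele_count < 0:
        raise InvalidInputError(f"allele count must be >= 0, got {allele_count}")
    if allele_count == 0:
        return FrequencyBin.ABSENT
    if allele_count <= 4:
        return [FrequencyBin.SINGLETON, FrequencyBin.DOUBLETON,
                FrequencyBin.TRIPLETON, FrequencyBin.QUADRUPLETON][allele_count - 1]
    if maf < rare_maf:
        return FrequencyBin.RARE_POLYMORPHIC
    return FrequencyBin.COMMON


@dataclass(frozen=True)
class ReclassConfig:
    """Thresholds for the frequency-based reclassification rules."""

    maf_ar: float = 0.005
    maf_ad: float = 0.001
    #: secondary rule fires at half the primary threshold plus a benign
    #: computational-prediction flag
    secondary_fraction: float = 0.5
    min_controls: int = 2


def apply_frequency_reclassification(
    variant: VariantRecord,
    benign_prediction: bool = False,
    control_count: int = 0,
    config: ReclassConfig = ReclassConfig(),
) -> ReclassResult:
    """Decide whether a P/LP call should be demoted to B/LB on frequency.

    Rules, in priority order: (1) max population MAF above the
    inheritance-specific threshold (0.5% AR / 0.1% AD); (2) MAF above half
    that threshold combined with a benign computational prediction; (3) a
    dominant variant observed in >= ``min_controls`` unaffected controls.
    Missing inheritance yields a not-applicable result, not an error.  The
    decision is a pure function of its inputs, hence idempotent.
    """
    if variant.inheritance is None:
        return ReclassResult(ReclassDecision.NOT_APPLICABLE, "no inheritance mode")
    maf = variant.max_maf()
    if maf is None:
        return ReclassResult(ReclassDecision.NOT_APPLICABLE, "no population MAF")

    mode = variant.inheritance
    dominant = mode in ("AD", "XL")
    # AD/AR genes take the stricter (higher) recessive threshold; MT treated
    # as recessive-like.
    threshold = config.maf_ad if dominant else config.maf_ar

    if maf > threshold:
        return ReclassResult(
            ReclassDecision.TO_BLB_FREQUENCY,
            f"max MAF {maf:.3g} > {threshold:.3g} ({mode})")
    if benign_prediction and maf > threshold * config.secondary_fraction:
        return ReclassResult(
            ReclassDecision.TO_BLB_FREQUENCY_PLUS_PREDICTION,
            f"max MAF {maf:.3g} > {threshold * config.secondary_fraction:.3g} "
            f"with benign prediction")
    if dominant and control_count >= config.min_controls:
        return ReclassResult(
            ReclassDecision.TO_BLB_IN_CONTROLS,
            f"seen in {control_count} unaffected controls (AD)")
    return ReclassResult(ReclassDecision.UNCHANGED, "no rule fired")


# --------------------------------------------------------------------------
# catalog summary
# --------------------------------------------------------------------------

def summarize_catalog(records: Sequence[VariantRecord],
                      population: str = "gnomad") -> pd.DataFrame:
    """Counts and proportions by consequence, frequency bin, and conflict class.

    Returns a long-format table with columns ``stratification``, ``category``,
    ``count`` and ``proportion``; proportions sum to 1 within each
    stratification (when any records exist).
    """
    rows = []
    n = len(records)

    def _tally(name: str, values) -> None:
        counts = Counter(values)
        for category, count in sorted(counts.items()):
            rows.append({
                "stratification": name,
                "category": category,
                "count": count,
                "proportion": count / n if n else 0.0,
            })

    if n:
        _tally("consequence",
               [r.consequence.value if r.consequence else "unknown" for r in records])
        _tally("frequency_bin",
               [frequency_bin(r.allele_count.get(population, 0),
                              r.allele_frequency.get(population, 0.0)).value
                for r in records])
        conflicts = []
        for r in records:
            if r.source_labels:
                conflicts.append(consensus_and_conflict(r.source_labels).conflict_class.value)
            else:
                conflicts.append("none")
        _tally("conflict_class", conflicts)
    return pd.DataFrame(rows, columns=["stratification", "category", "count", "proportion"])


def conflict_report(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Per-variant consensus/conflict table for records with any source label."""
    rows = []
    for r in records:
        if not r.source_labels:
            continue
        res = consensus_and_conflict(r.source_labels)
        rows.append({
            "gene": r.gene, "chrom": r.chrom, "pos": r.pos,
            "ref": r.ref, "alt": r.alt,
            "consensus": res.consensus,
            "agreement_count": res.agreement_count,
            "conflict_class": res.conflict_class.value,
            "labels": ";".join(f"{s}:{l}" for s, l in sorted(res.normalized_labels.items())),
        })
    return pd.DataFrame(rows, columns=["gene", "chrom", "pos", "ref", "alt",
                                       "consensus", "agreement_count",
                                       "conflict_class", "labels"])
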