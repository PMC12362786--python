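"""Protein-truncating variants: mechanism statistics and NMD-escape calls.

A PTV is a stop-gain, frameshift, start-loss, stop-loss or canonical splice
change.  Premature termination codons escape nonsense-mediated decay when
they sit in the last coding exon or within the final 50 nt of the penultimate
coding exon (single-coding-exon transcripts always escape: there is no
downstream exon junction).  Per-gene composition of P/LP and PTV strata
places genes in mechanism quadrants separating loss-of-function genes from
LoF-tolerant ones, and an OLS fit of PTV count on CDS size flags genes with
fewer truncating variants than their coding length predicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ConsequenceClass, VariantRecord, consensus_and_conflict
from .exceptions import DegenerateFitError, InvalidInputError
from .transcripts import TranscriptModel

PTV_CLASSES = frozenset({
    ConsequenceClass.STOP_GAIN,
    ConsequenceClass.FRAMESHIFT,
    ConsequenceClass.START_LOSS,
    ConsequenceClass.STOP_LOSS,
    ConsequenceClass.CANONICAL_SPLICE,
})


def is_ptv(consequence: ConsequenceClass) -> bool:
    """True exactly for the five protein-truncating consequence classes."""
    if not isinstance(consequence, ConsequenceClass):
        raise InvalidInputError(f"not a ConsequenceClass: {consequence!r}")
    return consequence in PTV_CLASSES


class NmdReason(str, Enum):
    LAST_EXON = "last_exon"
    PENULTIMATE_50NT = "penultimate_50nt"
    SINGLE_EXON = "single_exon"
    NMD_TARGET = "nmd_target"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class NmdCall:
    escape: bool
    reason: NmdReason
    ptc_cds_pos: Optional[int]


def nmd_region(cds_pos: int, coding_exon_lengths: Sequence[int],
               window: int = 50) -> NmdReason:
    """Label one CDS position by the NMD rule given coding exon lengths.

    The three regions (last exon, final ``window`` nt of the penultimate
    exon, remainder) partition the CDS.  The window never extends past the
    penultimate exon's 5' end, and the boundary position exactly ``window``
    nt from the exon's 3' end is inside the window (escape).
    """
    lengths = list(coding_exon_lengths)
    total = sum(lengths)
    if not 1 <= cds_pos <= total:
        raise InvalidInputError(f"cds_pos {cds_pos} outside CDS of length {total}")
    if len(lengths) == 1:
        return NmdReason.SINGLE_EXON
    last_start = total - lengths[-1] + 1
    if cds_pos >= last_start:
        return NmdReason.LAST_EXON
    penult_start = last_start - lengths[-2]
    window_start = max(penult_start, last_start - window)
    if cds_pos >= window_start:
        return NmdReason.PENULTIMATE_50NT
    return NmdReason.NMD_TARGET


def nmd_escape_call(variant: VariantRecord, transcript: TranscriptModel,
                    window: int = 50) -> NmdCall:
    """NMD-escape call for one PTV.

    Frameshift and stop-gain PTCs are placed at the variant's own CDS
    position (the first affected codon).  Canonical splice PTVs have no
    defined PTC position and return a not-applicable call.
    """
    if variant.consequence is None or not is_ptv(variant.consequence):
        raise InvalidInputError("nmd_escape_call expects a PTV")
    if variant.consequence is ConsequenceClass.CANONICAL_SPLICE:
        return NmdCall(escape=False, reason=NmdReason.NOT_APPLICABLE, ptc_cds_pos=None)
    cds_pos = variant.cds_pos
    if cds_pos is None:
        cds_pos = transcript.genomic_to_cds(variant.pos - 1)
    if cds_pos is None:
        raise InvalidInputError("PTV has no resolvable CDS position")
    reason = nmd_region(cds_pos, transcript.coding_exon_lengths(), window=window)
    return NmdCall(escape=reason is not NmdReason.NMD_TARGET,
                   reason=reason, ptc_cds_pos=cds_pos)


# --------------------------------------------------------------------------
# per-gene mechanism summary
# --------------------------------------------------------------------------

class MechanismQuadrant(str, Enum):
    LOF_MECHANISM = "lof_mechanism"      # both ratios > 50%
    LOF_TOLERANT = "lof_tolerant"        # both ratios <= 50%
    MIXED_HIGH_PLP = "mixed_high_plp"    # high P/LP ratio of PTVs only
    MIXED_HIGH_PTV = "mixed_high_ptv"    # high PTV ratio of P/LP only
    UNASSIGNED = "unassigned"


@dataclass
class GenePtvSummary:
    gene: str
    n_ptv: int
    n_plp: int
    n_plp_ptv: int
    plp_ratio_of_ptvs: Optional[float]
    ptv_ratio_of_plp: Optional[float]
    quadrant: MechanismQuadrant


def _is_plp(record: VariantRecord) -> bool:
    if not record.source_labels:
        return False
    return consensus_and_conflict(record.source_labels).consensus == "P/LP"


def gene_ptv_summary(records: Sequence[VariantRecord]) -> GenePtvSummary:
    """P/LP-vs-PTV composition for one gene's records.

    ``plp_ratio_of_ptvs`` = P/LP PTVs / classified PTVs (PTVs with any source
    label); ``ptv_ratio_of_plp`` = P/LP PTVs / all P/LP variants.  The
    quadrant applies the >50% rule to both ratios; it stays unassigned when
    either denominator is zero.
    """
    genes = {r.gene for r in records}
    if len(genes) > 1:
        raise InvalidInputError(f"records span multiple genes: {sorted(genes)}")
    gene = genes.pop() if genes else ""

    ptvs = [r for r in records if r.consequence is not None and is_ptv(r.consequence)]
    classified_ptvs = [r for r in ptvs if r.source_labels]
    plp = [r for r in records if _is_plp(r)]
    plp_ptv = [r for r in plp if r.consequence is not None and is_ptv(r.consequence)]

    ratio_a = len(plp_ptv) / len(classified_ptvs) if classified_ptvs else None
    ratio_b = len(plp_ptv) / len(plp) if plp else None
    if ratio_a is None or ratio_b is None:
        quadrant = MechanismQuadrant.UNASSIGNED
    elif ratio_a > 0.5 and ratio_b > 0.5:
        quadrant = MechanismQuadrant.LOF_MECHANISM
    elif ratio_a > 0.5:
        quadrant = MechanismQuadrant.MIXED_HIGH_PLP
    elif ratio_b > 0.5:
        quadrant = MechanismQuadrant.MIXED_HIGH_PTV
    else:
        quadrant = MechanismQuadrant.LOF_TOLERANT
    return GenePtvSummary(gene=gene, n_ptv=len(ptvs), n_plp=len(plp),
                          n_plp_ptv=len(plp_ptv),
                          plp_ratio_of_ptvs=ratio_a, ptv_ratio_of_plp=ratio_b,
                          quadrant=quadrant)


@dataclass
class PtvCdsFit:
    slope: float
    intercept: float
    r_squared: float
    flagged_genes: list
    residuals: pd.Series


def ptv_vs_cds_fit(ptv_counts: Sequence[int], cds_lengths: Sequence[int],
                   genes: Optional[Sequence[str]] = None,
                   flag_z: float = -2.0) -> PtvCdsFit:
    """OLS of per-gene PTV count on CDS length, with intolerance flagging.

    Genes whose standardized residual falls below ``flag_z`` carry fewer PTVs
    than their coding size predicts (candidate PTV-intolerant).
    """
    y = np.asarray(ptv_counts, dtype=float)
    x = np.asarray(cds_lengths, dtype=float)
    if len(x) < 3:
        raise InvalidInputError("need >= 3 genes to fit")
    if np.ptp(x) == 0:
        raise DegenerateFitError("CDS lengths are constant")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    sd = resid.std(ddof=2) if len(x) > 2 else 0.0
    z = resid / sd if sd > 0 else np.zeros_like(resid)
    idx = genes if genes is not None else list(range(len(x)))
    residuals = pd.Series(resid, index=idx, name="residual")
    flagged = [g for g, zz in zip(idx, z) if zz < flag_z]
    return PtvCdsFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue ** 2),
                     flagged_genes=flagged, residuals=residuals)
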