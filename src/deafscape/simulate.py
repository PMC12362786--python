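"""Synthetic inputs with the statistical structure the analyses assume.

Generators for transcript models (multi-exon genes with UTRs and a stop-free
random CDS), protein domain annotations, variant catalogs with a planted
domain odds ratio, multi-source pathogenicity labels with a controllable
conflict rate, a singleton-dominated allele-count spectrum, labeled gene
feature matrices with a controllable effect size, and correlated cross-
species expression pairs.  Every generator is a pure function of its config
and seed: identical inputs give byte-identical outputs.

The planted enrichment works through the 2x2 expectation: benign missense
positions are uniform over the protein, so their in-domain probability is
the domain's length fraction p0; pathogenic positions fall in the designated
domain with probability p1 solved from the target odds ratio theta via
odds(p1) = theta * odds(p0).  theta is thereby the single interpretable knob
and the expected table's odds ratio equals theta exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import VariantRecord, ConsequenceClass
from .concordance import ExpressionProfile
from .exceptions import InvalidConfigError
from .prioritize import FeatureMatrix
from .transcripts import TranscriptModel, aa_from_cds

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES
           if a + b + c not in _STOPS]

SOURCES = ("CDGC", "ClinVar", "DVD", "HGMD")
_FIVE_TIER_RAW = {"P": "Pathogenic", "LP": "Likely pathogenic",
                  "VUS": "Uncertain significance",
                  "LB": "Likely benign", "B": "Benign"}
_HGMD_RAW = {"P": "DM", "LP": "DM?"}


# --------------------------------------------------------------------------
# configs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic variant landscape.

    ``target_domain_or`` is the planted odds ratio theta of pathogenic
    missense enrichment in each gene's designated (DNA-binding-flagged)
    domain; ``spectrum_exponent`` is the power-law exponent of the discrete
    allele-count spectrum (larger -> more singletons);
    ``source_conflict_rate`` is the per-source probability of reporting a
    label outside the variant's true stratum.
    """

    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (1, 8)
    exon_length_range: tuple[int, int] = (90, 450)
    domains_per_gene: tuple[int, int] = (1, 3)
    n_pathogenic_missense: int = 60
    n_benign_missense: int = 240
    target_domain_or: float = 1.0
    source_conflict_rate: float = 0.0
    n_ptv_per_gene: int = 20
    spectrum_exponent: float = 2.5
    codon_aligned_exons: bool = True
    ptv_pathogenic_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_genes, self.n_pathogenic_missense,
                  self.n_benign_missense, self.n_ptv_per_gene)
        if min(counts) < 0:
            raise InvalidConfigError("all counts must be >= 0")
        if self.target_domain_or <= 0:
            raise InvalidConfigError("target_domain_or must be > 0")
        if not 0 <= self.source_conflict_rate <= 1:
            raise InvalidConfigError("source_conflict_rate must be in [0, 1]")
        if self.exons_per_gene[0] < 1:
            raise InvalidConfigError("exons_per_gene must be >= 1")
        if self.exon_length_range[0] < 3:
            raise InvalidConfigError("exon lengths must be >= 3 nt")
        if self.spectrum_exponent <= 1:
            raise InvalidConfigError("spectrum_exponent must be > 1")


@dataclass(frozen=True)
class FeatureSimConfig:
    """Knobs of the gene feature matrix for the prioritizer.

    ``effect_size`` is the class-mean shift (in within-class SD units) of
    the informative continuous features; ``informative_fraction`` the share
    of features per block that carry it; ``hidden_positive_fraction`` plants
    genes drawn from the positive distribution inside the negative label set
    (for recovery experiments).
    """

    n_positive: int = 200
    n_negative: int = 1800
    n_expression_features: int = 18
    n_correlation_features: int = 30
    n_binary_features: int = 12
    effect_size: float = 1.0
    informative_fraction: float = 0.3
    hidden_positive_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 2:
            raise InvalidConfigError("n_positive must be >= 2 (SMOTE needs neighbors)")
        if min(self.n_negative, self.n_expression_features,
               self.n_correlation_features, self.n_binary_features) < 0:
            raise InvalidConfigError("counts must be >= 0")
        if not 0 <= self.informative_fraction <= 1:
            raise InvalidConfigError("informative_fraction must be in [0, 1]")
        if not 0 <= self.hidden_positive_fraction <= 1:
            raise InvalidConfigError("hidden_positive_fraction must be in [0, 1]")

    @property
    def n_features(self) -> int:
        return (self.n_expression_features + self.n_correlation_features
                + self.n_binary_features)


@dataclass(frozen=True)
class DomainAnnotation:
    """One protein domain: inclusive 1-based aa interval."""

    gene: str
    name: str
    start_aa: int
    end_aa: int
    dna_binding: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.start_aa <= self.end_aa:
            raise InvalidConfigError(f"bad domain interval {self.start_aa}-{self.end_aa}")

    @property
    def length(self) -> int:
        return self.end_aa - self.start_aa + 1


# --------------------------------------------------------------------------
# transcripts
# --------------------------------------------------------------------------

_UTR5_LEN = 60
_UTR3_LEN = 90


def gen_transcript_models(config: SimulationConfig,
                          rng: Optional[np.random.Generator] = None
                          ) -> list[TranscriptModel]:
    """Random multi-exon transcripts, one per gene, each on its own contig.

    Coding exon lengths are multiples of 3 by default so protein length is
    CDS length / 3 exactly; short UTR stubs extend the terminal exons so the
    UTR consequence classes are reachable.  The CDS sequence starts with ATG
    and contains no stop codon.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo_e, hi_e = config.exons_per_gene
    lo_l, hi_l = config.exon_length_range
    transcripts = []
    for i in range(config.n_genes):
        gene = f"GENE{i + 1:03d}"
        n_exons = int(rng.integers(lo_e, hi_e + 1))
        lengths = rng.integers(lo_l, hi_l + 1, size=n_exons)
        if config.codon_aligned_exons:
            lengths = np.maximum(3, (lengths // 3) * 3)
        introns = rng.integers(200, 2001, size=max(0, n_exons - 1))
        strand = "+" if rng.random() < 0.5 else "-"

        start = 1000
        coding = []
        pos = start
        for j, length in enumerate(lengths):
            coding.append((pos, pos + int(length)))
            pos += int(length)
            if j < n_exons - 1:
                pos += int(introns[j])
        cds_start, cds_end = coding[0][0], coding[-1][1]
        exons = [list(seg) for seg in coding]
        # UTR stubs on the transcription-terminal exons
        if strand == "+":
            exons[0][0] -= _UTR5_LEN
            exons[-1][1] += _UTR3_LEN
        else:
            exons[0][0] -= _UTR3_LEN
            exons[-1][1] += _UTR5_LEN

        cds_len = int(lengths.sum())
        n_codons = cds_len // 3
        codons = ["ATG"] + [_CODONS[k] for k in
                            rng.integers(0, len(_CODONS), size=n_codons - 1)]
        seq = "".join(codons)[:cds_len]
        transcripts.append(TranscriptModel(
            gene=gene, transcript_id=f"TX{i + 1:03d}", chrom=f"sim{i + 1}",
            strand=strand, exons=tuple((int(s), int(e)) for s, e in exons),
            cds_start=int(cds_start), cds_end=int(cds_end), cds_sequence=seq))
    return transcripts


# --------------------------------------------------------------------------
# domains
# --------------------------------------------------------------------------

def gen_domain_annotations(transcripts: Sequence[TranscriptModel],
                           config: SimulationConfig,
                           rng: Optional[np.random.Generator] = None
                           ) -> list[DomainAnnotation]:
    """Non-overlapping random domains per gene; one flagged DNA-binding.

    The DNA-binding domain is the designated target of the planted
    enrichment in :func:`gen_variant_catalog`.  Domain lengths are 5-15% of
    the protein (at least 5 aa); placement is rejection-sampled.
    """
    if not transcripts:
        raise InvalidConfigError("transcripts must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    lo_d, hi_d = config.domains_per_gene
    annotations: list[DomainAnnotation] = []
    for t in transcripts:
        L = t.protein_length
        k = int(rng.integers(lo_d, hi_d + 1))
        if k == 0:
            continue
        min_len = 5
        if min_len > L:
            raise InvalidConfigError(f"protein of {t.gene} too short for a domain")
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < k and attempts < 200:
            attempts += 1
            length = max(min_len, int(round(L * rng.uniform(0.05, 0.15))))
            length = min(length, L)
            start = int(rng.integers(1, L - length + 2))
            end = start + length - 1
            if all(end < s or start > e for s, e in placed):
                placed.append((start, end))
        placed.sort()
        target = int(rng.integers(0, len(placed)))
        for j, (s, e) in enumerate(placed):
            annotations.append(DomainAnnotation(
                gene=t.gene, name=f"{t.gene}_D{j + 1}", start_aa=s, end_aa=e,
                dna_binding=(j == target)))
    return annotations


def solve_in_domain_probability(theta: float, domain_fraction: float) -> float:
    """p1 such that odds(p1) = theta * odds(p0) with p0 the domain fraction."""
    if not 0 < domain_fraction < 1:
        raise InvalidConfigError("domain fraction must be in (0, 1)")
    odds1 = theta * domain_fraction / (1.0 - domain_fraction)
    return odds1 / (1.0 + odds1)


# --------------------------------------------------------------------------
# variants
# --------------------------------------------------------------------------

_GNOMAD_AN = 300_000  # alleles in the reference population


def _power_law_ac(rng: np.random.Generator, exponent: float, cap: int) -> int:
    """Allele count from a discretized power law, capped.

    P(AC = k) proportional to k^-exponent; the cap keeps benign variants in
    the rare range without changing the singleton-dominated shape.
    """
    ac = int(rng.zipf(exponent))
    return min(ac, cap)


def _source_labels(rng: np.random.Generator, true_stratum: str,
                   conflict_rate: float, sources: Sequence[str]) -> dict:
    """Raw per-source labels: correct with prob 1 - conflict_rate."""
    strata = {"P/LP": ["P", "LP"], "B/LB": ["B", "LB"], "VUS": ["VUS"]}
    labels = {}
    for src in sources:
        if rng.random() < conflict_rate:
            others = [lab for key, labs in strata.items() if key != true_stratum
                      for lab in labs]
            norm = others[int(rng.integers(0, len(others)))]
        else:
            mine = strata[true_stratum]
            norm = mine[int(rng.integers(0, len(mine)))]
        if src == "HGMD":
            raw = _HGMD_RAW.get(norm)
            if raw is None:
                continue  # HGMD has no benign/VUS vocabulary
        else:
            raw = _FIVE_TIER_RAW[norm]
        labels[src] = raw
    return labels


def _missense_snv(t: TranscriptModel, aa: int,
                  rng: np.random.Generator) -> tuple[int, str, str, int]:
    """A single-base substitution at codon ``aa`` whose effect is missense.

    Returns (pos 1-based genomic, ref, alt, cds_pos) on the forward strand.
    """
    from Bio.Seq import Seq

    seq = t.cds_sequence
    assert seq is not None
    codon = seq[(aa - 1) * 3: aa * 3]
    old_aa = str(Seq(codon).translate())
    for within in map(int, rng.permutation(3)):
        for alt_base in map(str, rng.permutation(list(_BASES))):
            if alt_base == codon[within]:
                continue
            new_codon = codon[:within] + alt_base + codon[within + 1:]
            new_aa = str(Seq(new_codon).translate())
            if new_aa != old_aa and new_aa != "*":
                cds_pos = (aa - 1) * 3 + within + 1
                pos0 = t.cds_to_genomic(cds_pos)
                ref, alt = codon[within], alt_base
                if t.strand == "-":
                    ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
                return pos0 + 1, ref, alt, cds_pos
    raise InvalidConfigError(f"no missense substitution found at aa {aa}")  # pragma: no cover


def _frameshift_deletion(t: TranscriptModel,
                         rng: np.random.Generator) -> tuple[int, str, str, int]:
    """A 1-bp coding deletion (anchor + deleted base within one exon)."""
    segs = [(s, e) for s, e in t.coding_segments() if e - s >= 2]
    s, e = segs[int(rng.integers(0, len(segs)))]
    g = int(rng.integers(s + 1, e))        # deleted genomic base; g-1 is the anchor
    cds_anchor = t.genomic_to_cds(g - 1)
    cds_del = t.genomic_to_cds(g)
    assert cds_anchor is not None and cds_del is not None
    seq = t.cds_sequence
    assert seq is not None

    def fwd_base(pos0: int) -> str:
        c = t.genomic_to_cds(pos0)
        base = seq[c - 1]
        return base if t.strand == "+" else _COMPLEMENT[base]

    ref = fwd_base(g - 1) + fwd_base(g)
    alt = ref[0]
    return g, ref, alt, cds_del  # VCF pos = anchor (1-based) = (g-1)+1


def gen_variant_catalog(transcripts: Sequence[TranscriptModel],
                        domains: Sequence[DomainAnnotation],
                        config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> list[VariantRecord]:
    """Missense and PTV catalog with planted domain enrichment.

    Pathogenic missense positions land in the gene's DNA-binding domain with
    the probability implied by ``target_domain_or``; benign missense are
    uniform over the protein.  Allele counts follow the power-law spectrum;
    per-source raw labels are drawn around each variant's latent class.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    by_gene: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        by_gene.setdefault(d.gene, []).append(d)

    records: list[VariantRecord] = []
    for t in transcripts:
        L = t.protein_length
        gene_domains = by_gene.get(t.gene, [])
        target = next((d for d in gene_domains if d.dna_binding), None)
        if config.target_domain_or != 1.0 and target is None:
            raise InvalidConfigError(
                f"target_domain_or != 1 requires a designated domain ({t.gene})")
        inheritance = ["AD", "AR", "AD/AR"][int(rng.choice(3, p=[0.4, 0.5, 0.1]))]

        if target is not None and target.length < L:
            p0 = target.length / L
            p1 = solve_in_domain_probability(config.target_domain_or, p0)
            in_dom = list(range(max(2, target.start_aa), target.end_aa + 1))
            out_dom = [a for a in range(2, L + 1)
                       if not target.start_aa <= a <= target.end_aa]
        else:
            p1 = None
            in_dom, out_dom = [], list(range(2, L + 1))

        def _emit(aa: int, stratum: str, ac_cap: int, exponent: float,
                  label_sources: Sequence[str]) -> None:
            pos, ref, alt, cds_pos = _missense_snv(t, aa, rng)
            ac = _power_law_ac(rng, exponent, ac_cap)
            records.append(VariantRecord(
                gene=t.gene, transcript_id=t.transcript_id, chrom=t.chrom,
                pos=pos, ref=ref, alt=alt,
                consequence=ConsequenceClass.MISSENSE,
                cds_pos=cds_pos, aa_pos=aa,
                source_labels=_source_labels(rng, stratum,
                                             config.source_conflict_rate,
                                             label_sources),
                allele_count={"gnomad": ac},
                allele_frequency={"gnomad": ac / _GNOMAD_AN},
                inheritance=inheritance,
                extra={"true_class": stratum,
                       "in_designated_domain": bool(
                           target and target.start_aa <= aa <= target.end_aa)}))

        for _ in range(config.n_pathogenic_missense):
            if p1 is not None and in_dom and rng.random() < p1:
                aa = in_dom[int(rng.integers(0, len(in_dom)))]
            else:
                pool = out_dom if (p1 is not None and out_dom) else list(range(2, L + 1))
                aa = pool[int(rng.integers(0, len(pool)))]
            n_src = 2 + int(rng.integers(0, 2))
            srcs = [SOURCES[i] for i in rng.choice(len(SOURCES), size=n_src,
                                                   replace=False)]
            _emit(aa, "P/LP", ac_cap=8, exponent=3.0, label_sources=srcs)

        for _ in range(config.n_benign_missense):
            aa = int(rng.integers(2, L + 1))
            srcs = ["ClinVar"] if rng.random() < 0.5 else []
            _emit(aa, "B/LB", ac_cap=25, exponent=config.spectrum_exponent,
                  label_sources=srcs)

        for _ in range(config.n_ptv_per_gene):
            pos, ref, alt, cds_pos = _frameshift_deletion(t, rng)
            stratum = ("P/LP" if rng.random() < config.ptv_pathogenic_fraction
                       else "VUS")
            n_src = 1 + int(rng.integers(0, 2))
            srcs = [SOURCES[i] for i in rng.choice(len(SOURCES), size=n_src,
                                                   replace=False)]
            ac = _power_law_ac(rng, 3.0, 6)
            records.append(VariantRecord(
                gene=t.gene, transcript_id=t.transcript_id, chrom=t.chrom,
                pos=pos, ref=ref, alt=alt,
                consequence=ConsequenceClass.FRAMESHIFT,
                cds_pos=cds_pos, aa_pos=aa_from_cds(cds_pos),
                source_labels=_source_labels(rng, stratum,
                                             config.source_conflict_rate, srcs),
                allele_count={"gnomad": ac},
                allele_frequency={"gnomad": ac / _GNOMAD_AN},
                inheritance=inheritance,
                extra={"true_class": stratum, "in_designated_domain": False}))
    return records


# --------------------------------------------------------------------------
# feature matrix
# --------------------------------------------------------------------------

def gen_feature_matrix(config: FeatureSimConfig,
                       rng: Optional[np.random.Generator] = None) -> FeatureMatrix:
    """Labeled gene feature matrix with block structure and planted signal.

    Continuous informative features shift the positive-class mean by the
    effect size delta (unit within-class SD); correlation-block values are
    kept in [-1, 1]; informative binary features shift the Bernoulli rate on
    the log-odds scale by delta.  Hidden positives are negatives drawn from
    the positive distribution, listed on the returned matrix.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_pos, n_neg = config.n_positive, config.n_negative
    n = n_pos + n_neg
    genes = ([f"POS{i + 1:05d}" for i in range(n_pos)]
             + [f"NEG{i + 1:05d}" for i in range(n_neg)])
    n_hidden = int(round(config.hidden_positive_fraction * n_neg))
    hidden_idx = rng.choice(n_neg, size=n_hidden, replace=False) + n_pos
    is_pos_dist = np.zeros(n, dtype=bool)
    is_pos_dist[:n_pos] = True
    is_pos_dist[hidden_idx] = True
    delta = config.effect_size

    cols, data, blocks = [], [], {}

    def _informative(count: int) -> int:
        return int(round(config.informative_fraction * count))

    k = _informative(config.n_expression_features)
    for j in range(config.n_expression_features):
        name = f"expr_{j + 1:03d}"
        shift = delta if j < k else 0.0
        col = rng.normal(0.0, 1.0, size=n) + shift * is_pos_dist
        cols.append(name); data.append(col); blocks[name] = "expression"

    k = _informative(config.n_correlation_features)
    corr_shift = min(0.9, 0.25 * delta)
    for j in range(config.n_correlation_features):
        name = f"corr_{j + 1:03d}"
        shift = corr_shift if j < k else 0.0
        col = np.clip(rng.normal(0.0, 0.3, size=n) + shift * is_pos_dist, -1.0, 1.0)
        cols.append(name); data.append(col); blocks[name] = "correlation"

    k = _informative(config.n_binary_features)
    base_p = 0.15
    logit = math.log(base_p / (1 - base_p))
    shifted_p = 1.0 / (1.0 + math.exp(-(logit + delta)))
    for j in range(config.n_binary_features):
        name = f"go_{j + 1:03d}"
        p = np.where(is_pos_dist & (j < k), shifted_p, base_p)
        col = (rng.random(n) < p).astype(float)
        cols.append(name); data.append(col); blocks[name] = "binary"

    values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    labels = pd.Series(["positive"] * n_pos + ["negative"] * n_neg,
                       index=genes, name="label")
    hidden = [genes[i] for i in sorted(hidden_idx)]
    return FeatureMatrix(values=values, labels=labels, blocks=blocks,
                         hidden_positive_genes=hidden)


# --------------------------------------------------------------------------
# expression pairs
# --------------------------------------------------------------------------

def gen_expression_pair(n_genes: int, rho: float, seed: Optional[int] = None,
                        rng: Optional[np.random.Generator] = None,
                        species: tuple[str, str] = ("human", "mouse")
                        ) -> tuple[ExpressionProfile, ExpressionProfile]:
    """Two z-scored expression profiles with population correlation rho.

    Values are drawn from a standardized bivariate normal and z-scored per
    profile; rho = 1 gives identical profiles.
    """
    if not -1.0 <= rho <= 1.0:
        raise InvalidConfigError(f"rho must be in [-1, 1], got {rho}")
    if n_genes < 3:
        raise InvalidConfigError("n_genes must be >= 3")
    if rng is None:
        rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    xy = rng.multivariate_normal([0.0, 0.0], cov, size=n_genes, method="svd")
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]

    def _z(v: np.ndarray) -> pd.Series:
        return pd.Series((v - v.mean()) / v.std(ddof=0), index=genes)

    a = ExpressionProfile(species[0], _z(xy[:, 0]), scale="zscore")
    b = ExpressionProfile(species[1], _z(xy[:, 1]), scale="zscore")
    return a, b
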