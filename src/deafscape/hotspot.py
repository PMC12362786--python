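"""Pathogenic-missense hotspot detection and likelihood-ratio calibration.

For each gene, Gaussian kernel densities contrast the amino-acid positions
of pathogenic (P/LP) versus population (non-pathogenic) missense variants.
For each annotated protein domain, a 2x2 table of the two strata inside and
outside the domain yields the positive likelihood ratio

    LR+ = [plp_in / (plp_in + plp_out)] / [1 - nonp_out / (nonp_in + nonp_out)]

(i.e. sensitivity / (1 - specificity) for "in the domain" as a diagnostic
test of pathogenicity), the odds ratio

    OR = (plp_in * nonp_out) / (plp_out * nonp_in),

a one-sided Fisher exact p-value of enrichment, and a stratified bootstrap
95% CI for LR+.  The CI lower bound (LR+_LB) is mapped onto evidence
strengths: supporting > 2.08, moderate > 4.3, strong > 18.7, very strong
> 350 (strict inequalities; boundary values take the lower level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    InvalidConfigError,
    InvalidInputError,
    UndefinedStatisticError,
    UnstableEstimateError,
)


@dataclass(frozen=True)
class DomainEnrichmentCounts:
    """The four cells of the per-domain 2x2 table."""

    plp_in: int
    plp_out: int
    nonp_in: int
    nonp_out: int

    def __post_init__(self) -> None:
        if min(self.plp_in, self.plp_out, self.nonp_in, self.nonp_out) < 0:
            raise InvalidInputError("counts must be nonnegative")

    @property
    def n_plp(self) -> int:
        return self.plp_in + self.plp_out

    @property
    def n_nonp(self) -> int:
        return self.nonp_in + self.nonp_out


@dataclass(frozen=True)
class AcmgThresholds:
    """Evidence-strength thresholds on the LR+ CI lower bound."""

    supporting: float = 2.08
    moderate: float = 4.3
    strong: float = 18.7
    very_strong: float = 350.0

    def __post_init__(self) -> None:
        if not (self.supporting < self.moderate < self.strong < self.very_strong):
            raise InvalidConfigError("thresholds must be strictly increasing")


class EvidenceStrength(str, Enum):
    NONE = "none"
    SUPPORTING = "supporting"
    MODERATE = "moderate"
    STRONG = "strong"
    VERY_STRONG = "very_strong"


@dataclass
class KdeProfile:
    gene: str
    grid: np.ndarray
    density_pathogenic: Optional[np.ndarray]
    density_benign: Optional[np.ndarray]
    bandwidth_pathogenic: Optional[float]
    bandwidth_benign: Optional[float]
    n_pathogenic: int
    n_benign: int


@dataclass
class HotspotCall:
    gene: str
    region: tuple[int, int]
    domain_name: str
    is_dna_binding: bool
    counts: DomainEnrichmentCounts
    lr_plus: float
    lr_lb: float
    lr_ub: float
    or_value: float
    fisher_p: float
    adjusted_p: float
    significant: bool
    strength: EvidenceStrength


# --------------------------------------------------------------------------
# density profiles
# --------------------------------------------------------------------------

def _kde_on_grid(positions: np.ndarray, grid: np.ndarray) -> tuple[np.ndarray, float]:
    """Gaussian KDE evaluated on the grid, renormalized to trapezoid mass 1.

    Scott's rule sets the bandwidth; degenerate inputs (one point, or all
    points identical) fall back to a fixed kernel width of max(1 aa, 2% of
    the protein length).
    """
    L = float(grid[-1])
    if positions.std() > 0 and len(positions) > 1:
        kde = stats.gaussian_kde(positions, bw_method="scott")
        dens = kde(grid)
        bw = float(np.sqrt(kde.covariance[0, 0]))
    else:
        bw = max(1.0, 0.02 * L)
        dens = np.exp(-0.5 * ((grid[:, None] - positions[None, :]) / bw) ** 2).sum(axis=1)
        dens /= len(positions) * bw * np.sqrt(2 * np.pi)
    mass = np.trapezoid(dens, grid)
    if mass <= 0:
        raise UndefinedStatisticError("density mass is zero on the grid")
    return dens / mass, bw


def kde_profile(pathogenic_positions: Sequence[int],
                benign_positions: Sequence[int],
                protein_length: int,
                gene: str = "") -> KdeProfile:
    """Per-gene density profile of the two missense strata on 1..L.

    An empty stratum yields an absent density (the profile is still
    returned).  Each returned density integrates to 1 over the grid by the
    trapezoid rule.
    """
    if protein_length < 2:
        raise InvalidInputError("protein length must be >= 2")
    grid = np.arange(1, protein_length + 1, dtype=float)
    for pos in list(pathogenic_positions) + list(benign_positions):
        if not 1 <= pos <= protein_length:
            raise InvalidInputError(f"aa position {pos} outside [1, {protein_length}]")
    dens_p = bw_p = dens_b = bw_b = None
    if len(pathogenic_positions):
        dens_p, bw_p = _kde_on_grid(np.asarray(pathogenic_positions, float), grid)
    if len(benign_positions):
        dens_b, bw_b = _kde_on_grid(np.asarray(benign_positions, float), grid)
    return KdeProfile(gene=gene, grid=grid,
                      density_pathogenic=dens_p, density_benign=dens_b,
                      bandwidth_pathogenic=bw_p, bandwidth_benign=bw_b,
                      n_pathogenic=len(pathogenic_positions),
                      n_benign=len(benign_positions))


# --------------------------------------------------------------------------
# 2x2 statistics
# --------------------------------------------------------------------------

def tabulate_domain_counts(pathogenic_positions: Sequence[int],
                           benign_positions: Sequence[int],
                           region: tuple[int, int],
                           protein_length: Optional[int] = None) -> DomainEnrichmentCounts:
    """Partition both missense strata by membership in an inclusive aa interval."""
    start, end = region
    if start > end or start < 1:
        raise InvalidInputError(f"bad region {region}")
    if protein_length is not None and end > protein_length:
        raise InvalidInputError(f"region {region} outside protein of length {protein_length}")
    p_in = sum(1 for p in pathogenic_positions if start <= p <= end)
    b_in = sum(1 for p in benign_positions if start <= p <= end)
    return DomainEnrichmentCounts(
        plp_in=p_in, plp_out=len(pathogenic_positions) - p_in,
        nonp_in=b_in, nonp_out=len(benign_positions) - b_in)


def lr_plus(counts: DomainEnrichmentCounts) -> float:
    """Positive likelihood ratio of the 2x2 table.

    Haldane correction (0.5 added to every cell) when no non-pathogenic
    variant falls inside the domain, keeping the ratio finite.
    """
    if counts.n_plp == 0 or counts.n_nonp == 0:
        raise UndefinedStatisticError("a stratum is empty")
    a, b, c, d = counts.plp_in, counts.plp_out, counts.nonp_in, counts.nonp_out
    if c == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    sens = a / (a + b)
    one_minus_spec = 1.0 - d / (c + d)
    return sens / one_minus_spec


def odds_ratio(counts: DomainEnrichmentCounts) -> float:
    """Odds ratio of the 2x2 table, Haldane-corrected on any zero cell."""
    if counts.n_plp == 0 and counts.n_nonp == 0:
        raise UndefinedStatisticError("all-zero table")
    a, b, c, d = counts.plp_in, counts.plp_out, counts.nonp_in, counts.nonp_out
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_exact_p(counts: DomainEnrichmentCounts) -> float:
    """One-sided (enrichment-direction) Fisher exact p-value."""
    if counts.n_plp == 0 or counts.n_nonp == 0:
        raise UndefinedStatisticError("a stratum is empty")
    table = [[counts.plp_in, counts.plp_out], [counts.nonp_in, counts.nonp_out]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

def bootstrap_lr_ci(pathogenic_positions: Sequence[int],
                    benign_positions: Sequence[int],
                    region: tuple[int, int],
                    n_boot: int = 2000,
                    seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None,
                    max_drop_fraction: float = 0.5) -> tuple[float, float, float]:
    """Stratified percentile bootstrap of LR+ over a region.

    Variants are resampled with replacement within each stratum; each
    resample's LR+ is recomputed (with the same Haldane handling as the point
    estimate).  Returns (point, lower, upper) at the 2.5/97.5 percentiles.
    Degenerate resamples are dropped; if more than ``max_drop_fraction`` of
    resamples are dropped the estimate is declared unstable.
    """
    if n_boot < 200:
        raise InvalidConfigError("n_boot must be >= 200")
    if not len(pathogenic_positions) or not len(benign_positions):
        raise UndefinedStatisticError("both strata must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    start, end = region
    in_p = np.asarray([start <= p <= end for p in pathogenic_positions], dtype=float)
    in_b = np.asarray([start <= p <= end for p in benign_positions], dtype=float)
    n_p, n_b = len(in_p), len(in_b)

    point = lr_plus(tabulate_domain_counts(pathogenic_positions,
                                           benign_positions, region))

    k_p = in_p[rng.integers(0, n_p, size=(n_boot, n_p))].sum(axis=1)
    k_b = in_b[rng.integers(0, n_b, size=(n_boot, n_b))].sum(axis=1)

    sens = k_p / n_p
    frac_b = k_b / n_b
    lr = np.where(k_b > 0, sens / np.where(k_b > 0, frac_b, 1.0),
                  ((k_p + 0.5) / (n_p + 1.0)) / ((k_b + 0.5) / (n_b + 1.0)))
    valid = np.isfinite(lr)
    dropped = int(n_boot - valid.sum())
    if dropped > max_drop_fraction * n_boot:
        raise UnstableEstimateError(f"{dropped}/{n_boot} degenerate resamples")
    lo, hi = np.quantile(lr[valid], [0.025, 0.975])
    return float(point), float(lo), float(hi)


# --------------------------------------------------------------------------
# strength + gene scan
# --------------------------------------------------------------------------

def acmg_strength(lr_lb: float,
                  thresholds: AcmgThresholds = AcmgThresholds()) -> EvidenceStrength:
    """Largest strictly-exceeded threshold determines the evidence level."""
    if lr_lb > thresholds.very_strong:
        return EvidenceStrength.VERY_STRONG
    if lr_lb > thresholds.strong:
        return EvidenceStrength.STRONG
    if lr_lb > thresholds.moderate:
        return EvidenceStrength.MODERATE
    if lr_lb > thresholds.supporting:
        return EvidenceStrength.SUPPORTING
    return EvidenceStrength.NONE


@dataclass(frozen=True)
class HotspotScanConfig:
    alpha: float = 0.05
    n_boot: int = 2000
    correction: str = "bonferroni"  # or "fdr_bh"
    thresholds: AcmgThresholds = field(default_factory=AcmgThresholds)


def scan_gene(pathogenic_positions: Sequence[int],
              benign_positions: Sequence[int],
              domains: Sequence,   # objects with name, start_aa, end_aa, dna_binding
              protein_length: int,
              gene: str = "",
              config: HotspotScanConfig = HotspotScanConfig(),
              seed: Optional[int] = None,
              rng: Optional[np.random.Generator] = None) -> list[HotspotCall]:
    """One hotspot call per annotated domain, sorted by LR+_LB descending.

    Significance is a Fisher exact test per domain with a multiple-testing
    correction across the gene's domains (Bonferroni by default).
    """
    if not domains:
        return []
    if rng is None:
        rng = np.random.default_rng(seed)
    from statsmodels.stats.multitest import multipletests

    calls = []
    for dom in domains:
        region = (int(dom.start_aa), int(dom.end_aa))
        counts = tabulate_domain_counts(pathogenic_positions, benign_positions,
                                        region, protein_length)
        point, lo, hi = bootstrap_lr_ci(pathogenic_positions, benign_positions,
                                        region, n_boot=config.n_boot, rng=rng)
        calls.append(HotspotCall(
            gene=gene, region=region, domain_name=dom.name,
            is_dna_binding=bool(dom.dna_binding),
            counts=counts, lr_plus=point, lr_lb=lo, lr_ub=hi,
            or_value=odds_ratio(counts), fisher_p=fisher_exact_p(counts),
            adjusted_p=np.nan, significant=False,
            strength=acmg_strength(lo, config.thresholds)))

    pvals = [c.fisher_p for c in calls]
    method = "bonferroni" if config.correction == "bonferroni" else "fdr_bh"
    reject, adj, _, _ = multipletests(pvals, alpha=config.alpha, method=method)
    for call, r, p in zip(calls, reject, adj):
        call.adjusted_p = float(p)
        call.significant = bool(r)
    calls.sort(key=lambda c: c.lr_lb, reverse=True)
    return calls
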