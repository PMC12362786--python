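"""Cross-species expression standardization and concordance metrics.

Expression profiles (mean TPM-like values per gene) are log2(x+1)-transformed
or z-scored; concordance between two species is the Pearson correlation over
shared orthologs (optionally also over a designated gene subset), plus a
per-gene relative difference of z-scores:

    (|z_a| - |z_b|) / max(|z_a|, |z_b|)   in [-1, 1],

defined as 0 (and flagged) when both z-scores are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, InvalidInputError, ZeroVarianceError


@dataclass
class ExpressionProfile:
    """Per-gene expression for one species on a declared scale."""

    species: str
    values: pd.Series  # index: gene symbols
    scale: str = "raw"  # raw | log2 | zscore

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2", "zscore"):
            raise InvalidInputError(f"unknown scale {self.scale!r}")
        if self.scale == "raw" and (self.values < 0).any():
            raise InvalidInputError("raw expression values must be >= 0")


@dataclass
class SpeciesComparison:
    species_a: str
    species_b: str
    shared_genes: list
    r_all: float
    r_subset: Optional[float]
    relative_difference: pd.Series
    both_zero_genes: list = field(default_factory=list)


def normalize_expression(profile: ExpressionProfile, scale: str) -> ExpressionProfile:
    """Transform a raw profile to log2(x+1) or per-gene z-scores."""
    if scale == profile.scale:
        return profile
    if profile.scale != "raw":
        raise InvalidInputError("can only normalize from the raw scale")
    if scale == "log2":
        vals = np.log2(profile.values + 1.0)
    elif scale == "zscore":
        sd = profile.values.std(ddof=0)
        if sd == 0:
            raise ZeroVarianceError(f"profile {profile.species} has zero variance")
        vals = (profile.values - profile.values.mean()) / sd
    else:
        raise InvalidInputError(f"unknown scale {scale!r}")
    return ExpressionProfile(profile.species, vals, scale)


def relative_difference(z_a, z_b):
    """(|z_a| - |z_b|) / max(|z_a|, |z_b|); 0 where both are zero.

    Accepts scalars or arrays; antisymmetric under swapping a and b.
    """
    a = np.abs(np.asarray(z_a, dtype=float))
    b = np.abs(np.asarray(z_b, dtype=float))
    m = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(m > 0, (a - b) / np.where(m > 0, m, 1.0), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def species_correlation(profile_a: ExpressionProfile,
                        profile_b: ExpressionProfile,
                        subset: Optional[Sequence[str]] = None,
                        ortholog_map: Optional[Mapping[str, str]] = None
                        ) -> SpeciesComparison:
    """Pearson concordance between two species over shared (ortholog) genes.

    ``ortholog_map`` maps species-a gene symbols onto species-b symbols; by
    default genes match by identical symbol.  Both profiles must be on the
    same scale.  The per-gene relative difference is computed on z-scores of
    the shared genes (z-scoring within the shared set).
    """
    if profile_a.scale != profile_b.scale:
        raise InvalidInputError("profiles must be on the same scale")
    if ortholog_map is None:
        ortholog_map = {g: g for g in profile_a.values.index}
    shared = [g for g in profile_a.values.index
              if g in ortholog_map and ortholog_map[g] in profile_b.values.index]
    if len(shared) < 3:
        raise InsufficientDataError(f"only {len(shared)} shared genes")
    a = profile_a.values.loc[shared].to_numpy(dtype=float)
    b = profile_b.values.loc[[ortholog_map[g] for g in shared]].to_numpy(dtype=float)
    r_all = float(stats.pearsonr(a, b)[0])

    r_subset = None
    if subset is not None:
        keep = [i for i, g in enumerate(shared) if g in set(subset)]
        if len(keep) < 3:
            raise InsufficientDataError(f"only {len(keep)} shared subset genes")
        r_subset = float(stats.pearsonr(a[keep], b[keep])[0])

    def _z(x: np.ndarray) -> np.ndarray:
        sd = x.std(ddof=0)
        if sd == 0:
            raise ZeroVarianceError("zero variance over shared genes")
        return (x - x.mean()) / sd

    za, zb = _z(a), _z(b)
    rel = relative_difference(za, zb)
    both_zero = [g for g, x, y in zip(shared, za, zb) if x == 0 and y == 0]
    return SpeciesComparison(
        species_a=profile_a.species, species_b=profile_b.species,
        shared_genes=shared, r_all=r_all, r_subset=r_subset,
        relative_difference=pd.Series(rel, index=shared, name="relative_difference"),
        both_zero_genes=both_zero)
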