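"""Encoding-quality diagnostics.

Two complementary views of what an encoding does to the feature space:

* ``topk_abs_correlation`` measures *flexibility*: the mean absolute
  Pearson correlation to the trait of the k markers most correlated with
  it.  Trait-aware encodings raise this by aligning each marker's values
  with the trait.
* ``within_group_distance`` measures *order preservation*: samples are
  binned by their discretized trait z-score (-1/0/+1) and the mean
  pairwise Euclidean distance between same-bin samples is computed in
  marker-z-score space.  Encodings that scramble category order scatter
  samples with similar traits, inflating this distance; per-marker
  standardization makes the number comparable across encodings despite
  their different scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .core import TraitVector, ValidationError


@dataclass(frozen=True)
class DiscretizationParams:
    """Trait mean and population standard deviation used for binning."""

    mu: float
    delta: float

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValidationError("trait standard deviation must be positive")


def trait_discretization_params(y: TraitVector) -> DiscretizationParams:
    v = y.values
    return DiscretizationParams(float(v.mean()), float(v.std()))


def _check_aligned_matrix(Xenc: np.ndarray, y: TraitVector) -> np.ndarray:
    Xenc = np.asarray(Xenc, dtype=np.float64)
    if Xenc.ndim != 2 or Xenc.shape[0] != y.n_samples:
        raise ValidationError("encoded matrix rows must match trait samples")
    return Xenc


def topk_abs_correlation(Xenc: np.ndarray, y: TraitVector, k: int = 100) -> float:
    """Mean |Pearson r| of the k markers most correlated with the trait.

    Markers are ranked by absolute correlation (ties broken by column
    order); zero-variance columns count as correlation 0.
    """
    Xenc = _check_aligned_matrix(Xenc, y)
    m = Xenc.shape[1]
    if not 1 <= k <= m:
        raise ValidationError(f"k={k} outside [1, {m}]")
    yc = y.values - y.values.mean()
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        raise ValidationError("trait is constant; correlations are undefined")
    Xc = Xenc - Xenc.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    a = np.abs(r)
    top = np.argsort(-a, kind="stable")[:k]
    return float(a[top].mean())


def discretize_trait(y: TraitVector) -> np.ndarray:
    """Trait bins in {-1, 0, 1} by population z-score thresholds at +/-1."""
    p = trait_discretization_params(y)
    z = (y.values - p.mu) / p.delta
    return np.where(z < -1, -1, np.where(z > 1, 1, 0)).astype(np.int8)


def standardize_markers(Xenc: np.ndarray) -> np.ndarray:
    """Column z-scores with population variance; constant columns -> 0."""
    Xenc = np.asarray(Xenc, dtype=np.float64)
    mu = Xenc.mean(axis=0)
    sd = Xenc.std(axis=0)
    out = np.zeros_like(Xenc)
    nz = sd > 0
    out[:, nz] = (Xenc[:, nz] - mu[nz]) / sd[nz]
    return out


def within_group_distance(Xenc: np.ndarray, y: TraitVector) -> float:
    """Mean pairwise distance between samples sharing a discretized trait bin.

    Distances are Euclidean in per-marker z-score space; pairs are pooled
    across the three bins before averaging.  Invariant to any per-marker
    affine rescaling of the encoded matrix.
    """
    Xenc = _check_aligned_matrix(Xenc, y)
    Z = standardize_markers(Xenc)
    bins = discretize_trait(y)
    dists: list[np.ndarray] = []
    for b in (-1, 0, 1):
        rows = np.flatnonzero(bins == b)
        if rows.size >= 2:
            dists.append(pdist(Z[rows]))
    if not dists:
        raise ValidationError("no discretized trait group has >= 2 samples")
    return float(np.concatenate(dists).mean())
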