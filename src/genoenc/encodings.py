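"""Single-marker genotype encoding schemes.

Trait prediction by linear regression needs a numeric value per genotype
category.  Five schemes are provided:

``ordinal``
    The fixed labels {0,1,2} (or {-1,0,1}), identical for every marker.
``ordinal_flipped``
    Ordinal, but markers negatively correlated with the training trait get
    their 0 and 2 labels swapped so every feature correlates positively.
``target``
    Each category encoded as the mean training trait of the samples in
    that category at that marker (classic target encoding).
``hybrid_one``
    Homozygote categories target-encoded; the heterozygote encoded as the
    overall training-trait mean, which keeps the category order whenever
    the heterozygote group mean lies between the homozygote means.
``hybrid_two``
    Homozygote categories target-encoded; the heterozygote encoded as the
    midpoint of the two homozygote encodings, which keeps the category
    order by construction.

All trait-aware fits use training data only; applying a fitted model to
new samples is a pure table lookup, so no test-fold information can leak
through the features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import MISSING, GenotypeMatrix, TraitVector, ValidationError

ENCODING_METHODS = ("ordinal", "ordinal_flipped", "target", "hybrid_one", "hybrid_two")

OrdinalBase = Literal["zero_one_two", "minus_one_zero_one"]

_BASES: dict[str, tuple[float, float, float]] = {
    "zero_one_two": (0.0, 1.0, 2.0),
    "minus_one_zero_one": (-1.0, 0.0, 1.0),
}


class TransformError(ValueError):
    """Genotype data incompatible with a fitted encoding model."""


@dataclass(frozen=True)
class MarkerEncodingModel:
    """Fitted per-marker map from genotype category to a real value.

    ``table[j]`` holds the encoded values ``(E(j,0), E(j,1), E(j,2))`` for
    marker ``j``; ``impute[j]`` is the mean encoded value over the training
    rows, used for missing genotypes at transform time; ``train_mean`` is
    the overall training-trait mean (the fallback for categories unseen in
    training; ``nan`` for trait-free ordinal fits).
    """

    method: str
    marker_ids: tuple[str, ...]
    table: np.ndarray  # (m, 3) float64
    impute: np.ndarray  # (m,) float64
    train_mean: float

    def __post_init__(self) -> None:
        if self.method not in ENCODING_METHODS:
            raise ValidationError(f"unknown encoding method {self.method!r}")
        t = np.asarray(self.table, dtype=np.float64)
        im = np.asarray(self.impute, dtype=np.float64)
        if t.shape != (len(self.marker_ids), 3) or im.shape != (len(self.marker_ids),):
            raise ValidationError("encoding table/impute shape mismatch")
        t.setflags(write=False)
        im.setflags(write=False)
        object.__setattr__(self, "table", t)
        object.__setattr__(self, "impute", im)
        object.__setattr__(self, "marker_ids", tuple(self.marker_ids))


def _require_oriented(G: GenotypeMatrix) -> None:
    if not G.oriented:
        raise ValidationError(
            "genotype matrix must be oriented (orient_major_allele) before "
            "fitting or applying an encoding"
        )


def _require_aligned(G: GenotypeMatrix, y: TraitVector) -> None:
    if G.sample_ids != y.sample_ids:
        raise ValidationError(
            "genotypes and traits are not aligned; call validate_aligned first"
        )


def _impute_values(table: np.ndarray, G: GenotypeMatrix) -> np.ndarray:
    """Per-marker mean encoded value over the (training) rows of G."""
    v = G.values
    obs = v != MISSING
    enc = np.take_along_axis(table.T, np.where(obs, v, 0), axis=0)
    counts = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(obs, enc, 0.0).sum(axis=0) / counts
    # a fully-missing training column has no encoded mean; use the middle cat
    return np.where(counts > 0, means, table[:, 1])


def _group_stats(G: GenotypeMatrix, y: TraitVector) -> tuple[np.ndarray, np.ndarray]:
    """Training trait sums and counts per (marker, category)."""
    v = G.values
    sums = np.empty((G.n_markers, 3))
    counts = np.empty((G.n_markers, 3), dtype=np.int64)
    for g in (0, 1, 2):
        mask = v == g
        counts[:, g] = mask.sum(axis=0)
        sums[:, g] = mask.T @ y.values
    return sums, counts


def _homozygote_means(
    sums: np.ndarray, counts: np.ndarray, fallback: float
) -> tuple[np.ndarray, np.ndarray]:
    """Target means for categories 0 and 2, fallback where unobserved."""
    out = []
    n_fallback = 0
    for g in (0, 2):
        with np.errstate(invalid="ignore"):
            m = sums[:, g] / counts[:, g]
        absent = counts[:, g] == 0
        n_fallback += int(absent.sum())
        out.append(np.where(absent, fallback, m))
    if n_fallback:
        warnings.warn(
            f"{n_fallback} absent homozygote categor(ies) encoded with the "
            "overall training-trait mean",
            stacklevel=3,
        )
    return out[0], out[1]


def fit_ordinal(
    G: GenotypeMatrix, base: OrdinalBase = "zero_one_two"
) -> MarkerEncodingModel:
    """Fixed-label encoding, identical across markers; no trait needed."""
    _require_oriented(G)
    if base not in _BASES:
        raise ValidationError(f"unknown ordinal base {base!r}")
    table = np.tile(np.asarray(_BASES[base]), (G.n_markers, 1))
    return MarkerEncodingModel(
        "ordinal", G.marker_ids, table, _impute_values(table, G), float("nan")
    )


def marker_trait_correlations(G: GenotypeMatrix, y: TraitVector) -> np.ndarray:
    """Pearson correlation of each marker's category value with the trait.

    Missing calls are excluded pairwise; a zero-variance side gives 0.
    """
    _require_aligned(G, y)
    v = G.values
    obs = v != MISSING
    x = np.where(obs, v, 0).astype(np.float64)
    yv = y.values
    n = obs.sum(axis=0).astype(np.float64)
    sx = x.sum(axis=0)
    sy = obs.T @ yv
    sxx = (x * x).sum(axis=0)
    syy = obs.T @ (yv * yv)
    sxy = x.T @ yv
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r = cov / np.sqrt(vx * vy)
    r[~np.isfinite(r)] = 0.0
    r[n < 2] = 0.0
    return r


def fit_ordinal_flipped(G: GenotypeMatrix, y: TraitVector) -> MarkerEncodingModel:
    """Ordinal {0,1,2}, with 0/2 swapped at negatively correlated markers."""
    _require_oriented(G)
    _require_aligned(G, y)
    table = np.tile(np.asarray(_BASES["zero_one_two"]), (G.n_markers, 1))
    flip = marker_trait_correlations(G, y) < 0.0
    table[flip] = table[flip][:, ::-1]
    return MarkerEncodingModel(
        "ordinal_flipped", G.marker_ids, table, _impute_values(table, G),
        float(np.mean(y.values)),
    )


def fit_target_based(G: GenotypeMatrix, y: TraitVector) -> MarkerEncodingModel:
    """Each category encoded as its training-trait group mean."""
    _require_oriented(G)
    _require_aligned(G, y)
    overall = float(np.mean(y.values))
    sums, counts = _group_stats(G, y)
    with np.errstate(invalid="ignore"):
        table = sums / counts
    n_absent = int((counts == 0).sum())
    if n_absent:
        warnings.warn(
            f"{n_absent} absent categor(ies) encoded with the overall "
            "training-trait mean",
            stacklevel=2,
        )
    table = np.where(counts == 0, overall, table)
    return MarkerEncodingModel(
        "target", G.marker_ids, table, _impute_values(table, G), overall
    )


def _per_marker_overall_mean(G: GenotypeMatrix, y: TraitVector, overall: float) -> np.ndarray:
    """Mean trait over samples with an observed call at each marker."""
    obs = G.values != MISSING
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        m = (obs.T @ y.values) / n
    return np.where(n > 0, m, overall)


def fit_hybrid_one(G: GenotypeMatrix, y: TraitVector) -> MarkerEncodingModel:
    """Target-encoded homozygotes; heterozygote = overall training mean."""
    _require_oriented(G)
    _require_aligned(G, y)
    overall = float(np.mean(y.values))
    sums, counts = _group_stats(G, y)
    e0, e2 = _homozygote_means(sums, counts, overall)
    e1 = _per_marker_overall_mean(G, y, overall)
    table = np.column_stack([e0, e1, e2])
    return MarkerEncodingModel(
        "hybrid_one", G.marker_ids, table, _impute_values(table, G), overall
    )


def fit_hybrid_two(G: GenotypeMatrix, y: TraitVector) -> MarkerEncodingModel:
    """Target-encoded homozygotes; heterozygote = their midpoint, exactly."""
    _require_oriented(G)
    _require_aligned(G, y)
    overall = float(np.mean(y.values))
    sums, counts = _group_stats(G, y)
    e0, e2 = _homozygote_means(sums, counts, overall)
    table = np.column_stack([e0, (e0 + e2) / 2.0, e2])
    return MarkerEncodingModel(
        "hybrid_two", G.marker_ids, table, _impute_values(table, G), overall
    )


def fit_encoding(
    method: str,
    G: GenotypeMatrix,
    y: TraitVector | None = None,
    base: OrdinalBase = "zero_one_two",
) -> MarkerEncodingModel:
    """Dispatch to the fit function for ``method``."""
    if method == "ordinal":
        return fit_ordinal(G, base)
    if y is None:
        raise ValidationError(f"encoding {method!r} needs a training trait vector")
    fits = {
        "ordinal_flipped": fit_ordinal_flipped,
        "target": fit_target_based,
        "hybrid_one": fit_hybrid_one,
        "hybrid_two": fit_hybrid_two,
    }
    try:
        return fits[method](G, y)
    except KeyError:
        raise ValidationError(f"unknown encoding method {method!r}") from None


def transform(model: MarkerEncodingModel, G: GenotypeMatrix) -> np.ndarray:
    """Apply a fitted encoding: category -> real value, per marker.

    Missing genotypes are imputed with the marker's mean encoded value over
    the fit-time training rows.  Output columns follow ``G``'s marker
    order; every marker of ``G`` must be present in the model.
    """
    _require_oriented(G)
    idx = {m: j for j, m in enumerate(model.marker_ids)}
    try:
        cols = np.asarray([idx[m] for m in G.marker_ids])
    except KeyError as exc:
        raise TransformError(f"marker {exc.args[0]!r} absent from encoding model")
    table = model.table[cols]
    impute = model.impute[cols]
    v = G.values
    obs = v != MISSING
    out = np.take_along_axis(table.T, np.where(obs, v, 0), axis=0).astype(np.float64)
    return np.where(obs, out, impute[np.newaxis, :])
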