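"""Leakage-safe k-fold cross-validation of encoding/predictor combinations.

Every fold re-decides allele orientation, re-fits the encoding (and any
pair grids) and re-fits the predictor on its training rows alone; the test
rows are transformed with the frozen fold objects and contribute only the
final squared correlation.  Folds are deterministic in the seed, and a
comparison across encodings reuses one fold assignment so that method
differences are not fold noise.

The reported accuracy is the mean of per-fold r-squared values (squared
Pearson correlation of predictions and observations), the standard metric
in genomic prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import GenotypeMatrix, TraitVector, ValidationError, orient_major_allele
from .encodings import fit_encoding, transform
from .epistasis import (
    PairSelection,
    fit_pair_grid_hybrid_one,
    fit_pair_grid_hybrid_two,
    product_features,
    select_pairs,
    transform_pairs,
)
from .predict import SVRConfig, fit_rrblup, fit_svr
from .predict import predict as rrblup_predict

PREDICTORS = ("rrblup", "svr")


class MetricError(ValueError):
    """Requested metric is undefined for the given vectors."""


def pearson_r2(pred: np.ndarray, obs: np.ndarray) -> float:
    """Squared Pearson correlation; 0.0 when predictions are constant."""
    pred = np.asarray(pred, dtype=np.float64)
    obs = np.asarray(obs, dtype=np.float64)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size < 2:
        raise MetricError("pred and obs must be equal-length vectors of size >= 2")
    if np.ptp(obs) == 0:
        raise MetricError("observed values are constant; r^2 is undefined")
    if np.ptp(pred) == 0:
        return 0.0
    r = np.corrcoef(pred, obs)[0, 1]
    return float(r * r)


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Fold label per sample: seeded shuffle, then contiguous blocks.

    Fold sizes differ by at most one; identical ``(n, k, seed)`` always
    yields the identical assignment.
    """
    if not 2 <= k <= n:
        raise ValidationError(f"fold count k={k} outside [2, {n}]")
    perm = np.random.default_rng(seed).permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    labels = np.empty(n, dtype=np.int64)
    start = 0
    for f, size in enumerate(sizes):
        labels[perm[start : start + size]] = f
        start += size
    return labels


@dataclass(frozen=True)
class EpistasisOptions:
    """Pair-feature settings for the epistasis design matrix.

    ``feature`` chooses product columns or one of the fitted 3x3 grids;
    selection happens per training fold unless an explicit pair list is
    given.
    """

    feature: str = "product"  # product | grid_hybrid_one | grid_hybrid_two
    selection: PairSelection = field(default_factory=PairSelection)

    def __post_init__(self) -> None:
        if self.feature not in ("product", "grid_hybrid_one", "grid_hybrid_two"):
            raise ValidationError(f"unknown epistasis feature {self.feature!r}")


@dataclass(frozen=True)
class CVReport:
    """Cross-validation result for one encoding/predictor combination."""

    encoding: str
    predictor: str
    k: int
    seed: int
    fold_assignment: np.ndarray
    fold_r2: tuple[float, ...]  # nan marks a fold whose test trait was constant
    predictions: np.ndarray  # out-of-fold prediction per sample, input order

    @property
    def mean_r2(self) -> float:
        vals = np.asarray(self.fold_r2)
        return float(np.nanmean(vals))


def _fold_pipeline(
    G: GenotypeMatrix,
    y: TraitVector,
    train: np.ndarray,
    test: np.ndarray,
    encoding: str,
    predictor: str,
    epistasis: EpistasisOptions | None,
    svr_config: SVRConfig | None,
    ordinal_base: str,
) -> np.ndarray:
    """Fit everything on the training rows, return test predictions."""
    Gor = orient_major_allele(G, reference_rows=train)
    Gtr, Gte = Gor.take_samples(train), Gor.take_samples(test)
    ytr = y.take(train)
    model = fit_encoding(encoding, Gtr, ytr, base=ordinal_base)
    Xtr = transform(model, Gtr)
    Xte = transform(model, Gte)
    if epistasis is not None:
        pairs = select_pairs(Xtr, ytr, epistasis.selection, Gor.marker_ids)
        if epistasis.feature == "product":
            Ptr = product_features(Xtr, pairs, Gor.marker_ids)
            Pte = product_features(Xte, pairs, Gor.marker_ids)
        else:
            fit_grid = (
                fit_pair_grid_hybrid_one
                if epistasis.feature == "grid_hybrid_one"
                else fit_pair_grid_hybrid_two
            )
            grid = fit_grid(Gtr, ytr, pairs)
            Ptr = transform_pairs(grid, Gtr)
            Pte = transform_pairs(grid, Gte)
        Xtr = np.hstack([Xtr, Ptr])
        Xte = np.hstack([Xte, Pte])
    if predictor == "rrblup":
        fitted = fit_rrblup(Xtr, ytr.values)
        return rrblup_predict(fitted, Xte)
    if predictor == "svr":
        return fit_svr(Xtr, ytr.values, svr_config).predict(Xte)
    raise ValidationError(f"unknown predictor {predictor!r}")


def cross_validate(
    G: GenotypeMatrix,
    y: TraitVector,
    encoding: str = "hybrid_two",
    predictor: str = "rrblup",
    k: int = 10,
    seed: int = 0,
    folds: np.ndarray | None = None,
    epistasis: EpistasisOptions | None = None,
    svr_config: SVRConfig | None = None,
    ordinal_base: str = "zero_one_two",
) -> CVReport:
    """k-fold CV of one encoding/predictor combination.

    ``folds`` may be supplied to share an assignment across methods;
    otherwise :func:`make_folds` derives one from ``(n, k, seed)``.
    A fold whose test trait is constant gets ``nan`` (excluded from the
    mean) with a warning.
    """
    if G.sample_ids != y.sample_ids:
        raise ValidationError("inputs must be aligned; call validate_aligned first")
    n = G.n_samples
    if folds is None:
        folds = make_folds(n, k, seed)
    else:
        folds = np.asarray(folds)
        if folds.shape != (n,):
            raise ValidationError("fold assignment length mismatch")
        k = int(folds.max()) + 1
    fold_r2: list[float] = []
    preds = np.full(n, np.nan)
    for f in range(k):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        p = _fold_pipeline(
            G, y, train, test, encoding, predictor, epistasis, svr_config,
            ordinal_base,
        )
        preds[test] = p
        obs = y.values[test]
        if np.ptp(obs) == 0:
            warnings.warn(
                f"fold {f}: constant test trait; r^2 recorded as missing",
                stacklevel=2,
            )
            fold_r2.append(float("nan"))
        else:
            fold_r2.append(pearson_r2(p, obs))
    return CVReport(
        encoding, predictor, k, seed, folds, tuple(fold_r2), preds
    )


def compare_encodings(
    G: GenotypeMatrix,
    y: TraitVector,
    encodings: Sequence[str],
    predictor: str = "rrblup",
    k: int = 10,
    seed: int = 0,
    epistasis: EpistasisOptions | None = None,
    svr_config: SVRConfig | None = None,
) -> dict[str, CVReport]:
    """Cross-validate several encodings on one shared fold assignment."""
    folds = make_folds(G.n_samples, k, seed)
    return {
        enc: cross_validate(
            G, y, enc, predictor, k=k, seed=seed, folds=folds,
            epistasis=epistasis, svr_config=svr_config,
        )
        for enc in encodings
    }
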