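"""Pairwise marker-interaction features.

Two routes are supported.  The traditional one multiplies the encoded
values of the two markers, adding one product column per pair to the
design matrix.  The grid route instead fits, per pair, a 3x3 table of
real values indexed by the two genotype categories: corner cells (both
markers homozygous) are target-encoded from the training trait, and the
heterozygote-involving cells are filled either from pooled marginal means
(hybrid one) or by averaging adjacent fitted cells (hybrid two).

The design matrix for an epistasis model is the single-marker encoded
matrix augmented with the pair columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np

from .core import MISSING, GenotypeMatrix, TraitVector, ValidationError
from .encodings import TransformError, _require_aligned, _require_oriented

Pair = tuple[str, str]

PairStrategy = Literal["all_pairs", "explicit_list", "top_t_by_correlation"]

#: ``all_pairs`` is refused above this many markers (quadratic blow-up).
DEFAULT_ALL_PAIRS_CAP = 200

#: Default number of screened markers for ``top_t_by_correlation``.
DEFAULT_TOP_T = 50


@dataclass(frozen=True)
class PairSelection:
    """How to choose the marker pairs that get interaction features."""

    strategy: PairStrategy = "top_t_by_correlation"
    t: int = DEFAULT_TOP_T
    pairs: tuple[Pair, ...] | None = None
    all_pairs_cap: int = DEFAULT_ALL_PAIRS_CAP


@dataclass(frozen=True)
class PairGridEncodingModel:
    """Fitted 3x3 encoding grid per marker pair.

    ``grids[p, a, b]`` is the encoded value for category ``a`` at the
    pair's first marker and ``b`` at its second.  ``fallback[p]`` (the
    overall training-trait mean) fills empty training cells and stands in
    for missing genotypes at transform time.
    """

    method: str
    pairs: tuple[Pair, ...]
    grids: np.ndarray  # (P, 3, 3) float64
    fallback: np.ndarray  # (P,) float64

    def __post_init__(self) -> None:
        if self.method not in ("hybrid_one", "hybrid_two"):
            raise ValidationError(f"unknown pair-grid method {self.method!r}")
        g = np.asarray(self.grids, dtype=np.float64)
        f = np.asarray(self.fallback, dtype=np.float64)
        if g.shape != (len(self.pairs), 3, 3) or f.shape != (len(self.pairs),):
            raise ValidationError("pair grid shape mismatch")
        g.setflags(write=False)
        f.setflags(write=False)
        object.__setattr__(self, "grids", g)
        object.__setattr__(self, "fallback", f)
        object.__setattr__(self, "pairs", tuple((str(a), str(b)) for a, b in self.pairs))


def _canonical_pairs(
    pairs: Sequence[Pair], marker_ids: Sequence[str]
) -> tuple[Pair, ...]:
    """Validate, orient (first marker earlier in marker order), deduplicate."""
    order = {m: j for j, m in enumerate(marker_ids)}
    seen: set[Pair] = set()
    out: list[Pair] = []
    for a, b in pairs:
        if a not in order or b not in order:
            missing = a if a not in order else b
            raise ValidationError(f"pair references unknown marker {missing!r}")
        if a == b:
            raise ValidationError(f"self-pair ({a!r}, {a!r}) is not allowed")
        p = (a, b) if order[a] < order[b] else (b, a)
        if p not in seen:
            seen.add(p)
            out.append(p)
    return tuple(out)


def select_pairs(
    Xenc: np.ndarray,
    y: TraitVector,
    sel: PairSelection,
    marker_ids: Sequence[str],
) -> tuple[Pair, ...]:
    """Choose marker pairs on training data only.

    ``top_t_by_correlation`` ranks markers by the absolute Pearson
    correlation of their encoded column with the trait (ties broken by
    marker order) and forms all pairs among the top ``t``.
    """
    Xenc = np.asarray(Xenc, dtype=np.float64)
    m = Xenc.shape[1]
    if len(marker_ids) != m:
        raise ValidationError("marker_ids do not match encoded matrix width")
    if sel.strategy == "explicit_list":
        if not sel.pairs:
            raise ValidationError("explicit_list selection needs a pair list")
        return _canonical_pairs(sel.pairs, marker_ids)
    if sel.strategy == "all_pairs":
        if m > sel.all_pairs_cap:
            raise ValidationError(
                f"all_pairs refused for {m} markers (cap {sel.all_pairs_cap})"
            )
        return tuple(combinations(marker_ids, 2))
    if sel.strategy == "top_t_by_correlation":
        if not 2 <= sel.t <= m:
            raise ValidationError(f"top_t t={sel.t} outside [2, {m}]")
        yc = y.values - y.values.mean()
        Xc = Xenc - Xenc.mean(axis=0)
        sx = np.sqrt((Xc**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc.T @ yc) / (sx * np.sqrt((yc**2).sum()))
        r[~np.isfinite(r)] = 0.0
        top = np.sort(np.argsort(-np.abs(r), kind="stable")[: sel.t])
        ids = [marker_ids[j] for j in top]
        return tuple(combinations(ids, 2))
    raise ValidationError(f"unknown pair strategy {sel.strategy!r}")


def product_features(
    Xenc: np.ndarray, pairs: Sequence[Pair], marker_ids: Sequence[str]
) -> np.ndarray:
    """Traditional multiplicative epistasis: one X_i * X_j column per pair."""
    idx = {mk: j for j, mk in enumerate(marker_ids)}
    Xenc = np.asarray(Xenc, dtype=np.float64)
    cols = [Xenc[:, idx[a]] * Xenc[:, idx[b]] for a, b in pairs]
    return np.column_stack(cols) if cols else np.empty((Xenc.shape[0], 0))


def _pair_categories(
    G: GenotypeMatrix, pairs: Sequence[Pair]
) -> tuple[np.ndarray, np.ndarray]:
    idx = G.marker_index()
    try:
        ai = np.asarray([idx[a] for a, _ in pairs])
        bi = np.asarray([idx[b] for _, b in pairs])
    except KeyError as exc:
        raise TransformError(f"pair references marker {exc.args[0]!r} absent from data")
    return G.values[:, ai], G.values[:, bi]


def _fit_grids(
    G: GenotypeMatrix,
    y: TraitVector,
    pairs: tuple[Pair, ...],
    method: str,
) -> PairGridEncodingModel:
    _require_oriented(G)
    _require_aligned(G, y)
    overall = float(np.mean(y.values))
    va, vb = _pair_categories(G, pairs)
    yv = y.values
    grids = np.full((len(pairs), 3, 3), overall)
    for p in range(len(pairs)):
        ga, gb = va[:, p], vb[:, p]
        valid = (ga != MISSING) & (gb != MISSING)
        # corner cells: plain target means of the four double-homozygote cells
        for a in (0, 2):
            for b in (0, 2):
                in_cell = valid & (ga == a) & (gb == b)
                if in_cell.any():
                    grids[p, a, b] = yv[in_cell].mean()
        if method == "hybrid_one":
            # edges pool over the unconstrained marker; center pools everything
            for b in (0, 2):
                in_col = valid & (gb == b)
                if in_col.any():
                    grids[p, 1, b] = yv[in_col].mean()
            for a in (0, 2):
                in_row = valid & (ga == a)
                if in_row.any():
                    grids[p, a, 1] = yv[in_row].mean()
            if valid.any():
                grids[p, 1, 1] = yv[valid].mean()
        else:  # hybrid_two: average adjacent fitted cells
            g = grids[p]
            g[1, 0] = (g[0, 0] + g[2, 0]) / 2.0
            g[1, 2] = (g[0, 2] + g[2, 2]) / 2.0
            g[0, 1] = (g[0, 0] + g[0, 2]) / 2.0
            g[2, 1] = (g[2, 0] + g[2, 2]) / 2.0
            g[1, 1] = (g[1, 0] + g[1, 2] + g[0, 1] + g[2, 1]) / 4.0
    return PairGridEncodingModel(method, pairs, grids, np.full(len(pairs), overall))


def fit_pair_grid_hybrid_one(
    G: GenotypeMatrix, y: TraitVector, pairs: Sequence[Pair]
) -> PairGridEncodingModel:
    """Corner cells target-encoded; edges/center from pooled marginal means."""
    return _fit_grids(G, y, _canonical_pairs(pairs, G.marker_ids), "hybrid_one")


def fit_pair_grid_hybrid_two(
    G: GenotypeMatrix, y: TraitVector, pairs: Sequence[Pair]
) -> PairGridEncodingModel:
    """Corner cells target-encoded; edges average their adjacent corners and
    the center averages the four edges."""
    return _fit_grids(G, y, _canonical_pairs(pairs, G.marker_ids), "hybrid_two")


def transform_pairs(model: PairGridEncodingModel, G: GenotypeMatrix) -> np.ndarray:
    """Grid lookup per sample per pair; missing at either marker falls back."""
    _require_oriented(G)
    va, vb = _pair_categories(G, model.pairs)
    obs = (va != MISSING) & (vb != MISSING)
    a = np.where(obs, va, 0)
    b = np.where(obs, vb, 0)
    p = np.arange(len(model.pairs))[np.newaxis, :]
    out = model.grids[p, a, b]
    return np.where(obs, out, model.fallback[np.newaxis, :])
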