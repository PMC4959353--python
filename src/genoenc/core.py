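"""Genotype and trait containers shared by every other module.

A biallelic marker genotype is a category in {0, 1, 2}: 0 is the
homozygote for the major allele, 1 the heterozygote, 2 the homozygote for
the minor allele.  Internally categories are stored as ``int8`` with ``-1``
marking a missing call.

Which homozygote the "2" counts is not a property of a genotype file; it
depends on allele frequencies in a reference set of samples.  In
cross-validation that reference set is the training fold, so orientation
decisions never look at test data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

MISSING: int = -1

CATEGORIES = (0, 1, 2)


class ValidationError(ValueError):
    """Malformed genotype/trait structure (duplicate ids, bad values...)."""


class AlignmentError(ValueError):
    """Sample ids of a genotype matrix and a trait vector cannot be joined."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} id: {dup!r}")


@dataclass(frozen=True)
class GenotypeMatrix:
    """Samples x markers table of genotype categories.

    Parameters
    ----------
    sample_ids, marker_ids
        Unique opaque identifiers; row/column order is meaningful (the
        sample order of first appearance is the canonical join order).
    values
        ``int8`` array of shape ``(n_samples, n_markers)`` with entries in
        ``{0, 1, 2}`` or ``MISSING`` (= -1).
    oriented
        True once :func:`orient_major_allele` has fixed, per marker, that
        the allele counted by "2" is the minor allele in the reference
        samples used for orientation.
    """

    sample_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    values: np.ndarray
    oriented: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "marker_ids", tuple(str(m) for m in self.marker_ids))
        v = np.asarray(self.values, dtype=np.int8)
        if v.ndim != 2:
            raise ValidationError("genotype values must be a 2-D table")
        if v.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValidationError(
                f"value table shape {v.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.marker_ids, "marker")
        bad = (v != MISSING) & ((v < 0) | (v > 2))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"genotype value {int(v[r, c])} at sample {self.sample_ids[r]!r}, "
                f"marker {self.marker_ids[c]!r} is not in {{0,1,2}} or missing"
            )
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def marker_index(self) -> dict[str, int]:
        return {m: j for j, m in enumerate(self.marker_ids)}

    def take_samples(self, rows: np.ndarray) -> "GenotypeMatrix":
        """Row subset/reorder by integer or boolean index, metadata preserved."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        ids = tuple(self.sample_ids[i] for i in rows)
        return replace(self, sample_ids=ids, values=self.values[rows].copy())


@dataclass(frozen=True)
class TraitVector:
    """Quantitative trait values keyed by sample id."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.shape[0] != len(self.sample_ids):
            raise ValidationError("trait values must be 1-D, one per sample id")
        _check_unique(self.sample_ids, "sample")
        if len(self.sample_ids) < 2:
            raise ValidationError("a trait vector needs at least 2 samples")
        if not np.all(np.isfinite(v)):
            raise ValidationError("trait values must all be finite")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def take(self, rows: np.ndarray) -> "TraitVector":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return TraitVector(
            tuple(self.sample_ids[i] for i in rows), self.values[rows].copy()
        )


def validate_aligned(
    G: GenotypeMatrix, y: TraitVector
) -> tuple[GenotypeMatrix, TraitVector, dict[str, list[str]]]:
    """Restrict ``G`` and ``y`` to their shared samples, in canonical order.

    Canonical order is the genotype matrix's sample order (order of first
    appearance in the genotype file).  Returns the aligned pair and a report
    of the ids dropped from each side.

    Raises
    ------
    AlignmentError
        If the two id sets are disjoint.
    """
    gset = set(G.sample_ids)
    yset = set(y.sample_ids)
    shared = gset & yset
    if not shared:
        raise AlignmentError("genotype and trait sample ids are disjoint")
    dropped = {
        "genotypes": [s for s in G.sample_ids if s not in shared],
        "traits": [s for s in y.sample_ids if s not in shared],
    }
    if not dropped["genotypes"] and not dropped["traits"] and G.sample_ids == y.sample_ids:
        return G, y, dropped
    keep = [i for i, s in enumerate(G.sample_ids) if s in shared]
    G2 = G.take_samples(np.asarray(keep))
    yidx = {s: i for i, s in enumerate(y.sample_ids)}
    order = np.asarray([yidx[s] for s in G2.sample_ids])
    y2 = y.take(order)
    return G2, y2, dropped


def counted_allele_frequency(
    G: GenotypeMatrix, reference_rows: np.ndarray | None = None
) -> np.ndarray:
    """Frequency, per marker, of the allele counted by the input coding.

    Missing calls are excluded.  Markers with no observed call in the
    reference rows get ``nan``.
    """
    v = G.values if reference_rows is None else G.values[np.asarray(reference_rows)]
    obs = v != MISSING
    counts = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(obs, v, 0).sum(axis=0) / (2.0 * counts)
    return np.where(counts > 0, freq, np.nan)


def major_allele_swaps(
    G: GenotypeMatrix, reference_rows: np.ndarray | None = None
) -> np.ndarray:
    """Boolean mask of markers whose 0/2 categories must be swapped.

    A marker is swapped when the allele its coding counts has frequency
    strictly above 0.5 among the reference rows; an exact tie keeps the
    input orientation.
    """
    freq = counted_allele_frequency(G, reference_rows)
    if np.isnan(freq).any():
        bad = [G.marker_ids[j] for j in np.flatnonzero(np.isnan(freq))]
        warnings.warn(
            f"{len(bad)} marker(s) with all calls missing in the orientation "
            f"reference left unswapped (first: {bad[0]!r})",
            stacklevel=2,
        )
    return np.nan_to_num(freq, nan=0.0) > 0.5


def orient_major_allele(
    G: GenotypeMatrix, reference_rows: np.ndarray | None = None
) -> GenotypeMatrix:
    """Re-orient markers so "2" counts the minor allele in the reference rows.

    For each marker whose counted-allele frequency among ``reference_rows``
    exceeds 0.5, categories 0 and 2 are swapped in *all* rows; heterozygotes
    and missing calls are untouched.  The swap decision uses only the
    reference rows, so in cross-validation the training fold decides and
    the test fold inherits.

    Idempotent for a fixed reference set: once swapped, each frequency is
    at most 0.5 and no further swap triggers.
    """
    if reference_rows is not None:
        ref = np.asarray(reference_rows)
        if ref.dtype == bool:
            if not ref.any():
                raise ValidationError("orientation reference rows are empty")
        elif ref.size == 0:
            raise ValidationError("orientation reference rows are empty")
    swap = major_allele_swaps(G, reference_rows)
    v = G.values.copy()
    cols = np.flatnonzero(swap)
    if cols.size:
        block = v[:, cols]
        obs = block != MISSING
        block[obs] = 2 - block[obs]
        v[:, cols] = block
    return replace(G, values=v, oriented=True)
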