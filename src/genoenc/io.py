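"""Readers and writers for the package's delimited text formats.

Tab-separated text is the canonical interchange everywhere: genotype
matrices (plain ``matrix_tsv`` or the PLINK ``.raw`` dialect), trait
tables, fitted encoding/pair-grid/model tables and CV reports.  Floats are
written with ``repr`` so every round-trip is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, TraitVector, ValidationError
from .encodings import MarkerEncodingModel
from .epistasis import PairGridEncodingModel
from .evaluate import CVReport
from .predict import RRBlupModel


class ParseError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclass(frozen=True)
class GenotypeFileSpec:
    """Dialect and conventions of a genotype file."""

    dialect: Literal["matrix_tsv", "plink_raw"] = "matrix_tsv"
    missing_token: str = "NA"
    orientation: Literal["as_is", "counted_allele"] = "as_is"


_PLINK_LEADING = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _fmt(x: float) -> str:
    return repr(float(x))


def _parse_genotype_frame(
    df: pd.DataFrame, sample_ids: list[str], marker_ids: list[str],
    missing_token: str, path: str,
) -> np.ndarray:
    values = np.full(df.shape, MISSING, dtype=np.int8)
    raw = df.to_numpy(dtype=object)
    for r in range(raw.shape[0]):
        for c in range(raw.shape[1]):
            cell = raw[r, c]
            txt = "" if cell is None else str(cell).strip()
            if txt == missing_token or txt == "" or (
                isinstance(cell, float) and np.isnan(cell)
            ):
                continue
            try:
                v = int(float(txt)) if float(txt).is_integer() else None
            except ValueError:
                v = None
            if v is None or v not in (0, 1, 2):
                raise ParseError(
                    f"{path}: invalid genotype {txt!r} at sample "
                    f"{sample_ids[r]!r}, marker {marker_ids[c]!r}"
                )
            values[r, c] = v
    return values


def read_genotypes(path: str | Path, spec: GenotypeFileSpec | None = None) -> GenotypeMatrix:
    """Read a genotype matrix in the ``matrix_tsv`` or ``plink_raw`` dialect.

    ``matrix_tsv``: header of marker ids with a leading sample-id column.
    ``plink_raw``: whitespace-delimited PLINK ``--recode A`` output; the
    six leading pedigree columns are skipped, IID becomes the sample id and
    the counted-allele suffix (``_A``) is stripped from marker names.
    """
    spec = spec or GenotypeFileSpec()
    path = Path(path)
    if spec.dialect == "matrix_tsv":
        df = pd.read_csv(path, sep="\t", dtype=object)
        if df.shape[1] < 2:
            raise ParseError(f"{path}: matrix_tsv needs a sample column and markers")
        sample_ids = [str(s) for s in df.iloc[:, 0]]
        marker_ids = [str(c) for c in df.columns[1:]]
        body = df.iloc[:, 1:]
    elif spec.dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=object)
        missing_cols = [c for c in _PLINK_LEADING if c not in df.columns]
        if missing_cols:
            raise ParseError(
                f"{path}: plink_raw header lacks column(s) {missing_cols}"
            )
        sample_ids = [str(s) for s in df["IID"]]
        data_cols = [c for c in df.columns if c not in _PLINK_LEADING]
        marker_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in data_cols]
        body = df[data_cols]
    else:
        raise ValidationError(f"unknown genotype dialect {spec.dialect!r}")
    values = _parse_genotype_frame(
        body, sample_ids, marker_ids, spec.missing_token, str(path)
    )
    try:
        return GenotypeMatrix(
            tuple(sample_ids), tuple(marker_ids), values,
            oriented=(spec.orientation == "counted_allele"),
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_genotypes(
    path: str | Path, G: GenotypeMatrix, missing_token: str = "NA"
) -> None:
    """Write the canonical ``matrix_tsv`` form."""
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(G.marker_ids) + "\n")
        for i, s in enumerate(G.sample_ids):
            row = [
                missing_token if v == MISSING else str(int(v)) for v in G.values[i]
            ]
            fh.write(s + "\t" + "\t".join(row) + "\n")


def read_traits(path: str | Path) -> TraitVector:
    """Two-column delimited trait file (sample id, value); header optional."""
    path = Path(path)
    ids: list[str] = []
    vals: list[float] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected two columns")
            sid, txt = parts
            if ln == 1:
                try:
                    float(txt)
                except ValueError:
                    continue  # header line
            try:
                v = float(txt)
            except ValueError:
                raise ParseError(f"{path}:{ln}: non-numeric trait {txt!r}")
            if not np.isfinite(v):
                raise ParseError(f"{path}:{ln}: non-finite trait {txt!r}")
            if sid in ids:
                raise ParseError(f"{path}:{ln}: duplicate sample id {sid!r}")
            ids.append(sid)
            vals.append(v)
    return TraitVector(tuple(ids), np.asarray(vals))


def write_traits(path: str | Path, y: TraitVector) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttrait\n")
        for s, v in zip(y.sample_ids, y.values):
            fh.write(f"{s}\t{_fmt(v)}\n")


def _read_header_block(path: Path) -> tuple[dict[str, str], list[str]]:
    meta: dict[str, str] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line:
                body.append(line)
    return meta, body


def write_encoding_model(path: str | Path, model: MarkerEncodingModel) -> None:
    """Per-marker table (marker_id, E0, E1, E2, impute) with a method header."""
    with open(path, "w") as fh:
        fh.write(f"# method: {model.method}\n")
        fh.write(f"# train_mean: {_fmt(model.train_mean)}\n")
        fh.write("marker_id\tE0\tE1\tE2\timpute\n")
        for j, mk in enumerate(model.marker_ids):
            e = model.table[j]
            fh.write(
                f"{mk}\t{_fmt(e[0])}\t{_fmt(e[1])}\t{_fmt(e[2])}\t"
                f"{_fmt(model.impute[j])}\n"
            )


def read_encoding_model(path: str | Path) -> MarkerEncodingModel:
    path = Path(path)
    meta, body = _read_header_block(path)
    if "method" not in meta:
        raise ParseError(f"{path}: missing '# method:' header")
    rows = [line.split("\t") for line in body[1:]]  # body[0] is the column header
    if any(len(r) != 5 for r in rows):
        raise ParseError(f"{path}: malformed encoding table row")
    marker_ids = tuple(r[0] for r in rows)
    table = np.asarray([[float(r[1]), float(r[2]), float(r[3])] for r in rows])
    impute = np.asarray([float(r[4]) for r in rows])
    return MarkerEncodingModel(
        meta["method"], marker_ids, table, impute, float(meta["train_mean"])
    )


def write_pair_grid_model(path: str | Path, model: PairGridEncodingModel) -> None:
    """Pair table: marker_i, marker_j, 9 cells row-major (a outer, b inner),
    then the fallback."""
    with open(path, "w") as fh:
        fh.write(f"# method: {model.method}\n")
        cells = [f"E{a}{b}" for a in (0, 1, 2) for b in (0, 1, 2)]
        fh.write("marker_i\tmarker_j\t" + "\t".join(cells) + "\tfallback\n")
        for p, (a, b) in enumerate(model.pairs):
            flat = "\t".join(_fmt(v) for v in model.grids[p].ravel())
            fh.write(f"{a}\t{b}\t{flat}\t{_fmt(model.fallback[p])}\n")


def read_pair_grid_model(path: str | Path) -> PairGridEncodingModel:
    path = Path(path)
    meta, body = _read_header_block(path)
    if "method" not in meta:
        raise ParseError(f"{path}: missing '# method:' header")
    rows = [line.split("\t") for line in body[1:]]
    if any(len(r) != 12 for r in rows):
        raise ParseError(f"{path}: malformed pair grid row")
    pairs = tuple((r[0], r[1]) for r in rows)
    grids = np.asarray(
        [[float(v) for v in r[2:11]] for r in rows]
    ).reshape(len(rows), 3, 3)
    fallback = np.asarray([float(r[11]) for r in rows])
    return PairGridEncodingModel(meta["method"], pairs, grids, fallback)


def write_rrblup_model(path: str | Path, model: RRBlupModel) -> None:
    """Effects table with a header block of intercept and variance components."""
    with open(path, "w") as fh:
        fh.write(f"# beta0: {_fmt(model.beta0)}\n")
        fh.write(f"# lambda: {_fmt(model.lam)}\n")
        fh.write(f"# sigma_beta_sq: {_fmt(model.sigma_beta_sq)}\n")
        fh.write(f"# sigma_e_sq: {_fmt(model.sigma_e_sq)}\n")
        fh.write(f"# boundary: {int(model.boundary)}\n")
        fh.write("feature_id\teffect\n")
        for fid, b in zip(model.feature_ids, model.beta):
            fh.write(f"{fid}\t{_fmt(b)}\n")


def read_rrblup_model(path: str | Path) -> RRBlupModel:
    path = Path(path)
    meta, body = _read_header_block(path)
    rows = [line.split("\t") for line in body[1:]]
    if any(len(r) != 2 for r in rows):
        raise ParseError(f"{path}: malformed effects row")
    return RRBlupModel(
        tuple(r[0] for r in rows),
        float(meta["beta0"]),
        np.asarray([float(r[1]) for r in rows]),
        float(meta["lambda"]),
        float(meta["sigma_beta_sq"]),
        float(meta["sigma_e_sq"]),
        bool(int(meta.get("boundary", "0"))),
    )


def write_encoded_matrix(
    path: str | Path, X: np.ndarray, sample_ids: Iterable[str],
    column_ids: Iterable[str],
) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(column_ids) + "\n")
        for sid, row in zip(sample_ids, np.asarray(X)):
            fh.write(sid + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_encoded_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=np.float64), [str(i) for i in df.index], [
        str(c) for c in df.columns
    ]


def write_cv_reports(path: str | Path, reports: Iterable[CVReport]) -> None:
    """Long-format fold table plus one summary row per combination."""
    with open(path, "w") as fh:
        fh.write("method\tpredictor\tfold\tr2\n")
        for rep in reports:
            for f, r2 in enumerate(rep.fold_r2):
                val = "NA" if np.isnan(r2) else _fmt(r2)
                fh.write(f"{rep.encoding}\t{rep.predictor}\t{f}\t{val}\n")
            fh.write(f"{rep.encoding}\t{rep.predictor}\tmean\t{_fmt(rep.mean_r2)}\n")


def write_simulation_truth(path: str | Path, truth) -> None:
    """Structured sidecar with the generative values of a simulated trait."""
    import json

    payload = {
        "seed": truth.seed,
        "sigma_e_sq": truth.sigma_e_sq,
        "realized_h2": truth.realized_h2,
        "causal_markers": list(truth.causal_markers),
        "category_values": {k: list(v) for k, v in truth.category_values.items()},
        "pair_values": {
            f"{a},{b}": np.asarray(g).ravel().tolist()
            for (a, b), g in truth.pair_values.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
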