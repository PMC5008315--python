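"""Readers and writers for the package's on-disk formats.

Everything is plain TSV. Expression matrices are genes-as-rows (the GEO
series-matrix orientation); GCT is accepted as a convenience dialect.
Signatures use a GMT-inspired layout: one module per line, name followed by
``gene:weight`` tokens.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CentroidMatrix,
    ClinicalTable,
    CoxResult,
    ExpressionStudy,
    GeneSignature,
    ModsurvError,
    ParseError,
)

__all__ = [
    "read_expression", "write_expression",
    "read_clinical", "write_clinical",
    "read_signatures", "write_signatures",
    "read_centroids", "write_centroids",
    "write_cox_table", "read_cox_table",
]


def _detect_dialect(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "gct" if first.startswith("#1.2") else "tsv"


def read_expression(path, dialect: str | None = None, study_id: str | None = None) -> ExpressionStudy:
    """Read a genes x samples expression matrix from TSV or GCT.

    Duplicate gene rows are preserved (and flagged on the returned study) so
    that probe collapsing stays an explicit preprocessing step.

    Parameters
    ----------
    dialect : {"tsv", "gct", None}
        ``None`` auto-detects: a leading ``#1.2`` line means GCT.
    study_id :
        Defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = _detect_dialect(path)
    if dialect not in ("tsv", "gct"):
        raise ModsurvError(f"unknown expression dialect {dialect!r}")
    sid = study_id if study_id is not None else path.stem

    if dialect == "gct":
        with open(path) as fh:
            version = fh.readline().rstrip("\n")
            if not version.startswith("#1.2"):
                raise ParseError(f"{path}: GCT file must start with '#1.2'", line=1)
            dims = fh.readline().split()
            if len(dims) != 2:
                raise ParseError(f"{path}: malformed GCT size line", line=2)
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        if "Description" in df.columns:
            df = df.drop(columns=["Description"])
        if df.shape != (n_genes, n_samples):
            raise ParseError(
                f"{path}: GCT size line says {n_genes}x{n_samples}, "
                f"matrix is {df.shape[0]}x{df.shape[1]}", line=2,
            )
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[1] == 0:
            raise ParseError(f"{path}: expression TSV has no sample columns", line=1)

    if df.shape[0] == 0:
        raise ParseError(f"{path}: expression matrix has no gene rows")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric expression columns {non_numeric}", line=1)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    df.columns = df.columns.astype(str)
    study = ExpressionStudy(study_id=sid, data=df)
    if study.has_duplicate_genes:
        warnings.warn(
            f"study {sid!r}: duplicate gene rows present; collapse before scoring",
            stacklevel=2,
        )
    return study


def write_expression(study: ExpressionStudy, path, dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        study.data.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")
    elif dialect == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{study.shape[0]}\t{study.shape[1]}\n")
            out = study.data.copy()
            out.insert(0, "Description", out.index)
            out.to_csv(fh, sep="\t", index_label="Name", float_format="%.10g")
    else:
        raise ModsurvError(f"unknown expression dialect {dialect!r}")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"sample_id": str, "study_id": str},
    )
    for col in ("age_group", "nodal_status", "grade", "treatment", "er_status", "her2_status"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        clinical.df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_signatures(path) -> list[GeneSignature]:
    """Parse a signature file: ``name<TAB>gene:weight<TAB>gene:weight...``.

    Weights are signed reals; ``+1``/``-1`` for published modules. A zero
    weight or a duplicated gene within one record is rejected.
    """
    sigs: list[GeneSignature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("signature record needs a name and >=1 gene token", line=lineno)
            name, tokens = parts[0], parts[1:]
            entries: list[tuple[str, float]] = []
            for tok in tokens:
                if ":" not in tok:
                    raise ParseError(f"malformed token {tok!r}, expected gene:weight", line=lineno)
                gene, _, wtxt = tok.rpartition(":")
                try:
                    w = float(wtxt)
                except ValueError:
                    raise ParseError(f"non-numeric weight {wtxt!r} for gene {gene!r}", line=lineno)
                if w == 0:
                    raise ParseError(f"zero weight for gene {gene!r} is not allowed", line=lineno)
                entries.append((gene, w))
            try:
                sigs.append(GeneSignature(name=name, entries=entries))
            except ModsurvError as exc:
                raise ParseError(str(exc), line=lineno) from exc
    if not sigs:
        raise ParseError(f"{path}: no signature records found")
    return sigs


def _fmt_weight(w: float) -> str:
    if w == int(w):
        return f"{int(w):+d}"
    return f"{w:+.10g}"


def write_signatures(signatures: Iterable[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            tokens = [f"{g}:{_fmt_weight(w)}" for g, w in sig.entries]
            fh.write("\t".join([sig.name] + tokens) + "\n")


def read_centroids(path) -> CentroidMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: centroid matrix needs >= 2 subtype columns", line=1)
    df.index = df.index.astype(str)
    return CentroidMatrix(df)


def write_centroids(centroids: CentroidMatrix, path) -> None:
    centroids.data.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


COX_TABLE_COLUMNS = ["predictor", "cohort", "n", "n_events", "HR", "CI_low", "CI_high", "p", "FDR"]


def write_cox_table(results: Sequence[CoxResult], path, header_lines: Sequence[str] = ()) -> None:
    """Write Cox results as TSV, numbers at 6 significant digits."""
    if not results:
        raise ModsurvError("refusing to write an empty Cox result table")
    rows = [r.as_dict() for r in results]
    df = pd.DataFrame(rows, columns=COX_TABLE_COLUMNS)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_cox_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
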