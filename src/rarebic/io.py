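"""Matrix readers and result writers.

Dense TSV/CSV with named rows and columns is the primary exchange
format; MatrixMarket coordinate files with companion gene/barcode name
files cover 10x-style sparse inputs.  Results are written as JSON
(lossless) or a flat TSV, one bicluster per block.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .core import Bicluster
from .matrix import ExpressionMatrix, MatrixError


@dataclass
class ResultRecord:
    """One reported bicluster plus everything needed to reproduce it."""

    rank: int
    cells: list[str]
    genes: list[str]
    objective: float
    negative_fraction: float
    params_echo: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _read_names(path: Path) -> list[str]:
    names = [
        line.split("\t")[0].strip()
        for line in path.read_text().splitlines()
        if line.strip()
    ]
    if len(set(names)) != len(names):
        raise MatrixError(f"duplicate names in {path}")
    return names


def read_matrix(
    path: str | Path,
    format: str = "auto",
    *,
    genes_in_rows: bool = True,
    normalized: bool = False,
) -> ExpressionMatrix:
    """Read a genes x cells expression matrix.

    TSV/CSV: first row holds cell names, first column gene names (or the
    transpose with ``genes_in_rows=False``).  MTX: MatrixMarket
    coordinate file with companion ``<stem>.genes.txt`` /
    ``<stem>.barcodes.txt`` name files (10x triplet style, also found as
    ``features.tsv`` / ``barcodes.tsv`` next to ``matrix.mtx``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        suffix = path.suffix.lower()
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            suffix
        )
        if format is None:
            raise MatrixError(f"cannot infer format from suffix {suffix!r}")

    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.isna().any().any():
            raise MatrixError(f"{path}: missing or ragged entries")
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as e:
            raise MatrixError(f"{path}: non-numeric entry ({e})") from None
        gene_names = [str(i) for i in df.index]
        cell_names = [str(c) for c in df.columns]
    elif format == "mtx":
        values = np.asarray(mmread(path).todense(), dtype=float)
        stem = path.with_suffix("")
        gene_file = Path(f"{stem}.genes.txt")
        barcode_file = Path(f"{stem}.barcodes.txt")
        if not gene_file.exists():
            gene_file = path.parent / "features.tsv"
        if not barcode_file.exists():
            barcode_file = path.parent / "barcodes.tsv"
        if not gene_file.exists() or not barcode_file.exists():
            raise MatrixError(
                f"{path}: companion gene/barcode name files not found"
            )
        gene_names = _read_names(gene_file)
        cell_names = _read_names(barcode_file)
    else:
        raise ValueError(f"unknown format {format!r}")

    if not genes_in_rows:
        values = values.T
        gene_names, cell_names = cell_names, gene_names
    if values.shape != (len(gene_names), len(cell_names)):
        raise MatrixError(
            f"{path}: matrix shape {values.shape} does not match "
            f"{len(gene_names)} genes x {len(cell_names)} cells"
        )
    if not np.all(np.isfinite(values)):
        raise MatrixError(f"{path}: NaN or infinite entries")
    return ExpressionMatrix(
        values, gene_names=gene_names, cell_names=cell_names,
        normalized=normalized or bool(np.any(values < 0)),
    )


def write_matrix(M: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a matrix as dense TSV/CSV (genes in rows)."""
    sep = {"tsv": "\t", "csv": ","}[format]
    df = pd.DataFrame(M.values, index=M.gene_names, columns=M.cell_names)
    df.to_csv(path, sep=sep)


def make_records(
    biclusters: list[Bicluster],
    params_echo: dict | None = None,
    input_path: str | Path | None = None,
) -> list[ResultRecord]:
    provenance: dict = {"tool": "rarebic", "version": _version(),
                        "timestamp": datetime.now(timezone.utc).isoformat()}
    if input_path is not None:
        p = Path(input_path)
        provenance["input"] = str(p)
        if p.exists():
            provenance["sha256"] = hashlib.sha256(p.read_bytes()).hexdigest()
    return [
        ResultRecord(
            rank=i + 1,
            cells=list(bc.cells),
            genes=list(bc.genes),
            objective=bc.objective,
            negative_fraction=bc.negative_fraction,
            params_echo=dict(params_echo or {}),
            provenance=provenance,
        )
        for i, bc in enumerate(biclusters)
    ]


def _version() -> str:
    from . import __version__

    return __version__


def write_results(
    results: list[ResultRecord], path: str | Path, format: str = "json"
) -> None:
    """Serialize result records; JSON round-trips losslessly."""
    path = Path(path)
    if format == "json":
        payload = [asdict(r) for r in results]
        text = json.dumps(payload, indent=2, allow_nan=False)
        path.write_text(text + "\n")
    elif format == "tsv":
        lines = []
        for r in results:
            lines.append(f"# bicluster {r.rank}")
            lines.append(f"objective\t{r.objective:.12g}")
            lines.append(f"negative_fraction\t{r.negative_fraction:.12g}")
            lines.append("cells\t" + "\t".join(r.cells))
            lines.append("genes\t" + "\t".join(r.genes))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path: str | Path) -> list[ResultRecord]:
    payload = json.loads(Path(path).read_text())
    return [ResultRecord(**entry) for entry in payload]
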