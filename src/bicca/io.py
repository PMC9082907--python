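"""Reading and writing on-disk formats.

Supported inputs: Matrix Market triplet directories (matrix + feature +
barcode sidecars, the common sparse single-cell exchange layout), dense
CSV/TSV tables (features in rows, cells in columns), BED/GTF gene
models, and two-column label TSVs.  Integration results are written to
a directory of per-array files plus a JSON manifest, so every piece is
inspectable with standard tools.

Genomic coordinates are 0-based half-open everywhere inside the
package; BED is taken as-is and GTF (1-based inclusive) is converted on
load.
"""

from __future__ import annotations

import json
import os
import re
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import (
    CellAnnotation,
    CoEmbedding,
    FormatError,
    FusionMatrix,
    GeneModel,
    IntegrationResult,
    ModalityMatrix,
    ValidationError,
)

_MTX_NAMES = ("matrix.mtx", "matrix.mtx.gz")
_FEATURE_NAMES = ("features.tsv", "genes.tsv", "features.txt", "peaks.tsv")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.txt", "cells.tsv")


def _find_companion(d: Path, names: tuple[str, ...], what: str) -> Path:
    for n in names:
        p = d / n
        if p.exists():
            return p
    raise FormatError(f"{d}: no {what} file (looked for {', '.join(names)})")


def _read_id_column(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def load_modality(
    path: str | os.PathLike,
    format: str = "auto",
    modality: str = "unknown",
    transpose: bool = False,
) -> ModalityMatrix:
    """Load a feature-by-cell matrix.

    ``format`` is ``mtx_dir`` (directory with matrix.mtx + features.tsv
    + barcodes.tsv), ``dense_table`` (CSV/TSV, header row of cell IDs,
    first column of feature IDs) or ``auto``.  ``transpose`` accepts the
    cell-by-feature dialect of dense tables.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file or directory")
    if format == "auto":
        format = "mtx_dir" if path.is_dir() else "dense_table"

    if format == "mtx_dir":
        mtx = _find_companion(path, _MTX_NAMES, "matrix")
        feat = _find_companion(path, _FEATURE_NAMES, "feature")
        bc = _find_companion(path, _BARCODE_NAMES, "barcode")
        try:
            values = sp.csr_matrix(scipy.io.mmread(mtx), dtype=float)
        except Exception as e:  # noqa: BLE001
            raise FormatError(f"{mtx}: cannot parse Matrix Market file: {e}") from e
        feature_ids = _read_id_column(feat)
        cell_ids = _read_id_column(bc)
        if values.shape != (len(feature_ids), len(cell_ids)):
            raise FormatError(
                f"{path}: matrix is {values.shape} but sidecars list "
                f"{len(feature_ids)} features / {len(cell_ids)} barcodes"
            )
        return ModalityMatrix(values, feature_ids, cell_ids, modality)

    if format == "dense_table":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as e:  # noqa: BLE001
            raise FormatError(f"{path}: cannot parse table: {e}") from e
        with open(path) as fh:
            raw_header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(raw_header) == df.shape[1]:
            df.columns = raw_header  # undo pandas' silent dedup of repeats
        if transpose:
            df = df.T
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as e:
            raise FormatError(f"{path}: non-numeric entries: {e}") from e
        return ModalityMatrix(
            values, [str(i) for i in df.index], [str(c) for c in df.columns], modality
        )

    raise ValueError(f"unknown format {format!r}")


def save_modality(m: ModalityMatrix, path: str | os.PathLike, format: str = "auto") -> None:
    """Write a ModalityMatrix as an MTX directory or a dense table."""
    path = Path(path)
    if format == "auto":
        format = "mtx_dir" if sp.issparse(m.values) else "dense_table"
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(m.values))
        (path / "features.tsv").write_text("".join(f"{f}\n" for f in m.feature_ids))
        (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))
    elif format == "dense_table":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        pd.DataFrame(m.dense(), index=m.feature_ids, columns=m.cell_ids).to_csv(
            path, sep=sep
        )
    else:
        raise ValueError(f"unknown format {format!r}")


_BED_MIN_COLS = 3


def _parse_bed_line(line: str, lineno: int) -> GeneModel:
    parts = re.split(r"\s+", line.strip())
    if len(parts) < _BED_MIN_COLS:
        raise FormatError(f"BED line {lineno}: expected >=3 columns, got {len(parts)}")
    chrom = parts[0]
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError as e:
        raise FormatError(f"BED line {lineno}: non-integer coordinates") from e
    gene_id = parts[3] if len(parts) > 3 and parts[3] != "." else f"{chrom}:{start}-{end}"
    strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "+"
    try:
        return GeneModel(gene_id, chrom, start, end, strand)
    except ValidationError as e:
        raise ValidationError(f"BED line {lineno}: {e}") from e


_GTF_ATTR = re.compile(r'gene_id\s+"([^"]+)"|gene_id\s+([^;\s]+)')


def _parse_gtf_records(path: Path) -> list[tuple[str, str, int, int, str, str]]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(
                    f"GTF line {lineno}: expected 9 tab-separated columns, got {len(parts)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = parts[:9]
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as e:
                raise FormatError(f"GTF line {lineno}: non-integer coordinates") from e
            m = _GTF_ATTR.search(attrs)
            if m is None:
                raise FormatError(f"GTF line {lineno}: no gene_id attribute")
            gene_id = m.group(1) or m.group(2)
            # GTF is 1-based inclusive -> 0-based half-open
            start, end = start1 - 1, end1
            if start >= end:
                raise ValidationError(f"GTF line {lineno}: empty interval after conversion")
            records.append((gene_id, chrom, start, end, strand if strand in "+-" else "+", feature))
    return records


def load_gene_models(path: str | os.PathLike, format: str = "auto") -> list[GeneModel]:
    """Read gene models from BED (0-based half-open) or GTF (1-based).

    GTF is restricted to rows of feature type ``gene``; when a file has
    none, the union of each gene_id's transcripts is used instead.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if format == "auto":
        format = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed"

    if format == "bed":
        genes = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                genes.append(_parse_bed_line(line, lineno))
        return genes

    if format == "gtf":
        records = _parse_gtf_records(path)
        gene_rows = [r for r in records if r[5] == "gene"]
        if gene_rows:
            return [GeneModel(g, c, s, e, st) for g, c, s, e, st, _ in gene_rows]
        # fallback: span of transcripts per gene_id, file order of first sight
        span: dict[str, list] = {}
        order = []
        for g, c, s, e, st, feat in records:
            if feat != "transcript":
                continue
            if g not in span:
                span[g] = [c, s, e, st]
                order.append(g)
            else:
                span[g][1] = min(span[g][1], s)
                span[g][2] = max(span[g][2], e)
        return [GeneModel(g, *span[g]) for g in order]

    raise ValueError(f"unknown format {format!r}")


def load_labels(path: str | os.PathLike, modality: str = "unknown") -> CellAnnotation:
    """Two-column TSV (cell_id, label), optional header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need two columns (cell_id, label)")
    first = df.iloc[0]
    if str(first[0]).lower() in ("cell", "cell_id", "barcode"):
        df = df.iloc[1:]
    return CellAnnotation(list(df.iloc[:, 0]), list(df.iloc[:, 1]), modality)


def save_labels(ann: CellAnnotation, path: str | os.PathLike) -> None:
    pd.DataFrame({"cell_id": ann.cell_ids, "label": ann.labels}).to_csv(
        path, sep="\t", index=False, header=False
    )


def load_fusion(path: str | os.PathLike, transpose: bool = False) -> FusionMatrix:
    m = load_modality(path, transpose=transpose)
    return FusionMatrix(m.dense(), m.feature_ids, m.cell_ids)


def load_config(path: str | os.PathLike) -> dict[str, str]:
    """Flat ``key = value`` / ``key: value`` config file."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            for sep in ("=", ":"):
                if sep in line:
                    k, v = line.split(sep, 1)
                    cfg[k.strip()] = v.strip()
                    break
            else:
                raise FormatError(f"config line {lineno}: expected key=value")
    return cfg


_ARRAYS = {
    "U": lambda r: r.embedding.U,
    "S": lambda r: r.embedding.S,
    "T": lambda r: r.embedding.T,
    "V": lambda r: r.embedding.V,
    "canonical_correlations": lambda r: r.embedding.canonical_correlations,
    "singular_values": lambda r: r.embedding.singular_values,
    "Z": lambda r: r.fusion.values,
}


def save_result(result: IntegrationResult, out_dir: str | os.PathLike) -> dict:
    """Serialize an IntegrationResult to a directory.

    Arrays go to ``.npy`` files, the objective trace to a TSV, IDs to
    plain text, parameters to ``manifest.json``.  The manifest is
    written last via an atomic rename, so a directory containing a
    manifest is always complete.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "format": "bicca-result-v1",
        "alpha": result.alpha,
        "lambda": result.lambda_,
        "n_l": result.n_l,
        "n_r": result.n_r,
        "E": int(result.embedding.E),
        "converged": bool(result.converged),
        "iterations": int(result.iterations),
        "mode": result.mode,
        "seed": result.seed,
        "arrays": [],
    }
    for name, get in _ARRAYS.items():
        np.save(out / f"{name}.npy", np.asarray(get(result)))
        manifest["arrays"].append(name)
    if result.iteration0 is not None:
        for name in ("U", "S", "T", "V"):
            np.save(out / f"iteration0_{name}.npy", getattr(result.iteration0, name))
        manifest["iteration0"] = True
    with open(out / "objective_trace.tsv", "w") as fh:
        fh.write("iteration\tobjective\n")
        for t, f in enumerate(result.objective_trace):
            fh.write(f"{t}\t{f!r}\n")
    for name, ids in (
        ("cell_ids_x", result.cell_ids_x),
        ("cell_ids_y", result.cell_ids_y),
        ("feature_ids_x", result.feature_ids_x),
        ("feature_ids_y", result.feature_ids_y),
    ):
        (out / f"{name}.txt").write_text("".join(f"{i}\n" for i in ids))
    fd, tmp = tempfile.mkstemp(dir=out, suffix=".json.tmp")
    with os.fdopen(fd, "w") as fh:
        json.dump(manifest, fh, indent=1)
    os.replace(tmp, out / "manifest.json")
    return manifest


def load_result(out_dir: str | os.PathLike) -> IntegrationResult:
    """Inverse of :func:`save_result`; arrays restored exactly."""
    out = Path(out_dir)
    mpath = out / "manifest.json"
    if not mpath.exists():
        raise FormatError(f"{out}: no manifest.json (incomplete result directory?)")
    manifest = json.loads(mpath.read_text())
    arrays = {name: np.load(out / f"{name}.npy") for name in manifest["arrays"]}
    emb = CoEmbedding(
        U=arrays["U"], S=arrays["S"], T=arrays["T"], V=arrays["V"],
        canonical_correlations=arrays["canonical_correlations"],
        singular_values=arrays["singular_values"],
    )
    it0 = None
    if manifest.get("iteration0"):
        it0 = CoEmbedding(
            U=np.load(out / "iteration0_U.npy"),
            S=np.load(out / "iteration0_S.npy"),
            T=np.load(out / "iteration0_T.npy"),
            V=np.load(out / "iteration0_V.npy"),
            canonical_correlations=arrays["canonical_correlations"],
            singular_values=arrays["singular_values"],
        )
    trace = list(
        pd.read_csv(out / "objective_trace.tsv", sep="\t")["objective"].astype(float)
    )
    ids = {}
    for name in ("cell_ids_x", "cell_ids_y", "feature_ids_x", "feature_ids_y"):
        p = out / f"{name}.txt"
        ids[name] = p.read_text().splitlines() if p.exists() else []
    fusion = FusionMatrix(
        arrays["Z"],
        ids["feature_ids_x"] or [f"f{i}" for i in range(arrays["Z"].shape[0])],
        ids["cell_ids_y"] or [f"c{i}" for i in range(arrays["Z"].shape[1])],
    )
    return IntegrationResult(
        embedding=emb,
        fusion=fusion,
        objective_trace=trace,
        alpha=float(manifest["alpha"]),
        lambda_=float(manifest["lambda"]),
        n_l=float(manifest["n_l"]),
        n_r=float(manifest["n_r"]),
        converged=bool(manifest["converged"]),
        iterations=int(manifest["iterations"]),
        iteration0=it0,
        mode=manifest.get("mode", "full"),
        seed=manifest.get("seed"),
        cell_ids_x=ids["cell_ids_x"],
        cell_ids_y=ids["cell_ids_y"],
        feature_ids_x=ids["feature_ids_x"],
        feature_ids_y=ids["feature_ids_y"],
    )
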