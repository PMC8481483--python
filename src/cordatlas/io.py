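"""Reading and writing the pipeline's on-disk formats.

Count matrices travel as Matrix Market (matrix.mtx) with barcodes.tsv /
features.tsv sidecars and an optional metadata.tsv of per-cell annotations;
dense CSV is accepted as an alternative.  Matrices are cells-by-genes in
memory; MTX on disk may be gene-by-cell (the common convention), controlled
by a transpose flag on read.  Gene lists are one name per line; reports are
JSON; cluster labels and tables are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
from anndata import AnnData

__all__ = ["read_counts", "write_counts", "write_json", "read_json"]


def _dedupe(names: list[str]) -> tuple[list[str], list[str]]:
    """Deterministically suffix duplicate names with -1, -2, ..."""
    seen: dict[str, int] = {}
    out, logged = [], []
    for n in names:
        if n in seen:
            seen[n] += 1
            new = f"{n}-{seen[n]}"
            logged.append(new)
            out.append(new)
        else:
            seen[n] = 0
            out.append(n)
    return out, logged


def read_counts(
    path: str | Path, fmt: str = "mtx_dir", transpose: bool = False
) -> AnnData:
    """Read a counts matrix with sidecars into a cells-by-genes AnnData.

    ``mtx_dir`` expects matrix.mtx, barcodes.tsv, features.tsv, and an
    optional metadata.tsv indexed by barcode.  ``csv`` expects one dense
    cells-by-genes table with barcode index and gene columns.  Duplicate gene
    names are suffixed deterministically and recorded in ``.uns``.
    """
    path = Path(path)
    if fmt == "mtx_dir":
        X = sp.csr_matrix(sio.mmread(path / "matrix.mtx"))
        if transpose:
            X = X.T.tocsr()
        barcodes = (path / "barcodes.tsv").read_text().split()
        features = (path / "features.tsv").read_text().split()
        if X.shape[0] != len(barcodes) or X.shape[1] != len(features):
            raise ValueError(
                f"dimension mismatch: matrix.mtx is {X.shape} but barcodes.tsv has "
                f"{len(barcodes)} entries and features.tsv has {len(features)}"
            )
        genes, logged = _dedupe(features)
        adata = AnnData(
            X=X, obs=pd.DataFrame(index=barcodes), var=pd.DataFrame(index=genes)
        )
        meta_path = path / "metadata.tsv"
        if meta_path.exists():
            meta = pd.read_csv(meta_path, sep="\t", index_col=0)
            adata.obs = adata.obs.join(meta)
    elif fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        genes, logged = _dedupe(list(df.columns))
        adata = AnnData(
            X=sp.csr_matrix(df.to_numpy()),
            obs=pd.DataFrame(index=df.index.astype(str)),
            var=pd.DataFrame(index=genes),
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty count matrix")
    if logged:
        adata.uns["deduplicated_genes"] = logged
    return adata


def write_counts(adata: AnnData, outdir: str | Path) -> None:
    """Write MTX + sidecars (+ metadata.tsv when obs has columns)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    sio.mmwrite(str(outdir / "matrix.mtx"), X.tocoo())
    (outdir / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    (outdir / "features.tsv").write_text("\n".join(adata.var_names) + "\n")
    if len(adata.obs.columns):
        adata.obs.to_csv(outdir / "metadata.tsv", sep="\t")


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
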