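"""Readers and writers for the package's on-disk formats.

Counts travel as MatrixMarket (MTX) plus row/column TSVs or as a dense TSV;
cell metadata, GRN edges and truth tables as TSV; genomic intervals as BED
(0-based half-open); gene sets as GMT.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .nbgam import TrajectoryDataset

__all__ = [
    "write_trajectory_dataset",
    "read_trajectory_dataset",
    "write_counts_mtx",
    "read_counts_mtx",
    "read_gmt",
]


def write_counts_mtx(counts: pd.DataFrame, out_dir: Path, prefix: str = "counts") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out_dir / f"{prefix}.mtx", scipy.sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(out_dir / f"{prefix}.rows.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.columns).to_csv(out_dir / f"{prefix}.cols.tsv", sep="\t", index=False, header=False)


def read_counts_mtx(out_dir: Path, prefix: str = "counts") -> pd.DataFrame:
    out_dir = Path(out_dir)
    mat = scipy.io.mmread(out_dir / f"{prefix}.mtx").toarray()
    rows = pd.read_csv(out_dir / f"{prefix}.rows.tsv", sep="\t", header=None)[0].tolist()
    cols = pd.read_csv(out_dir / f"{prefix}.cols.tsv", sep="\t", header=None)[0].tolist()
    return pd.DataFrame(mat, index=rows, columns=cols)


def write_trajectory_dataset(data: TrajectoryDataset, out_dir: Path) -> None:
    """Counts as MTX + row/column TSVs; cell metadata as one TSV."""
    out_dir = Path(out_dir)
    counts = pd.DataFrame(data.counts, index=data.genes, columns=data.cells)
    write_counts_mtx(counts, out_dir)
    meta = pd.DataFrame({"cell_id": data.cells, "lineage": data.lineage, "offset": data.offsets})
    for l in range(data.n_lineages):
        meta[f"pseudotime_{l}"] = data.pseudotime[:, l]
    for j in range(data.covariates.shape[1]):
        meta[f"covariate_{j}"] = data.covariates[:, j]
    meta.to_csv(out_dir / "cell_meta.tsv", sep="\t", index=False)


def read_trajectory_dataset(out_dir: Path) -> TrajectoryDataset:
    out_dir = Path(out_dir)
    counts = read_counts_mtx(out_dir)
    meta = pd.read_csv(out_dir / "cell_meta.tsv", sep="\t")
    pt_cols = sorted(c for c in meta.columns if c.startswith("pseudotime_"))
    cov_cols = sorted(c for c in meta.columns if c.startswith("covariate_"))
    return TrajectoryDataset(
        counts=counts.to_numpy(),
        genes=list(counts.index),
        cells=list(meta["cell_id"].astype(str)),
        pseudotime=meta[pt_cols].to_numpy(),
        lineage=meta["lineage"].to_numpy(),
        offsets=meta["offset"].to_numpy(),
        covariates=meta[cov_cols].to_numpy() if cov_cols else np.zeros((len(meta), 0)),
    )


def read_gmt(path: Path) -> dict[str, set[str]]:
    """Gene sets in GMT format: name <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets
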