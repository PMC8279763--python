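"""File formats: MatrixMarket count matrices, lineage logs, summary tables.

Count matrices follow the CellRanger-style triplet convention — a
genes x cells coordinate-integer ``matrix.mtx`` beside ``features.tsv``
(gene_id, length_kb) and ``barcodes.tsv`` (cell_id) — so simulated
populations drop straight into standard single-cell toolchains. Cells with
empty transcriptomes are legal and are preserved as barcodes with no
nonzero entries.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .genome import Genome
from .lineage import Population

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_lineage",
    "read_lineage",
    "write_genome_features",
    "read_genome_features",
]


def write_genome_features(genome: Genome, path: os.PathLike | str) -> None:
    """Two-column TSV (gene_id, length_kb) — the features file."""
    pd.DataFrame({"gene_id": genome.names, "length_kb": genome.lengths}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_genome_features(path: os.PathLike | str, ploidy: int = 1) -> Genome:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length_kb"])
    return Genome.from_lengths(df["length_kb"].tolist(), ploidy=ploidy)


def write_matrix(
    counts: np.ndarray,
    genome: Genome,
    out_dir: os.PathLike | str,
    cell_ids: Sequence | None = None,
) -> Path:
    """Write a cells x genes count matrix as matrix.mtx + features/barcodes TSVs.

    The mtx file is stored genes x cells (coordinate integer), entries in
    row-major gene order so repeated writes are byte-identical.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] != genome.n_genes:
        raise ValueError("counts must be a cells x genes matrix matching the genome")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gxc = scipy.sparse.coo_matrix(counts.T.astype(np.int64))
    scipy.io.mmwrite(out / "matrix.mtx", gxc, field="integer")
    write_genome_features(genome, out / "features.tsv")
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(counts.shape[0])]
    pd.Series(list(cell_ids)).to_csv(out / "barcodes.tsv", header=False, index=False)
    return out


def read_matrix(
    in_dir: os.PathLike | str, ploidy: int = 1
) -> tuple[np.ndarray, Genome, list[str]]:
    """Read matrix.mtx + features.tsv + barcodes.tsv back into memory.

    Returns (cells x genes int array, genome, barcodes); round-trips
    :func:`write_matrix` exactly.
    """
    in_dir = Path(in_dir)
    gxc = scipy.io.mmread(in_dir / "matrix.mtx")
    counts = np.asarray(gxc.todense()).T.astype(np.int64)
    genome = read_genome_features(in_dir / "features.tsv", ploidy=ploidy)
    barcodes = pd.read_csv(
        in_dir / "barcodes.tsv", header=None
    )[0].astype(str).tolist()
    return counts, genome, barcodes


LINEAGE_COLUMNS = [
    "cell_id",
    "parent_id",
    "generation",
    "lineage_label",
    "gamma_hr",
    "birth_time_hr",
    "division_time_hr",
    "n_divisions",
]


def write_lineage(population: Population, out_path: os.PathLike | str) -> Path:
    """Lineage log CSV: one row per cell ever created; founders have empty parent."""
    df = population.to_lineage_frame()
    df["parent_id"] = df["parent_id"].map(lambda p: "" if p < 0 else str(int(p)))
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_path, index=False, columns=LINEAGE_COLUMNS)
    return out_path


def read_lineage(path: os.PathLike | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["parent_id"] = (
        df["parent_id"].fillna(-1).astype(np.int64)
        if df["parent_id"].dtype != object
        else df["parent_id"].replace("", -1).fillna(-1).astype(np.int64)
    )
    return df
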