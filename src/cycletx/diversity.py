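"""Transcriptome diversity: analytic formula, enumeration oracle, census, binning.

After one cell cycle a parent holds a deterministic transcript vector
(N_1, ..., N_G); random partitioning at mitosis can hand a daughter any
count c_i between 0 and N_i for each gene independently, so the number of
distinct daughter transcriptomes is

    diversity = n * prod_i (N_i + 1)

with n the ploidy-level leading factor. Because N_i collapses to 0 as soon
as gene length exceeds gamma * lambda, the cell cycle duration directly
tunes how many factors exceed one — the combinatorial heart of the
transcriptional-filter model. This module provides that closed form, an
exhaustive enumeration oracle to validate it, an empirical census of
distinct transcriptomes in simulated populations, and the short/medium/long
gene-length binning used to summarise expression by length class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import Genome, TranscriptionParams
from .transcription import transcribe, transcripts_per_gene

__all__ = [
    "DiversityResult",
    "BinSummary",
    "analytic_diversity",
    "enumerate_reachable_transcriptomes",
    "empirical_diversity",
    "bin_by_length",
    "assign_length_bins",
]

DEFAULT_BIN_NAMES = ("short", "medium", "long")


@dataclass(frozen=True)
class DiversityResult:
    """Analytic and (optionally) empirical diversity under one configuration."""

    analytic: int
    empirical: int | None
    gamma: float
    genome: Genome
    params: TranscriptionParams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "analytic_diversity": self.analytic,
                    "empirical_diversity": self.empirical,
                    "gamma_hr": self.gamma,
                    "n_genes": self.genome.n_genes,
                    "ploidy": self.genome.ploidy,
                    "rate_kb_hr": self.params.rate,
                    "reinit_spacing_kb": self.params.reinit_spacing,
                    "serial_mode": self.params.serial_mode,
                }
            ]
        )


def analytic_diversity(
    genome: Genome,
    gamma: float,
    params: TranscriptionParams,
    *,
    ploidy_variant: str = "leading",
) -> int:
    """Closed-form count of distinct daughter transcriptomes after one division.

    ``n * prod_i (N_i + 1)`` where ``N_i`` is the complete-transcript count
    of gene i for one genome copy in a cycle of length gamma. The default
    treats ploidy as the printed leading factor n; ``ploidy_variant="per_gene"``
    instead counts partitions of the pooled n-copy output,
    ``prod_i (n * N_i + 1)``, exposed for sensitivity analysis.
    """
    counts = [transcripts_per_gene(gamma, params, g.length) for g in genome.genes]
    if ploidy_variant == "leading":
        prod = 1
        for N in counts:
            prod *= N + 1
        return genome.ploidy * prod
    if ploidy_variant == "per_gene":
        prod = 1
        for N in counts:
            prod *= genome.ploidy * N + 1
        return prod
    raise ValueError(f"unknown ploidy_variant {ploidy_variant!r}")


def enumerate_reachable_transcriptomes(
    genome: Genome,
    gamma: float,
    params: TranscriptionParams,
    *,
    cap: int = 100_000,
) -> set[tuple[int, ...]]:
    """Exhaustively enumerate every daughter transcriptome (oracle).

    A daughter can receive any per-gene count between 0 and the parental
    count, independently per gene; the Cartesian product of those ranges is
    the exact reachable set. For ploidy 1 its size must equal
    :func:`analytic_diversity`. Refuses (with the required cap) when the
    product exceeds ``cap``.
    """
    parent = transcribe(genome, gamma, params)
    size = int(np.prod([int(c) + 1 for c in parent], dtype=object))
    if size > cap:
        raise ValueError(
            f"enumeration would produce {size} transcriptomes, above cap {cap}; "
            "raise cap explicitly to proceed"
        )
    ranges = [range(int(c) + 1) for c in parent]
    return set(itertools.product(*ranges))


def empirical_diversity(matrix: np.ndarray) -> int:
    """Number of distinct transcriptomes (distinct integer rows) observed."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise ValueError("expected a cells x genes 2-D count matrix")
    if matrix.shape[0] == 0:
        return 0
    return int(np.unique(matrix, axis=0).shape[0])


def assign_length_bins(
    lengths: Sequence[float],
    n_bins: int = 3,
    edges: Sequence[float] | None = None,
) -> np.ndarray:
    """Bin index (0 = shortest class) per gene.

    Default is equal-fill binning by length rank: genes are sorted by length
    and dealt into ``n_bins`` contiguous rank blocks whose sizes differ by at
    most one, remainder genes going to the shortest bins; ties in length are
    resolved to the lower bin by stable rank order. Explicit ``edges``
    switches to fixed thresholds: bin b holds genes with
    ``edges[b-1] <= length < edges[b]``.
    """
    lengths = np.asarray(lengths, dtype=float)
    G = len(lengths)
    if edges is not None:
        return np.digitize(lengths, np.asarray(edges, dtype=float))
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > G:
        raise ValueError(f"n_bins ({n_bins}) exceeds gene count ({G})")
    order = np.argsort(lengths, kind="stable")
    base, rem = divmod(G, n_bins)
    sizes = [base + (1 if b < rem else 0) for b in range(n_bins)]
    bins = np.empty(G, dtype=np.int64)
    start = 0
    for b, s in enumerate(sizes):
        bins[order[start : start + s]] = b
        start += s
    return bins


@dataclass(frozen=True)
class BinSummary:
    """Per-cell mean transcript count per gene-length bin."""

    bin_of_gene: np.ndarray  # bin index per gene
    bin_names: tuple[str, ...]
    genes_per_bin: np.ndarray
    per_cell_means: pd.DataFrame  # cells x bins
    edges: tuple[float, ...] | None

    @property
    def bin_means(self) -> pd.Series:
        """Grand mean transcript count per bin (mean over cells)."""
        return self.per_cell_means.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        out = self.per_cell_means.copy()
        out.index.name = "cell"
        return out


def bin_by_length(
    matrix: np.ndarray,
    lengths: Sequence[float],
    n_bins: int = 3,
    edges: Sequence[float] | None = None,
    bin_names: Sequence[str] | None = None,
) -> BinSummary:
    """Average each cell's transcript counts within gene-length bins.

    Returns a :class:`BinSummary` whose ``per_cell_means`` table has one row
    per cell and one column per bin (shortest class first).
    """
    matrix = np.asarray(matrix)
    lengths = np.asarray(lengths, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != len(lengths):
        raise ValueError(
            f"matrix columns ({matrix.shape[1] if matrix.ndim == 2 else '?'}) "
            f"must match number of gene lengths ({len(lengths)})"
        )
    bins = assign_length_bins(lengths, n_bins=n_bins, edges=edges)
    k = int(bins.max()) + 1 if len(bins) else 0
    if edges is not None:
        k = len(edges) + 1
    if bin_names is None:
        bin_names = (
            DEFAULT_BIN_NAMES if k == 3 else tuple(f"bin_{b}" for b in range(k))
        )
    genes_per_bin = np.bincount(bins, minlength=k)
    cols = {}
    for b in range(k):
        sel = bins == b
        cols[bin_names[b]] = (
            matrix[:, sel].mean(axis=1) if sel.any() else np.zeros(matrix.shape[0])
        )
    return BinSummary(
        bin_of_gene=bins,
        bin_names=tuple(bin_names),
        genes_per_bin=genes_per_bin,
        per_cell_means=pd.DataFrame(cols),
        edges=tuple(edges) if edges is not None else None,
    )
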