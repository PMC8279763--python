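"""Genomes, genes, and global transcription parameters.

A genome here is nothing more than an ordered list of gene lengths (in kb)
plus a ploidy level: the model treats transcription time as proportional to
gene length, so lengths are the only per-gene attribute that matters. By
convention every gene has a distinct length and genes are ordered from
shortest to longest, which lets a gene be labelled by its length
(``gene^1.5`` is the 1.5 kb gene).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Gene",
    "Genome",
    "TranscriptionParams",
    "make_uniform_genome",
    "validate_genome",
]


@dataclass(frozen=True)
class Gene:
    """A single gene: 1-based position in the genome and length in kb."""

    index: int
    length: float

    @property
    def name(self) -> str:
        """Length-based display label, e.g. ``gene^2.5`` for a 2.5 kb gene."""
        length = self.length
        if float(length).is_integer():
            return f"gene^{int(length)}"
        return f"gene^{length:g}"

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"gene index must be >= 1, got {self.index}")
        if not self.length > 0:
            raise ValueError(f"gene length must be positive, got {self.length}")


@dataclass(frozen=True)
class Genome:
    """Ordered collection of genes plus ploidy.

    Parameters
    ----------
    genes
        Genes ordered by position; lengths are expected to be strictly
        increasing (use ``strict=False`` to permit ties, which
        :func:`validate_genome` will still flag).
    ploidy
        Number of genome copies per cell (>= 1). Each copy transcribes
        independently and deterministically, so ploidy simply multiplies
        per-gene transcript output.
    """

    genes: tuple[Gene, ...]
    ploidy: int = 1
    strict: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("genome must contain at least one gene")
        if self.strict:
            if self.ploidy < 1:
                raise ValueError(f"ploidy must be >= 1, got {self.ploidy}")
            lengths = self.lengths
            if np.any(np.diff(lengths) <= 0):
                raise ValueError(
                    "gene lengths must be strictly increasing; "
                    "pass strict=False to allow ties"
                )

    @classmethod
    def from_lengths(
        cls, lengths: Sequence[float], ploidy: int = 1, strict: bool = True
    ) -> "Genome":
        genes = tuple(Gene(i + 1, float(L)) for i, L in enumerate(lengths))
        return cls(genes=genes, ploidy=ploidy, strict=strict)

    @property
    def lengths(self) -> np.ndarray:
        """Gene lengths in kb, genome order, as a float array."""
        return np.array([g.length for g in self.genes], dtype=float)

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.genes]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class TranscriptionParams:
    """Global transcription machinery parameters.

    Parameters
    ----------
    rate
        RNA polymerase II elongation rate lambda, kb/hr (> 0). All genes
        share one rate.
    reinit_spacing
        Re-initiation spacing Omega, kb (> 0): transcribed distance after
        which a new polymerase may initiate on the same gene, i.e. the gap
        between concurrent polymerases.
    serial_mode
        If True, a single polymerase per gene: re-initiation happens only
        after the previous transcript completes (one initiation slot).
    parental_retention
        Proportion in [0, 1] of inherited parental transcripts that survive
        each division. 0 recovers the base model in which every cycle starts
        transcription from scratch.
    """

    rate: float = 1.0
    reinit_spacing: float = 0.25
    serial_mode: bool = False
    parental_retention: float = 0.0

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError(f"transcription rate must be positive, got {self.rate}")
        if not self.reinit_spacing > 0:
            raise ValueError(
                f"re-initiation spacing must be positive, got {self.reinit_spacing}"
            )
        if not 0.0 <= self.parental_retention <= 1.0:
            raise ValueError(
                f"parental_retention must be in [0, 1], got {self.parental_retention}"
            )


def make_uniform_genome(
    count: int, min_len: float, max_len: float, ploidy: int = 1
) -> Genome:
    """Build a genome of `count` genes evenly spaced from min_len to max_len kb.

    Examples
    --------
    >>> make_uniform_genome(5, 1, 2).lengths
    array([1.  , 1.25, 1.5 , 1.75, 2.  ])
    """
    if count < 1:
        raise ValueError(f"gene count must be >= 1, got {count}")
    if not min_len > 0:
        raise ValueError(f"min_len must be positive, got {min_len}")
    if count > 1 and not min_len < max_len:
        raise ValueError("min_len must be < max_len when count > 1")
    if count == 1:
        lengths = [float(min_len)]
    else:
        lengths = np.linspace(min_len, max_len, count).tolist()
    return Genome.from_lengths(lengths, ploidy=ploidy)


def validate_genome(genome: Genome) -> list[str]:
    """Report all genome invariant violations (empty list means valid).

    Never raises: intended for checking relaxed (``strict=False``) genomes
    or externally supplied length tables.
    """
    violations: list[str] = []
    lengths = genome.lengths
    for i, L in enumerate(lengths):
        if not L > 0 or not math.isfinite(L):
            violations.append(f"gene {i + 1}: non-positive or non-finite length {L}")
    diffs = np.diff(lengths)
    for i in np.flatnonzero(diffs <= 0):
        violations.append(
            f"genes {i + 1} and {i + 2}: lengths not strictly increasing "
            f"({lengths[i]} >= {lengths[i + 1]})"
        )
    if genome.ploidy < 1:
        violations.append(f"ploidy must be >= 1, got {genome.ploidy}")
    return violations
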