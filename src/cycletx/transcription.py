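"""Complete-transcript counts per gene per cell cycle.

The model's central quantity: how many *complete* transcripts of a gene of
length ``L`` kb does a cell make in one cycle of duration ``gamma`` hours?
Polymerases elongate at ``rate`` kb/hr, and a new polymerase may initiate on
the same gene each time the previous one has transcribed ``reinit_spacing``
(Omega) kb, giving ``ceil(L / Omega)`` concurrent initiation "slots" (one in
serial mode). The polymerase occupying slot ``a`` starts ``a * Omega`` kb of
transcribed distance behind the lead polymerase, so over a cycle it delivers

    floor( max(0, gamma * rate - a * Omega) / L )

complete transcripts. Fractional progress is discarded: any transcript that
cannot finish within the cycle is eliminated, modelling M-phase degradation
of nascent transcripts. This flooring is what makes the cell cycle act as a
transcriptional filter — a gene is expressible at all iff
``L <= gamma * rate``.
"""

from __future__ import annotations

import math

import numpy as np

from .genome import Genome, TranscriptionParams

__all__ = [
    "polymerase_slots",
    "transcripts_per_gene",
    "max_complete_length",
    "transcribe",
    "apply_parental_retention",
]


def polymerase_slots(length: float, reinit_spacing: float, serial_mode: bool) -> int:
    """Number of concurrent polymerase initiation slots on a gene.

    Serial mode means a single polymerase that re-initiates only after
    completing a transcript: one slot. Otherwise every initiation point
    strictly inside the gene gets a slot: ``ceil(length / reinit_spacing)``.
    """
    if not length > 0:
        raise ValueError(f"gene length must be positive, got {length}")
    if not reinit_spacing > 0:
        raise ValueError(f"re-initiation spacing must be positive, got {reinit_spacing}")
    if serial_mode:
        return 1
    return math.ceil(length / reinit_spacing)


def transcripts_per_gene(
    gamma: float, params: TranscriptionParams, length: float
) -> int:
    """Complete transcripts of one gene copy in one cell cycle.

    Sums per-slot complete-transcript counts, flooring each slot separately
    (only whole transcripts count; a slot whose delayed start leaves it no
    time budget contributes zero).
    """
    if gamma < 0:
        raise ValueError(f"cell cycle duration must be >= 0, got {gamma}")
    n_slots = polymerase_slots(length, params.reinit_spacing, params.serial_mode)
    a = np.arange(n_slots)
    budget = np.maximum(0.0, gamma * params.rate - a * params.reinit_spacing)
    return int(np.floor(budget / length).sum())


def max_complete_length(gamma: float, rate: float) -> float:
    """Longest gene (kb) fully transcribable in one cycle: ``gamma * rate``.

    A gene yields at least one complete transcript iff its length does not
    exceed this threshold — the transcriptional filter cutoff.
    """
    if gamma < 0:
        raise ValueError(f"cell cycle duration must be >= 0, got {gamma}")
    if not rate > 0:
        raise ValueError(f"transcription rate must be positive, got {rate}")
    return gamma * rate


def transcribe(genome: Genome, gamma: float, params: TranscriptionParams) -> np.ndarray:
    """Deterministic transcriptome produced in one cycle of duration gamma.

    Returns the per-gene complete-transcript count vector (genome order),
    with ploidy multiplying every count (each genome copy transcribes
    identically and independently).
    """
    counts = np.array(
        [transcripts_per_gene(gamma, params, g.length) for g in genome.genes],
        dtype=np.int64,
    )
    return counts * genome.ploidy


def transcribe_lengths(
    lengths: np.ndarray, gamma: float, params: TranscriptionParams
) -> np.ndarray:
    """Vectorised :func:`transcripts_per_gene` over an array of gene lengths."""
    lengths = np.asarray(lengths, dtype=float)
    if params.serial_mode:
        return np.floor(gamma * params.rate / lengths).astype(np.int64)
    out = np.empty(lengths.shape, dtype=np.int64)
    for i, L in enumerate(lengths.ravel()):
        out.ravel()[i] = transcripts_per_gene(gamma, params, L)
    return out


def apply_parental_retention(
    inherited: np.ndarray, retention: float, rng: np.random.Generator
) -> np.ndarray:
    """Stochastic survival of inherited parental transcripts at division.

    Each inherited transcript survives independently with probability
    ``retention`` (binomial thinning per gene). The caller adds the
    survivors to the daughter's newly transcribed vector. ``retention=0``
    recovers the base model (all parental transcripts degraded).
    """
    if not 0.0 <= retention <= 1.0:
        raise ValueError(f"retention must be in [0, 1], got {retention}")
    inherited = np.asarray(inherited)
    if retention == 0.0:
        return np.zeros_like(inherited)
    if retention == 1.0:
        return inherited.copy()
    return rng.binomial(inherited, retention)
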