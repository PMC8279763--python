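"""Small canned configurations with machine-checkable expectations.

Each fixture bundles a :class:`RunConfig` (or construction recipe) with the
expected outcome a correct implementation must reproduce, so the test suite
and quick smoke checks share one registry. All fixtures are synthetic and
generated at run time; none reads external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable

import numpy as np

from .config import RunConfig

__all__ = ["Fixture", "generate_fixture", "FIXTURES", "planted_two_group_matrix"]


@dataclass(frozen=True)
class Fixture:
    name: str
    config: RunConfig
    expected: dict[str, Any]


def planted_two_group_matrix(
    n_per_group: int = 500, n_genes: int = 6, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Count matrix with two planted groups expressing disjoint gene sets.

    Group 0 expresses only the first half of the genes, group 1 only the
    second half; within a group every cell expresses its genes at one common
    level drawn per cell (so raw totals vary, but library-size normalisation
    collapses each group to a single point). Returns (matrix, true labels).
    Any sane clustering must recover exactly two clusters.
    """
    rng = np.random.default_rng(seed)
    half = n_genes // 2
    X = np.zeros((2 * n_per_group, n_genes), dtype=np.int64)
    levels = rng.integers(15, 26, size=2 * n_per_group)
    X[:n_per_group, :half] = levels[:n_per_group, None]
    X[n_per_group:, half:] = levels[n_per_group:, None]
    labels = np.repeat([0, 1], n_per_group)
    return X, labels


def _worked_example_three_genes() -> Fixture:
    cfg = RunConfig(
        genome_lengths=[1.0, 2.0, 3.0],
        ploidy=1,
        rate=1.0,
        serial_mode=True,
        gamma=3.0,
        divisions=0,
        seed=0,
    )
    return Fixture(
        "worked_example_three_genes",
        cfg,
        {"transcriptome": (3, 1, 1), "n_expressed_at_gamma_1": 1, "n_expressed": 3},
    )


def _fastfast_even_split() -> Fixture:
    cfg = RunConfig(
        genome_count=5,
        genome_min_len=1.0,
        genome_max_len=2.0,
        ploidy=1,
        gamma1=1.0,
        gamma2=1.0,
        scenario="fast_fast",
        founders=2,
        divisions=18,
        seed=0,
    )
    return Fixture(
        "fastfast_even_split",
        cfg,
        {"n_cells": 2**19, "proportions": {"fast": 0.5, "slow": 0.5}},
    )


def _asymmetric_stem_like() -> Fixture:
    cfg = RunConfig(
        genome_count=5,
        genome_min_len=1.0,
        genome_max_len=2.0,
        ploidy=1,
        gamma1=1.0,
        gamma2=2.0,
        scenario="slow_fast_asymmetric",
        rule_kind="asymmetric",
        founders=2,
        divisions=12,
        seed=0,
    )
    return Fixture(
        "asymmetric_stem_like",
        cfg,
        {"n_fast_cells_live": 1},
    )


def _gaussian_drift_small() -> Fixture:
    cfg = RunConfig(
        genome_count=10,
        genome_min_len=1.0,
        genome_max_len=10.0,
        ploidy=1,
        gamma=1.0,
        rule_kind="gaussian_increment",
        delta_mean=0.1,
        sigma=0.06,
        divisions=8,
        iterations=10,
        seed=0,
    )
    return Fixture(
        "gaussian_drift_small",
        cfg,
        {"fastest_class_proportion_trend": "decreasing"},
    )


def _planted_two_clusters() -> Fixture:
    cfg = RunConfig(
        genome_lengths=[1, 2, 3, 4, 5, 6],
        gamma=6.0,
        divisions=0,
        seed=0,
    )
    return Fixture("planted_two_clusters", cfg, {"n_clusters": 2})


_REGISTRY: dict[str, Callable[[], Fixture]] = {
    "worked_example_three_genes": _worked_example_three_genes,
    "fastfast_even_split": _fastfast_even_split,
    "asymmetric_stem_like": _asymmetric_stem_like,
    "gaussian_drift_small": _gaussian_drift_small,
    "planted_two_clusters": _planted_two_clusters,
}

FIXTURES = tuple(_REGISTRY)


def generate_fixture(name: str) -> Fixture:
    """Return the named canned config + expectations; raises on unknown names."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; known: {sorted(_REGISTRY)}") from None
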