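"""Agent-based cell lineage engine.

Cells transcribe for one cell cycle, divide, and hand their transcripts to
two progeny; the full lineage is tracked so population proportions and
per-lineage diversity can be reconstructed at any time point.

Transcript bookkeeping
----------------------
A cell's recorded transcriptome is the share of transcripts it receives at
birth, when the parental pool is partitioned (each transcript independently
assigned to one daughter with probability 1/2 — the model's sole stochastic
core mechanism). At a cell's own division, the divisible pool is the set of
transcripts it produced during the cycle just completed, plus whatever
fraction of its inherited share survived (``parental_retention``; 0 in the
base model, where transcription begins anew each cycle and inherited
transcripts are fully turned over). Founders start with an empty
transcriptome unless given one explicitly (e.g. a maternal deposit).

Cycle-duration inheritance is controlled by a :class:`CycleRule`:
``constant``/``inherit`` copy the parent's duration, ``gaussian_increment``
draws each daughter's duration from a normal around the parent's plus a
drift term, and ``asymmetric`` splits a fast cell into one fast and one
slow daughter (stem-cell-like), slow cells breeding true.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genome import Genome, TranscriptionParams
from .transcription import (
    apply_parental_retention,
    transcribe,
    transcribe_lengths,
)

__all__ = [
    "Cell",
    "CycleRule",
    "Population",
    "partition_transcripts",
    "divide",
    "run_synchronous",
    "run_asynchronous",
    "run_mixed_lineage_scenario",
    "proportions_over_time",
]

RuleKind = Literal["constant", "inherit", "gaussian_increment", "asymmetric"]


@dataclass
class Cell:
    """One cell: identity, cycle state, transcriptome, and lineage bookkeeping."""

    cell_id: int
    parent_id: int | None
    generation: int
    gamma: float
    birth_time: float
    transcriptome: np.ndarray
    lineage_label: str = "founder"
    phase_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"cell cycle duration must be positive, got {self.gamma}")
        if self.generation < 0:
            raise ValueError("generation must be >= 0")
        self.transcriptome = np.asarray(self.transcriptome, dtype=np.int64)

    @property
    def n_divisions(self) -> int:
        """Divisions in this cell's ancestry (equals its generation)."""
        return self.generation


@dataclass(frozen=True)
class CycleRule:
    """How daughters' cycle durations relate to the parent's.

    kind
        ``constant`` / ``inherit``: daughters copy the parent's duration.
        ``gaussian_increment``: each daughter draws
        Normal(parent + delta_mean, sigma), truncated below at gamma_min.
        ``asymmetric``: a fast cell (duration == fast_gamma) yields one fast
        and one slow daughter; slow cells yield two slow daughters.
    delta_mean, sigma
        Mean drift (hr/generation) and standard deviation (hr) of the
        Gaussian increment.
    fast_gamma, slow_gamma
        Target durations (hr) for the asymmetric split; fast_gamma <= slow_gamma.
    gamma_min
        Truncation floor (hr) for Gaussian draws. If None, the engine uses
        the transcription time of the genome's shortest gene.
    """

    kind: RuleKind = "inherit"
    delta_mean: float = 0.1
    sigma: float = 0.06
    fast_gamma: float | None = None
    slow_gamma: float | None = None
    gamma_min: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "inherit", "gaussian_increment", "asymmetric"):
            raise ValueError(f"unknown cycle rule kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.gamma_min is not None and not self.gamma_min > 0:
            raise ValueError("gamma_min must be positive")
        if self.kind == "asymmetric":
            if self.fast_gamma is None or self.slow_gamma is None:
                raise ValueError("asymmetric rule requires fast_gamma and slow_gamma")
            if self.fast_gamma > self.slow_gamma:
                raise ValueError("asymmetric rule requires fast_gamma <= slow_gamma")


def partition_transcripts(
    parent: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly split a transcript pool between two daughters.

    Each transcript is independently assigned to daughter 1 or daughter 2
    with probability 1/2; per-gene counts are conserved exactly
    (child1 + child2 == parent).
    """
    parent = np.asarray(parent, dtype=np.int64)
    child1 = rng.binomial(parent, 0.5)
    return child1, parent - child1


def _default_gamma_min(rule: CycleRule, genome: Genome, params: TranscriptionParams) -> float:
    if rule.gamma_min is not None:
        return rule.gamma_min
    return float(genome.lengths.min()) / params.rate


def _child_gammas(
    rule: CycleRule,
    parent_gamma: float,
    gamma_min: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    if rule.kind in ("constant", "inherit"):
        return parent_gamma, parent_gamma
    if rule.kind == "gaussian_increment":
        draws = rng.normal(parent_gamma + rule.delta_mean, rule.sigma, size=2)
        draws = np.maximum(draws, gamma_min)
        return float(draws[0]), float(draws[1])
    # asymmetric: fast cells split fast/slow, slow cells breed true
    assert rule.fast_gamma is not None and rule.slow_gamma is not None
    if parent_gamma <= rule.fast_gamma:
        return rule.fast_gamma, rule.slow_gamma
    return rule.slow_gamma, rule.slow_gamma


def divide(
    cell: Cell,
    genome: Genome,
    params: TranscriptionParams,
    rule: CycleRule,
    rng: np.random.Generator,
    *,
    id_start: int | None = None,
) -> tuple[Cell, Cell]:
    """Divide a cell whose cycle has completed into two daughters.

    The divisible pool is the cell's new transcription for the completed
    cycle plus the retention-surviving part of its inherited share; the pool
    is partitioned uniformly at random between the daughters.
    """
    if cell.phase_time < cell.gamma:
        raise RuntimeError(
            f"cell {cell.cell_id} cannot divide: phase_time {cell.phase_time} "
            f"< cycle duration {cell.gamma}"
        )
    retained = apply_parental_retention(
        cell.transcriptome, params.parental_retention, rng
    )
    pool = retained + transcribe(genome, cell.gamma, params)
    share1, share2 = partition_transcripts(pool, rng)
    gamma_min = _default_gamma_min(rule, genome, params)
    g1, g2 = _child_gammas(rule, cell.gamma, gamma_min, rng)
    base = cell.cell_id * 2 + 1 if id_start is None else id_start
    t = cell.birth_time + cell.gamma
    c1 = Cell(base, cell.cell_id, cell.generation + 1, g1, t, share1, cell.lineage_label)
    c2 = Cell(base + 1, cell.cell_id, cell.generation + 1, g2, t, share2, cell.lineage_label)
    return c1, c2


class Population:
    """All cells ever created in a simulation, plus live-cell transcriptomes.

    Per-cell records (``cell_id``, ``parent_id``, ``generation``,
    ``lineage_label``, ``gamma``, ``birth_time``, ``division_time``) are
    stored as parallel arrays over every cell that ever existed; a cell with
    ``division_time`` NaN is a live leaf. ``counts`` holds the transcriptome
    (birth share) of each live cell, rows aligned with ``live_ids``.
    """

    def __init__(
        self,
        genome: Genome,
        params: TranscriptionParams,
        *,
        cell_id: np.ndarray,
        parent_id: np.ndarray,
        generation: np.ndarray,
        gamma: np.ndarray,
        birth_time: np.ndarray,
        division_time: np.ndarray,
        label: np.ndarray,
        live_ids: np.ndarray,
        counts: np.ndarray | None,
        clock: float,
    ) -> None:
        self.genome = genome
        self.params = params
        self.cell_id = cell_id
        self.parent_id = parent_id
        self.generation = generation
        self.gamma = gamma
        self.birth_time = birth_time
        self.division_time = division_time
        self.label = label
        self.live_ids = live_ids
        self.counts = counts
        self.clock = clock

    # -- sizes ---------------------------------------------------------------
    @property
    def n_total(self) -> int:
        return len(self.cell_id)

    @property
    def n_live(self) -> int:
        return len(self.live_ids)

    # -- views ---------------------------------------------------------------
    def to_lineage_frame(self) -> pd.DataFrame:
        """One row per cell ever created (the lineage log)."""
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "parent_id": self.parent_id,
                "generation": self.generation,
                "lineage_label": self.label,
                "gamma_hr": self.gamma,
                "birth_time_hr": self.birth_time,
                "division_time_hr": self.division_time,
                "n_divisions": self.generation,
            }
        )

    def live_frame(self) -> pd.DataFrame:
        """Metadata for live cells, row order matching ``counts``."""
        idx = np.searchsorted(self.cell_id, self.live_ids)
        return pd.DataFrame(
            {
                "cell_id": self.live_ids,
                "lineage_label": self.label[idx],
                "gamma_hr": self.gamma[idx],
                "generation": self.generation[idx],
                "birth_time_hr": self.birth_time[idx],
            }
        )

    def division_log(self) -> pd.DataFrame:
        """Append-only division event log: parent, children, time."""
        divided = ~np.isnan(self.division_time)
        parents = self.cell_id[divided]
        order = np.argsort(self.division_time[divided], kind="stable")
        rows = []
        children_of: dict[int, list[int]] = {}
        for cid, pid in zip(self.cell_id, self.parent_id):
            if pid >= 0:
                children_of.setdefault(int(pid), []).append(int(cid))
        for i in order:
            p = int(parents[i])
            kids = children_of.get(p, [])
            rows.append(
                {
                    "parent_id": p,
                    "child1_id": kids[0] if kids else None,
                    "child2_id": kids[1] if len(kids) > 1 else None,
                    "time_hr": self.division_time[divided][i],
                }
            )
        return pd.DataFrame(rows)

    def lineage_summary(self) -> pd.DataFrame:
        """Per-lineage-label live cell count, proportion, and diversity."""
        live = self.live_frame()
        rows = []
        for lab, grp in live.groupby("lineage_label", sort=True):
            row = {
                "lineage_label": lab,
                "n_cells": len(grp),
                "proportion": len(grp) / len(live),
            }
            if self.counts is not None:
                mask = (live["lineage_label"] == lab).to_numpy()
                row["transcriptome_diversity"] = int(
                    np.unique(self.counts[mask], axis=0).shape[0]
                )
            rows.append(row)
        return pd.DataFrame(rows)


def _founder(
    genome: Genome,
    gamma: float,
    label: str,
    cell_id: int,
    transcriptome: np.ndarray | None = None,
) -> Cell:
    tx = (
        np.zeros(genome.n_genes, dtype=np.int64)
        if transcriptome is None
        else np.asarray(transcriptome, dtype=np.int64)
    )
    return Cell(cell_id, None, 0, gamma, 0.0, tx, label)


def make_founders(
    genome: Genome,
    gammas: Sequence[float],
    labels: Sequence[str] | None = None,
) -> list[Cell]:
    """Convenience constructor for generation-0 cells with empty transcriptomes."""
    if labels is None:
        labels = [f"lineage_{i + 1}" for i in range(len(gammas))]
    return [_founder(genome, g, lab, i) for i, (g, lab) in enumerate(zip(gammas, labels))]


def run_synchronous(
    genome: Genome,
    params: TranscriptionParams,
    founders: Sequence[Cell],
    rule: CycleRule,
    divisions: int,
    rng: np.random.Generator,
    *,
    compute_transcriptomes: bool = True,
) -> Population:
    """Run a fixed number of synchronous division rounds for every live cell.

    All founders must share one cycle duration (use :func:`run_asynchronous`
    otherwise); every cohort divides together, so with a symmetric rule the
    final population holds ``len(founders) * 2**divisions`` cells. The heavy
    steps (new transcription, binomial partitioning) are vectorised over the
    whole cohort, so half-million-cell runs complete in seconds.

    ``compute_transcriptomes=False`` skips all transcript bookkeeping
    (count-only mode for large census runs).
    """
    if divisions < 0:
        raise ValueError(f"divisions must be >= 0, got {divisions}")
    gammas0 = {c.gamma for c in founders}
    if len(gammas0) > 1:
        raise ValueError(
            "run_synchronous requires founders with a common cycle duration; "
            "use run_asynchronous for mixed-gamma populations"
        )
    G = genome.n_genes
    gamma_min = _default_gamma_min(rule, genome, params)
    lengths = genome.lengths

    # cohort state
    n0 = len(founders)
    ids = np.array([c.cell_id for c in founders], dtype=np.int64)
    gam = np.array([c.gamma for c in founders], dtype=float)
    lab = np.array([c.lineage_label for c in founders], dtype=object)
    gen = np.array([c.generation for c in founders], dtype=np.int64)
    birth = np.array([c.birth_time for c in founders], dtype=float)
    X = np.stack([c.transcriptome for c in founders]).astype(np.int64)

    all_id = [ids]
    all_parent = [np.array([c.parent_id if c.parent_id is not None else -1 for c in founders], dtype=np.int64)]
    all_gen = [gen]
    all_gamma = [gam]
    all_birth = [birth]
    all_div = []  # division times, filled per cohort once it divides
    all_lab = [lab]

    next_id = int(ids.max()) + 1 if n0 else 0
    clock = 0.0
    for _ in range(divisions):
        n = len(ids)
        div_time = birth + gam
        clock = float(div_time.max())
        if compute_transcriptomes:
            # divisible pool = retained inherited share + new transcription
            retained = apply_parental_retention(X, params.parental_retention, rng)
            new = np.zeros((n, G), dtype=np.int64)
            for g in np.unique(gam):
                new[gam == g] = transcribe_lengths(lengths, float(g), params) * genome.ploidy
            pool = retained + new
            c1 = rng.binomial(pool, 0.5)
            c2 = pool - c1
            X = np.concatenate([c1, c2])
        child_gam = _child_gammas_vec(rule, gam, gamma_min, rng)
        child_ids = np.arange(next_id, next_id + 2 * n, dtype=np.int64)
        next_id += 2 * n
        all_div.append(div_time)
        all_id.append(child_ids)
        all_parent.append(np.concatenate([ids, ids]))
        gen = np.concatenate([gen + 1, gen + 1])
        all_gen.append(gen)
        all_gamma.append(np.concatenate([child_gam[0], child_gam[1]]))
        all_birth.append(np.concatenate([div_time, div_time]))
        all_lab.append(np.concatenate([lab, lab]))
        ids = child_ids
        gam = np.concatenate([child_gam[0], child_gam[1]])
        lab = np.concatenate([lab, lab])
        birth = np.concatenate([div_time, div_time])

    n_total = sum(len(a) for a in all_id)
    division_time = np.full(n_total, np.nan)
    filled = 0
    for i, dt in enumerate(all_div):
        division_time[filled : filled + len(dt)] = dt
        filled += len(dt)
    return Population(
        genome,
        params,
        cell_id=np.concatenate(all_id),
        parent_id=np.concatenate(all_parent),
        generation=np.concatenate(all_gen),
        gamma=np.concatenate(all_gamma),
        birth_time=np.concatenate(all_birth),
        division_time=division_time,
        label=np.concatenate(all_lab),
        live_ids=ids,
        counts=X if compute_transcriptomes else None,
        clock=clock,
    )


def _child_gammas_vec(
    rule: CycleRule,
    gam: np.ndarray,
    gamma_min: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    if rule.kind in ("constant", "inherit"):
        return gam.copy(), gam.copy()
    if rule.kind == "gaussian_increment":
        g1 = np.maximum(rng.normal(gam + rule.delta_mean, rule.sigma), gamma_min)
        g2 = np.maximum(rng.normal(gam + rule.delta_mean, rule.sigma), gamma_min)
        return g1, g2
    assert rule.fast_gamma is not None and rule.slow_gamma is not None
    fast = gam <= rule.fast_gamma
    g1 = np.where(fast, rule.fast_gamma, rule.slow_gamma)
    g2 = np.full_like(gam, rule.slow_gamma)
    return g1, g2


def run_asynchronous(
    genome: Genome,
    params: TranscriptionParams,
    founders: Sequence[Cell],
    rule: CycleRule,
    total_time: float,
    rng: np.random.Generator,
    *,
    stepping: Literal["event", "min_gamma"] = "event",
) -> Population:
    """Run the population for a fixed wall-clock time with per-cell schedules.

    Each cell divides exactly when its in-cycle time reaches its own cycle
    duration, so a constant-duration lineage registers ``floor(t / gamma)``
    division rounds in time ``t``. The default engine is event-driven (a
    priority queue on next-division times); ``stepping="min_gamma"``
    processes the same events in windows whose width is the shortest cycle
    duration among live cells, mirroring a literal minimum-duration
    time-stepping scheme, and yields identical populations.
    """
    if total_time < 0:
        raise ValueError(f"total_time must be >= 0, got {total_time}")
    if stepping not in ("event", "min_gamma"):
        raise ValueError(f"unknown stepping mode {stepping!r}")
    eps = 1e-9
    counter = itertools.count()

    # heap entries: (next_division_time, tiebreak, cell)
    heap: list[tuple[float, int, Cell]] = []
    next_id = max((c.cell_id for c in founders), default=-1) + 1
    for c in founders:
        heapq.heappush(heap, (c.birth_time + c.gamma, next(counter), c))

    records: list[Cell] = list(founders)
    division_times: dict[int, float] = {}
    live: list[Cell] = []

    def step(cell: Cell, t_div: float) -> None:
        nonlocal next_id
        cell.phase_time = cell.gamma
        c1, c2 = divide(cell, genome, params, rule, rng, id_start=next_id)
        next_id += 2
        division_times[cell.cell_id] = t_div
        records.extend([c1, c2])
        heapq.heappush(heap, (c1.birth_time + c1.gamma, next(counter), c1))
        heapq.heappush(heap, (c2.birth_time + c2.gamma, next(counter), c2))

    if stepping == "event":
        while heap:
            t_div, _, cell = heapq.heappop(heap)
            if t_div > total_time + eps:
                live.append(cell)
                continue
            step(cell, t_div)
    else:
        # literal minimum-duration time stepping: advance the global clock in
        # windows equal to the shortest cycle duration among live cells,
        # settling every division that falls inside each window in time order
        clock = 0.0
        while heap and clock < total_time - eps:
            window = min(c.gamma for _, _, c in heap)
            t_end = min(clock + window, total_time)
            while heap and heap[0][0] <= t_end + eps:
                t_div, _, cell = heapq.heappop(heap)
                step(cell, t_div)
            clock = t_end
        while heap:
            live.append(heapq.heappop(heap)[2])

    return _population_from_cells(
        genome, params, records, division_times, live, clock=total_time
    )


def _population_from_cells(
    genome: Genome,
    params: TranscriptionParams,
    records: list[Cell],
    division_times: dict[int, float],
    live: list[Cell],
    clock: float,
) -> Population:
    records = sorted(records, key=lambda c: c.cell_id)
    cell_id = np.array([c.cell_id for c in records], dtype=np.int64)
    live_sorted = sorted(live, key=lambda c: c.cell_id)
    return Population(
        genome,
        params,
        cell_id=cell_id,
        parent_id=np.array(
            [c.parent_id if c.parent_id is not None else -1 for c in records],
            dtype=np.int64,
        ),
        generation=np.array([c.generation for c in records], dtype=np.int64),
        gamma=np.array([c.gamma for c in records], dtype=float),
        birth_time=np.array([c.birth_time for c in records], dtype=float),
        division_time=np.array(
            [division_times.get(c.cell_id, np.nan) for c in records], dtype=float
        ),
        label=np.array([c.lineage_label for c in records], dtype=object),
        live_ids=np.array([c.cell_id for c in live_sorted], dtype=np.int64),
        counts=np.stack([c.transcriptome for c in live_sorted])
        if live_sorted
        else None,
        clock=clock,
    )


def sample_one_division(
    genome: Genome,
    gamma: float,
    params: TranscriptionParams,
    replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Daughter transcriptomes from many replicate single-division runs.

    Each replicate starts one founder with cycle duration ``gamma``, lets it
    transcribe once, and partitions the output between two daughters;
    returns the ``2 * replicates`` x genes daughter count matrix. This is
    the sampling scheme behind population-level summaries of a single
    division step (length-bin expression profiles, diversity censuses,
    cluster counts), vectorised across replicates.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    parent = transcribe(genome, gamma, params)
    pool = np.broadcast_to(parent, (replicates, genome.n_genes))
    c1 = rng.binomial(pool, 0.5)
    c2 = pool - c1
    out = np.empty((2 * replicates, genome.n_genes), dtype=np.int64)
    out[0::2] = c1
    out[1::2] = c2
    return out


SCENARIOS = ("fast_fast", "slow_fast_heritable", "slow_fast_asymmetric")


def run_mixed_lineage_scenario(
    scenario: str,
    gamma1: float,
    gamma2: float,
    genome: Genome,
    params: TranscriptionParams,
    divisions: int,
    rng: np.random.Generator,
    *,
    compute_transcriptomes: bool = True,
) -> tuple[Population, pd.DataFrame]:
    """Two-founder lineage competition scenarios.

    ``fast_fast``
        Both founders share one cycle duration and divide synchronously for
        the given number of rounds (gamma1 must equal gamma2); proportions
        end 50:50.
    ``slow_fast_heritable``
        Founder 1 is fast (gamma1), founder 2 slow (gamma2 >= gamma1);
        daughters inherit the parental duration. Run asynchronously for
        ``divisions * gamma1`` hours so the fast lineage registers
        ``divisions`` rounds; the slow lineage falls behind in cell number
        but ahead in per-cell diversity.
    ``slow_fast_asymmetric``
        As above, but fast cells divide asymmetrically into one fast and one
        slow daughter, so exactly one cell per founding fast cell ever holds
        the fast duration, while continuously seeding the slow pool.

    Returns the population and a per-lineage summary (cell count,
    proportion, transcriptome diversity).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if gamma1 > gamma2:
        raise ValueError("gamma1 must be <= gamma2")
    founders = make_founders(genome, [gamma1, gamma2], ["fast", "slow"])
    if scenario == "fast_fast":
        if gamma1 != gamma2:
            raise ValueError("fast_fast scenario requires gamma1 == gamma2")
        pop = run_synchronous(
            genome,
            params,
            founders,
            CycleRule("inherit"),
            divisions,
            rng,
            compute_transcriptomes=compute_transcriptomes,
        )
    elif scenario == "slow_fast_heritable":
        pop = run_asynchronous(
            genome, params, founders, CycleRule("inherit"), divisions * gamma1, rng
        )
    else:
        rule = CycleRule("asymmetric", fast_gamma=gamma1, slow_gamma=gamma2)
        pop = run_asynchronous(genome, params, founders, rule, divisions * gamma1, rng)
        # under asymmetric division the fast/slow classes are defined by the
        # cycle duration a cell holds, not by its founding lineage
        pop.label = np.where(pop.gamma <= gamma1, "fast", "slow").astype(object)
    return pop, pop.lineage_summary()


def proportions_over_time(
    population: Population,
    *,
    by: Literal["generation", "time"] = "generation",
    class_by: Literal["label", "gamma"] = "label",
    bin_edges: Sequence[float] | None = None,
    n_points: int = 20,
) -> pd.DataFrame:
    """Lineage (or cycle-duration-class) proportions across the simulation.

    The Muller-plot table: one row per (time point or generation) x class,
    with cell counts and proportions summing to one across classes at each
    point. ``class_by="gamma"`` bins cells by cycle duration using
    ``bin_edges`` (defaults to quartiles of observed durations), which is the
    natural classing for Gaussian-drift runs.
    """
    gamma = population.gamma
    if class_by == "label":
        classes = population.label.astype(str)
    else:
        if bin_edges is None:
            qs = np.quantile(np.unique(gamma), [0.25, 0.5, 0.75])
            bin_edges = list(np.unique(qs))
        idx = np.digitize(gamma, bin_edges)
        edges = [-np.inf, *bin_edges, np.inf]
        classes = np.array(
            [f"gamma[{edges[i]:g},{edges[i + 1]:g})" for i in idx], dtype=object
        )

    rows = []
    if by == "generation":
        for g in np.unique(population.generation):
            mask = population.generation == g
            labs, counts = np.unique(classes[mask], return_counts=True)
            total = counts.sum()
            for lab, cnt in zip(labs, counts):
                rows.append(
                    {"generation": int(g), "class": lab, "n_cells": int(cnt),
                     "proportion": cnt / total}
                )
    else:
        eps = 1e-9
        end = population.clock
        times = np.linspace(0.0, end, n_points)
        birth = population.birth_time
        death = np.where(
            np.isnan(population.division_time), np.inf, population.division_time
        )
        for t in times:
            alive = (birth <= t + eps) & (death > t + eps)
            if not alive.any():
                continue
            labs, counts = np.unique(classes[alive], return_counts=True)
            total = counts.sum()
            for lab, cnt in zip(labs, counts):
                rows.append(
                    {"time_hr": float(t), "class": lab, "n_cells": int(cnt),
                     "proportion": cnt / total}
                )
    return pd.DataFrame(rows)
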