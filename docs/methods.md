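# Methods

## Model

A cell is an agent holding a cycle duration Γ (hr), a transcript-count
vector over a fixed genome, and lineage bookkeeping. The genome is an
ordered list of gene lengths *L₁ < L₂ < … < L_G* (kb) with ploidy *n*;
transcription time is proportional to length at a common polymerase rate
λ (kb/hr). Re-initiation every Ω kb gives gene *i* ⌈*Lᵢ*/Ω⌉ concurrent
initiation slots; the slot delayed by *a*·Ω of transcribed distance
completes ⌊max(0, Γλ − aΩ)/*Lᵢ*⌋ transcripts per cycle. Only complete
transcripts count: per-slot flooring implements M-phase degradation of
nascent transcripts, and it is what makes the cycle a filter — gene *i* is
expressible at all iff *Lᵢ* ≤ Γλ. Serial mode (one polymerase, re-initiation
only after completion) is an explicit flag rather than a large-Ω limit, so
the single-polymerase worked example is unambiguous. Ploidy multiplies
counts deterministically (*n* identical genome copies). Splicing,
translation, gene–gene regulation, elongation-rate variation within a gene,
cell death and extracellular signalling are all outside the model.

Two stated formula ambiguities were resolved as follows. The per-slot sum
is dimensionally consistent only in its length-divided form (budget divided
by *Lᵢ*), which also reproduces the three-transcript worked example; we use
that form. The slot count for *L* not divisible by Ω is ⌈*L*/Ω⌉ — every
initiation point strictly inside the gene gets a slot — since the exact
quotient is undefined otherwise.

## Transcript bookkeeping across divisions

A cell's recorded transcriptome is the share it receives at birth when the
parental pool is partitioned (each transcript to a uniform-random daughter,
independently; counts conserved exactly per gene). At the cell's own
division, the divisible pool is its new transcription for the completed
cycle plus the surviving part of its inherited share: each inherited
transcript survives a division with probability `parental_retention`
(binomial thinning; 0 in the base model, where transcription begins anew
each cycle). Retention is stochastic per transcript rather than a
deterministic truncation so counts stay integral and decay is noisy.
Cells with empty transcriptomes are legal, persistent states. We note the
literal "all transcripts to one daughter" probability for *N* transcripts
is 2·(½)^*N* under this rule; the partition rule is implemented exactly as
independent uniform assignment.

## Diversity

Distinct daughter transcriptomes reachable from one parent:
*n*·Π(*Nᵢ*+1), with *Nᵢ* the integer per-gene complete-transcript count
(the formula's length-normalised transcribed budget realised as an
integer, matching how counting distinct integer vectors must work). An
exhaustive enumeration oracle (Cartesian product of per-gene ranges,
capped at 10⁵ states by default) validates the closed form; the test grid
covers all genomes of up to three genes with lengths ≤ 4 kb, both
transcription modes, Γ = 0 … 5 hr in half-hour steps. Ploidy enters as the
printed leading factor; the pooled-copy alternative Π(*n·Nᵢ*+1) is exposed
as `ploidy_variant="per_gene"` for sensitivity analysis but is not the
default. Empirical diversity is an exact distinct-row count (integer
equality, no tolerance).

## Lineage engines

*Synchronous*: every live cell divides each round; state is held in
per-cohort numpy arrays and new transcription, retention thinning and
binomial partitioning are vectorised over the cohort, so two founders over
18 rounds (524,288 final cells, five genes, transcriptomes throughout) run
in a few seconds. *Asynchronous*: event-driven on a priority queue of
next-division times, so each cell divides exactly when its in-cycle time
reaches its own Γ and a constant-Γ lineage registers ⌊t/Γ⌋ rounds in time
t; divisions falling exactly at the horizon are counted. A literal
minimum-duration time-stepping mode (`stepping="min_gamma"`) processes the
same schedule in windows equal to the shortest live cycle duration and is
asserted by test to produce bit-identical populations; the event queue is
the default because fixed-window stepping mis-times divisions when cycle
durations are incommensurable.

Cycle-duration rules: `constant`/`inherit` copy the parent's Γ;
`gaussian_increment` draws each daughter's Γ from
Normal(Γ_parent + δ, σ), truncated below at `gamma_min` (default: the
transcription time of the shortest gene) since negative or near-zero draws
are otherwise possible; `asymmetric` splits a fast cell into one fast and
one slow daughter while slow cells breed true, which pins the fast class at
one cell per founding fast cell. The drift increment δ defaults to 0.1 hr
with σ = 0.06 hr; both are free parameters (the magnitude of a "gradual"
per-generation lengthening is not pinned down by any single observation,
and sweeps over δ are supported). In the two-founder competition scenarios
the fast/slow classes are labelled by founding lineage, except under
asymmetric division where class follows the cycle duration a cell holds.

## Single-cell pipeline

Counts are scaled per cell to a common library size (10⁴), log(1+x)
transformed, and z-scored per gene (all-zero cells pass through; constant
genes become zero columns). PCA uses the full SVD solver with *G* − 1
components by default (the maximum informative dimensionality at tiny gene
counts); the embedding is produced by fitting then projecting, a row-wise
map, so identical cells land on bit-identical coordinates. With ≤ 10 genes
variable-feature selection is vacuous and all genes are used. The SNN graph
takes k = 20 nearest neighbours (self included), weights each kNN edge by
the Jaccard overlap of the endpoint neighbourhoods, and prunes weights
below 1/15; k and the prune threshold mirror the defaults of the standard
single-cell workflow rather than being derived quantities. Louvain
modularity optimisation at resolution 1 under a fixed seed gives labels
(Leiden available as an option). Finally, all cells with identical input
rows are reassigned the modal label of their duplicate set; simulated
matrices are dominated by exact duplicates, and this guarantees the cluster
count never exceeds the number of distinct transcriptomes. Exact cluster
counts are sensitive to k and pruning and are not meaningful point
estimates; the robust, tested property is the trend — few clusters at short
Γ (homogeneous, heavily filtered cells), a maximum at intermediate Γ, fewer
again at long Γ (all genes expressed similarly by everyone).

## Synthetic data and what passing tests show

All inputs are generated by the package itself: uniform-length genomes,
replicate single-division samples (`sample_one_division`), lineage
scenarios, and a planted two-group matrix whose groups express disjoint
gene sets at a per-cell common level (so library-size normalisation
collapses each group to a point — a construction with a known answer of
exactly two clusters). The generator emulates count matrices, extreme
transcriptome duplication, and empty cells, but not sequencing depth
variation, capture noise, dropout, batch effects, or biological gene-length
distributions; tests passing here demonstrate internal correctness of the
model and pipeline, not fidelity to any real dataset.

## Problem sizes and numerical choices

Test and acceptance runs use 10,000-replicate single-division samples
(20,000 cells) for binning, 5,000 replicates (10,000 cells) per Γ over
three seeds for clustering, 18-round synchronous censuses, and 10⁵-trial
Monte Carlo checks of the partition law (asserted at three standard
errors). Division-time comparisons use a 10⁻⁹ hr tolerance; the
discrete-event transcription oracle uses 10⁻¹² on completion times.
Stochastic assertions are seeded; every simulation takes an explicit
`numpy.random.Generator` and identical seeds give bit-identical
populations.

## Known limitations

Cycle sub-phases (G1/S/G2/M) are not distinguished — Γ is a single
transcription budget. The asynchronous engine holds Python-level cell
objects and is comfortable to ~10⁵ cells; only the synchronous engine is
vectorised for larger censuses. Cluster counts depend on neighbour-graph
parameters that are conventions, not measurements. The analytic diversity
formula counts reachable daughter states of a single division; iterated
multi-generation populations can realise fewer states than repeated
application of the formula would suggest because shares are coupled by
conservation.
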