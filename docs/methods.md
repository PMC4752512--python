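# Methods

This note documents the models behind `grnctx`, the choices made where the
procedure was genuinely open, and what the synthetic-data tests do and do not
establish about real data.

## Binding-site scanning

A PWM is a positions × {A,C,G,T} frequency matrix.  Scoring weights each
position by its information content

    I(i) = Σ_b f(i,b) · ln(4 f(i,b)),   0·ln 0 := 0,

i.e. ln 4 minus the position's Shannon entropy: 0 for a uniform position,
ln 4 for a fully conserved one.  A window s of motif length scores

    MSS = (Current − Min) / (Max − Min),
    Current = Σ_i I(i) f(i, s_i),

with Min/Max the analogous sums over per-position minimum/maximum
frequencies; CSS is the same quantity restricted to the *core*, the 5
consecutive positions with maximal summed information (leftmost on ties — a
deterministic convention; 5 is the conventional core width).  When
Max = Min over a span (an entirely uniform matrix) the score is defined as
1.0: every window matches an uninformative motif equally and maximally.
Scores are clipped to [0, 1].

Numerical choices: no pseudocounts are added at scan time — zero frequencies
are legal because scoring uses frequencies, not log-odds.  Both strands are
scanned by default; minus-strand hits are mapped back to forward
window-start coordinates (offset' = L_seq − offset − L_motif).  Windows
containing non-ACGT characters are skipped (logged at debug level).
Overlapping hits are all reported; network construction collapses every
(TF, gene) hit set to a single unsigned directed edge, so masking would
change nothing downstream.  Coordinates are 0-based half-open relative to
the window start; the default window is 2000 bp upstream and 1000 bp
downstream of the TSS.  The retention rule is the dual threshold
CSS ≥ 0.90 AND MSS ≥ 0.90; both thresholds are configurable, and a single
global pair is used rather than per-matrix profiles (per-matrix threshold
profiles belong to proprietary motif libraries and are not modelled).

## Network representation and merging

Edges are identified by the ordered (source, target) pair and carry a sign
in {+, −, ?} and a provenance set ⊆ {tfbs, literature}.  One edge per pair:
the contextualization genome is per-edge, and duplicated pairs would
double-count.  The merge is a union on edge keys; on a shared key a known
sign beats `?` and provenances union.  Two *different known* signs for the
same pair are treated as an input error rather than silently resolved —
nothing in the merged evidence justifies preferring one.  With that rule the
merge is commutative and associative, and |E_merged| = |E₁| + |E₂| − |shared
keys|.  Self-loops are dropped with a warning: under the fixed-point
semantics below a positive self-loop is trivially self-justifying.

## Differential expression and booleanization

Expression is a gene × sample matrix of log2 intensities with ≥ 2 replicates
per condition.  logFC = mean(stimulated) − mean(control); significance is a
two-sided equal-variance two-sample t-test.  A gene is called *up* iff
logFC ≥ +1 and p < 0.01, *down* iff logFC ≤ −1 and p < 0.01 — bounds closed
on logFC and open on p, exactly as stated.  No multiple-testing correction
is applied by default (the calling rule is a raw p cut); Benjamini–Hochberg
is available as an option.  Zero pooled variance leaves the t statistic
undefined; the edge rule is p := 0 when the means differ and p := 1 when
equal.  Probe-level moderation pipelines are deliberately not reimplemented:
the contextualization stage consumes only the binary calls, and a plain
t-test on gene-level values is sufficient for that interface.  An optional
pre-step collapses redundant probes to genes by the mean.

Booleanization is symmetric so that every DEG constrains both attractors:
up → (control 0, stimulated 1), down → (control 1, stimulated 0), unchanged
or absent → unconstrained in both.  Leaving unchanged genes unconstrained is
the weaker of the two defensible readings (the stricter one would pin them
to equal states across conditions); it was chosen because an "unchanged"
call is an absence of evidence, not evidence of a fixed state.  The stimulus
is an input, clamped 0/1, and may not appear among the DEGs.

## Boolean semantics and contextualization

Update rule (synchronous): a node becomes 1 iff at least one activator is 1
and no inhibitor is 1; a node with no regulators holds its state; inputs
stay clamped.  This is the simplest sign-respecting semantics and is the
normative contract here.  Phenotypes are required to be *fixed points* —
stable steady states — not general cyclic attractors; cyclic attractor
support is out of scope.

Checking whether a constrained partial state extends to a fixed point means
searching assignments of the unconstrained ("free") nodes.  The search is
exhaustive and fully vectorized up to 12 free nodes (4096 candidate states
evaluated as one matrix product); above that a greedy repair dynamics with
random restarts is used and the result is flagged approximate.  Witness
selection is deterministic: states in which every free node is locally
stable are preferred, then more satisfied constraints, then the first state
in enumeration order.  Every reported witness for a "stable" verdict
satisfies update(witness) = witness exactly.

The search space is one locus per merged edge: {absent, +, −} where the
original sign is unknown, {absent, keep} where the literature fixed it.
Literature-signed edges *are* eligible for removal — the expression data may
contradict a curated claim in this cell type.  Fitness is

    fitness = matched / total_constraints − λ · removed / |edges|,

where `matched` sums, over both phenotypes, the constrained non-input nodes
that are locally stable at their required value in the best witness.  The
removal penalty λ (default 0.01) is essential and deliberately small: with
the hold-state rule an edge-free network satisfies every constraint
trivially (fitness 1 − λ), so λ > 0 makes the trivial solution strictly
worse than any genuinely consistent one, while keeping constraint
satisfaction lexicographically dominant in practice.

The genetic algorithm is a plain generational GA on numpy's seeded
Generator: population 100, 200 generations, uniform crossover with
probability 0.7, per-locus mutation 1/|edges|, elitism 2, tournament
selection of size 3.  All values are configurable and none is sacred; on
networks of the size the pipeline produces the landscape is small and the GA
reaches the enumerated global optimum on every random ≤ 8-edge instance
tested (100 seeds).  The population is seeded with the keep-everything
genome (unknown signs → activating), which makes the "already consistent"
case exact at generation 0, and the search stops early at the fitness
ceiling (all constraints matched, nothing removed).  Ties are broken toward
fewer removed edges, then lexicographically smaller genomes, so fits are
fully deterministic for a fixed seed.  Fitness evaluations are memoized per
genome.

After pruning, stimulus edges from the curated downstream network are
re-attached to every retained node (idempotently, adding no other nodes):
pruning decides which genes stay, while the stimulus's direct connections to
those genes are curated facts.

## Path enumeration and essentiality

All simple directed paths stimulus → target are enumerated exhaustively
(networkx's simple-path generator; an optional length cap, and a safety cap
of 10⁶ paths that aborts with a clear error on pathological graphs).
Exhaustive enumeration replaces k-shortest-path approaches: it is exact and
removes the arbitrary choice of k.  Edge signs are ignored for
reachability — inhibitory routes are still routes.  Path lists are sorted
lexicographically, so results are deterministic.

For gene j, with N_TP total paths and N_jP paths not containing j,

    EM_j = (N_TP − N_jP) / N_TP.

(The equivalent per-path-fraction form is the normative one; an alternative
printed footnote form dividing by N_jP does not reproduce the worked
examples and is treated as an erratum.)  EM is reported both as an exact
rational and rounded to 2 decimals, half away from zero, which reproduces
all 13 published worked-example values.  Rankings sort by exact EM
descending with alphabetical tie-break and dense ranks; source and target
are excluded from the table by default (includable by flag).  A gene on
zero paths gets EM = 0 with a warning flag — for network genes this cannot
happen, and the flag keeps that claim checkable.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of (parameters, one integer seed).

* **PWMs**: per-position Dirichlet(1 + c·e_consensus) around a random
  consensus; concentration c controls sharpness (c → ∞ gives a 0/1 matrix).
  The default library size for a standalone library is 50 matrices — a
  plausible scale for a cell-type-restricted motif collection; nothing
  downstream depends on it.
* **Promoters**: i.i.d. background with configurable GC (default 0.41, a
  typical mammalian promoter-region value), window −2000/+1000.  Planted
  sites are exact consensus strings at recorded offsets/strands, never
  overlapping and never truncated (positions are redrawn, not clipped); a
  mutation-count parameter produces sub-consensus plants for
  threshold-sensitivity work.  No repeat structure, CpG islands or
  nucleosome signal is modelled — background hit rates on real promoters
  will be higher and position-dependent.
* **Literature network**: layered acyclic cascade with the stimulus as
  unique root; per-edge inhibition probability `sign_mix`.
* **Expression**: log2-scale Gaussian model — baselines N(7, 1.5²), planted
  shifts ±`lfc_effect`, noise sd `noise_sd`, `n_reps` per condition.
  Defaults: 3 replicates per condition (the usual design for this kind of
  two-condition array experiment), effect 4 log2 units with sd 0.25 — a
  strong-induction regime in which the t-test's power is ≈ 1, as the
  noncentral-t calculation in the tests confirms.  No probe-level artifacts,
  batch effects or intensity-dependent variance are simulated, so DEG
  calibration results here speak to the test statistic, not to array
  preprocessing.
* **Full scenario**: the first TF is the sole direct stimulus target and
  regulates the remaining TFs; all TFs have consensus sites planted on the
  target promoter; TFs and target are planted "up", background genes
  unchanged.  By construction the relay TF lies on every stimulus→target
  path (planted EM = 1), which is what the end-to-end plant-and-recover
  test checks.  The cascade is all-activating by default so the planted
  all-up expression phenotype is exactly consistent with the planted
  network — mixing in inhibitory edges would make the planted truth
  self-contradictory rather than harder.

Consequently, a passing suite shows the pipeline is *correct* (each stage
equals its independent oracle, and planted signal is recovered under
realistic noise); it does not show that real promoter scanning has a low
false-positive rate, nor that curated interaction databases are accurate —
those properties belong to the inputs, not the algorithms.

## Problem sizes used in the checks

The worked-example and merge checks run at the published sizes (92- and
100-path systems; 3936 + 1278 and 4235 + 2857 edges).  Oracle-equivalence
checks run where exhaustive enumeration is exact and cheap: ≤ 8-edge
contextualization instances (full genome enumeration, 100 seeds), ≤ 10-node
graphs for path enumeration, and 100-seed end-to-end scenarios with a
400/200 bp window, 4 TFs and 40 background genes with a pop-40/40-generation
GA — small enough to replicate a hundred times, large enough that every
stage (scanning, calling, merging, GA, ranking) is genuinely exercised.

## Known limitations

* Fixed points only; cyclic attractors and asynchronous schedules are out
  of scope.
* The fitness scalarization (constraint fraction minus λ·removal fraction)
  is this package's own objective; other contextualization formulations
  (e.g. building on elementary feedback circuits) exist and may prune
  differently.
* With > 12 free (unconstrained, non-input) nodes the attractor check is
  heuristic; results carry an `exact=False` flag but no error bound.
* The t-test stage assumes roughly Gaussian log-intensities and equal
  variances; moderated tests will disagree near the significance boundary.
* Simple-path enumeration is exponential in the worst case; the path cap
  turns pathological inputs into an explicit error rather than an
  open-ended computation.
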