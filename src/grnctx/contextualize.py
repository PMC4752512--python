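"""Contextualization: fitting a merged candidate network to expression phenotypes.

The merged network mixes heterogeneous evidence — unsigned binding-site
predictions and signed curated interactions — so it is generally inconsistent
with the observed condition-specific expression states.  Contextualization
resolves this by *pruning* edges and *assigning signs* so that the
booleanized control and stimulated phenotypes are both stable steady states
(fixed points) of the synchronous Boolean network, searched with a genetic
algorithm.

The search space is a per-edge genome: an edge whose sign is unknown takes a
value in {absent, activating, inhibiting}; a literature-signed edge takes
{absent, keep}.  A genome's fitness is

    fitness = matched / total_constraints − λ · removed_edges / |edges|,

where `matched` counts phenotype node constraints that are locally stable in
the best attractor witness of each condition.  The removal penalty λ (default
0.01) is essential: with the hold-state rule an edge-free network satisfies
every constraint trivially, so parsimony must cost something.

The stage is exposed as a model/results pair: :class:`NetworkContextualizer`
holds the data (merged network + phenotypes) and objective; ``fit()`` runs
the GA and returns a :class:`ContextualizationResults` with the selected
network, the fitness diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from grnctx.boolean import BooleanNet, best_witness
from grnctx.expression import BooleanPhenotype
from grnctx.network import GRN, Interaction

ABSENT = 0
KEEP_PLUS = 1  # '+' for unknown-sign loci; 'keep original sign' for signed loci
MINUS = 2  # only legal on unknown-sign loci


@dataclass(frozen=True)
class FitnessRecord:
    """Diagnostics of one candidate genome."""

    matched: int
    total_constraints: int
    removed_edges: int
    penalty_weight: float
    fitness: float
    seed: int = 0
    generations: int = 0
    exact: bool = True  # witness searches were exhaustive


@dataclass
class ContextualizationResults:
    """Fit outcome: the contextualized network plus search diagnostics."""

    model: "NetworkContextualizer"
    genome: np.ndarray
    network: GRN
    record: FitnessRecord
    ga_params: dict = field(default_factory=dict)
    n_evaluations: int = 0

    @property
    def fitness(self) -> float:
        return self.record.fitness

    def rank_regulators(self, max_len: int | None = None):
        """Simple-path essentiality ranking on the fitted network (after
        attaching stimulus edges is the caller's choice)."""
        from grnctx.paths import enumerate_simple_paths, rank_regulators

        ps = enumerate_simple_paths(
            self.network, self.model.stimulus, self.model.target, max_len=max_len
        )
        return rank_regulators(ps)

    def summary(self) -> str:
        m = self.model
        rec = self.record
        lines = [
            "Network contextualization (synchronous Boolean attractors, GA search)",
            "=" * 70,
            f"Merged network:        {len(m.merged.nodes)} nodes, {len(m.merged)} edges",
            f"Contextualized:        {len(self.network.nodes)} nodes, {len(self.network)} edges",
            f"Stimulus -> target:    {m.stimulus} -> {m.target}",
            f"Constraints matched:   {rec.matched} / {rec.total_constraints}",
            f"Removed edges:         {rec.removed_edges} (penalty λ = {rec.penalty_weight})",
            f"Fitness:               {rec.fitness:.6f}",
            f"Witness search:        {'exhaustive' if rec.exact else 'greedy (approximate)'}",
            f"GA: pop={self.ga_params.get('pop')} generations={rec.generations} "
            f"crossover_p={self.ga_params.get('crossover_p')} "
            f"mutation_p={self.ga_params.get('mutation_p'):.4g} "
            f"elitism={self.ga_params.get('elitism')} seed={rec.seed}",
            f"Genome evaluations:    {self.n_evaluations} (memoized)",
        ]
        return "\n".join(lines)

    def provenance(self) -> dict:
        return {
            "fitness": self.record.fitness,
            "matched": self.record.matched,
            "total_constraints": self.record.total_constraints,
            "removed_edges": self.record.removed_edges,
            "penalty_weight": self.record.penalty_weight,
            "seed": self.record.seed,
            "generations": self.record.generations,
            "ga_params": {k: v for k, v in self.ga_params.items()},
            "n_edges_merged": len(self.model.merged),
            "n_edges_contextualized": len(self.network),
        }


class NetworkContextualizer:
    """Model object: a merged GRN to be reconciled with two Boolean phenotypes.

    Parameters
    ----------
    merged : the union of the TFBS upstream and literature downstream networks.
    phenotypes : (control, stimulated) attractor constraints.
    stimulus, target : the clamped input node and the gene of interest; a
        directed path stimulus → target must exist in `merged`.
    penalty : λ, the removed-edge penalty weight.
    """

    def __init__(
        self,
        merged: GRN,
        phenotypes: tuple[BooleanPhenotype, BooleanPhenotype],
        stimulus: str,
        target: str,
        penalty: float = 0.01,
    ):
        if stimulus not in merged.nodes or target not in merged.nodes:
            raise ValueError("stimulus and target must be nodes of the merged network")
        if not nx.has_path(merged.to_networkx(), stimulus, target):
            raise ValueError(f"no path {stimulus} -> {target} in the merged network")
        self.merged = merged
        self.phenotypes = tuple(phenotypes)
        self.stimulus = stimulus
        self.target = target
        self.penalty = float(penalty)
        self.edge_keys: list[tuple[str, str]] = sorted(merged.edges)
        self.unknown_mask = np.array(
            [merged.edges[k].sign == "?" for k in self.edge_keys], dtype=bool
        )
        total = 0
        for ph in self.phenotypes:
            total += sum(1 for n in ph.state if n in merged.nodes and n != stimulus)
        self.total_constraints = total
        self._cache: dict[bytes, FitnessRecord] = {}

    # -- genome handling ----------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.edge_keys)

    def locus_cardinality(self) -> np.ndarray:
        """3 alleles on unknown-sign loci, 2 on literature-signed loci."""
        return np.where(self.unknown_mask, 3, 2)

    def keep_all_genome(self) -> np.ndarray:
        """Every edge retained; unknown signs set to activating."""
        return np.full(self.n_loci, KEEP_PLUS, dtype=np.int8)

    def decode(self, genome: np.ndarray) -> GRN:
        """Decode a genome into the retained, fully signed network.

        Nodes are the retained-edge endpoints plus stimulus and target (the
        result always contains both)."""
        genome = np.asarray(genome, dtype=np.int8)
        if genome.shape != (self.n_loci,):
            raise ValueError(f"genome length {genome.shape} != {self.n_loci} edges")
        if np.any((genome == MINUS) & ~self.unknown_mask):
            raise ValueError("sign-flip allele on a literature-signed locus")
        grn = GRN(nodes={self.stimulus, self.target})
        for allele, key in zip(genome, self.edge_keys):
            if allele == ABSENT:
                continue
            orig = self.merged.edges[key]
            sign = orig.sign if orig.sign != "?" else ("+" if allele == KEEP_PLUS else "-")
            grn.add(Interaction(orig.source, orig.target, sign, orig.provenance))
        return grn

    def _boolean_net(self, genome: np.ndarray) -> BooleanNet:
        # the Boolean system keeps every merged node: constrained nodes with
        # all edges removed still hold state (and trivially satisfy constraints)
        decoded = self.decode(genome)
        full = GRN(decoded.edges.values(), nodes=self.merged.nodes)
        return BooleanNet(full, inputs={self.stimulus})

    # -- objective ----------------------------------------------------------

    def fitness(self, genome: np.ndarray, seed: int = 0) -> FitnessRecord:
        """Evaluate a genome: constraint satisfaction minus removal penalty."""
        genome = np.asarray(genome, dtype=np.int8)
        key = genome.tobytes()
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        net = self._boolean_net(genome)
        matched = 0
        exact = True
        for ph in self.phenotypes:
            res = best_witness(net, ph.state, seed=seed)
            matched += res.matched
            exact = exact and res.exact
        removed = int(np.count_nonzero(genome == ABSENT))
        ratio = matched / self.total_constraints if self.total_constraints else 1.0
        fit = ratio - self.penalty * (removed / self.n_loci if self.n_loci else 0.0)
        rec = FitnessRecord(
            matched=matched,
            total_constraints=self.total_constraints,
            removed_edges=removed,
            penalty_weight=self.penalty,
            fitness=fit,
            seed=seed,
            exact=exact,
        )
        self._cache[key] = rec
        return rec

    def _sort_key(self, genome: np.ndarray, rec: FitnessRecord):
        # best fitness; ties to fewer removed edges, then lexicographic genome
        return (-rec.fitness, rec.removed_edges, tuple(int(a) for a in genome))

    # -- genetic algorithm --------------------------------------------------

    def fit(
        self,
        pop: int = 100,
        generations: int = 200,
        crossover_p: float = 0.7,
        mutation_p: float | None = None,
        elitism: int = 2,
        seed: int = 0,
    ) -> ContextualizationResults:
        """Run the GA and return the best contextualized network.

        Deterministic for a fixed seed.  The population is seeded with the
        keep-everything genome (unknown signs → activating) plus uniform
        random genomes; selection is 3-way tournament, crossover is uniform,
        mutation resamples each locus independently.  The search stops early
        when the fitness ceiling (all constraints matched, nothing removed)
        is reached.
        """
        rng = np.random.default_rng(seed)
        card = self.locus_cardinality()
        if mutation_p is None:
            mutation_p = 1.0 / max(self.n_loci, 1)
        population = [self.keep_all_genome()]
        for _ in range(pop - 1):
            population.append(rng.integers(0, card).astype(np.int8))

        def evaluate(genomes):
            return [self.fitness(g, seed=seed) for g in genomes]

        best_g, best_r = None, None
        gen_done = 0
        for gen in range(generations + 1):
            records = evaluate(population)
            order = sorted(
                range(len(population)),
                key=lambda i: self._sort_key(population[i], records[i]),
            )
            if best_g is None or self._sort_key(population[order[0]], records[order[0]]) < self._sort_key(best_g, best_r):
                best_g = population[order[0]].copy()
                best_r = records[order[0]]
            gen_done = gen
            ceiling = best_r.matched == self.total_constraints and best_r.removed_edges == 0
            if gen == generations or ceiling:
                break
            # next generation
            nxt = [population[i].copy() for i in order[:elitism]]
            while len(nxt) < pop:
                p1 = self._tournament(population, records, rng)
                p2 = self._tournament(population, records, rng)
                if rng.random() < crossover_p:
                    mask = rng.random(self.n_loci) < 0.5
                    child = np.where(mask, p1, p2).astype(np.int8)
                else:
                    child = p1.copy()
                mut = rng.random(self.n_loci) < mutation_p
                if mut.any():
                    resample = rng.integers(0, card).astype(np.int8)
                    child[mut] = resample[mut]
                nxt.append(child)
            population = nxt

        record = FitnessRecord(
            matched=best_r.matched,
            total_constraints=best_r.total_constraints,
            removed_edges=best_r.removed_edges,
            penalty_weight=best_r.penalty_weight,
            fitness=best_r.fitness,
            seed=seed,
            generations=gen_done,
            exact=best_r.exact,
        )
        return ContextualizationResults(
            model=self,
            genome=best_g,
            network=self.decode(best_g),
            record=record,
            ga_params={
                "pop": pop,
                "generations": generations,
                "crossover_p": crossover_p,
                "mutation_p": mutation_p,
                "elitism": elitism,
                "seed": seed,
            },
            n_evaluations=len(self._cache),
        )

    def _tournament(self, population, records, rng, k: int = 3) -> np.ndarray:
        idx = rng.integers(0, len(population), size=k)
        best = min(idx, key=lambda i: self._sort_key(population[i], records[i]))
        return population[best]


def contextualize_ga(
    merged: GRN,
    phenotypes: tuple[BooleanPhenotype, BooleanPhenotype],
    stimulus: str,
    target: str,
    ga: dict | None = None,
    penalty: float = 0.01,
) -> ContextualizationResults:
    """Functional entry point over :class:`NetworkContextualizer`."""
    model = NetworkContextualizer(merged, phenotypes, stimulus, target, penalty=penalty)
    return model.fit(**(ga or {}))


def attach_stimulus_edges(contextualized: GRN, downstream: GRN, stimulus: str) -> GRN:
    """Add every downstream edge from the stimulus to a retained node.

    The curated downstream network knows how the stimulus touches the
    retained genes; those incoming connections are restored after pruning.
    Idempotent; adds no new non-stimulus nodes.
    """
    out = GRN(contextualized.edges.values(), nodes=contextualized.nodes)
    for ix in downstream.sorted_edges():
        if ix.source == stimulus and ix.target in contextualized.nodes:
            if ix.key not in out.edges:
                out.add(ix)
    return out
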