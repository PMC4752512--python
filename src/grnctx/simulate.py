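"""Synthetic inputs with planted ground truth for the whole pipeline.

Every generator is a pure function of its arguments and one integer seed; no
global RNG state is touched.  The generators emulate, at the statistical
level the pipeline consumes:

* a PWM library (Dirichlet-concentrated per-position frequencies around a
  random consensus — sharper with higher concentration),
* promoter windows (i.i.d. background of configurable GC content with exact
  consensus binding sites planted at recorded offsets/strands; an optional
  mutation count yields sub-consensus plants),
* a signed stimulus-downstream literature network (layered, acyclic,
  stimulus as the unique root),
* two-condition log2-scale expression with planted up/down regulation at a
  configurable effect size, replicate count and Gaussian noise level.

`gen_full_scenario` wires these into a coherent study: one stimulus, one
inducible target gene whose promoter carries binding sites for the scenario
TFs, a literature cascade in which a single designated regulator relays the
stimulus — so that regulator lies on every stimulus→target path and its
planted essentiality is exactly 1 — and an expression matrix in which the
regulators and the target respond to the stimulus.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from grnctx import expression as expr_mod
from grnctx.network import GRN, Interaction
from grnctx.pwm import ALPHABET, CORE_WIDTH, PWM, reverse_complement, write_transfac


@dataclass
class ScenarioTruth:
    """Planted ground truth of a generated scenario."""

    planted_sites: list = field(default_factory=list)  # (tf_id, gene_id, offset, strand)
    true_regulators: list = field(default_factory=list)
    essential_regulator: str | None = None
    true_signs: dict = field(default_factory=dict)  # "src->tgt" -> '+'/'-'
    deg_truth: dict = field(default_factory=dict)  # gene -> up/down/unchanged
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScenarioTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_sites"] = [tuple(s) for s in d["planted_sites"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# PWM library
# ---------------------------------------------------------------------------

def gen_pwm_library(
    n_tf: int = 50,
    motif_len_range: tuple[int, int] = (8, 12),
    concentration: float = 5.0,
    seed: int = 0,
) -> list[PWM]:
    """Random PWM library.

    Each matrix gets a random consensus; per-position frequencies are drawn
    from Dirichlet(1 + concentration · e_consensus), so higher concentration
    gives a sharper consensus and ``concentration = inf`` a consensus-only
    (0/1) matrix.  Deterministic for a fixed seed.
    """
    if n_tf < 1:
        raise ValueError("n_tf must be >= 1")
    lo, hi = motif_len_range
    if lo < CORE_WIDTH:
        raise ValueError(
            f"motif length {lo} below the {CORE_WIDTH}-position core width; "
            f"motifs must span at least {CORE_WIDTH} positions"
        )
    if hi < lo:
        raise ValueError("empty motif length range")
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n_tf):
        length = int(rng.integers(lo, hi + 1))
        consensus = rng.integers(0, 4, size=length)
        freq = np.empty((length, 4))
        for pos in range(length):
            if np.isinf(concentration):
                freq[pos] = 0.0
                freq[pos, consensus[pos]] = 1.0
            else:
                alpha = np.ones(4)
                alpha[consensus[pos]] += concentration
                freq[pos] = rng.dirichlet(alpha)
        pwms.append(PWM(tf_id=f"TF{i + 1:02d}", freq=freq))
    return pwms


# ---------------------------------------------------------------------------
# Promoters with planted sites
# ---------------------------------------------------------------------------

def _background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(4, size=length, p=probs)


def gen_promoters(
    gene_ids: list[str],
    pwms: list[PWM],
    sites_per_gene: int | dict = 1,
    window: tuple[int, int] = (2000, 1000),
    background_gc: float = 0.41,
    mutations: int = 0,
    seed: int = 0,
) -> tuple[dict[str, str], ScenarioTruth]:
    """Promoter windows with planted binding sites.

    ``sites_per_gene`` is either a count (TFs drawn at random per site) or a
    mapping gene → list of tf_ids to plant.  Sites are exact consensus
    strings (or consensus with ``mutations`` random substitutions), inserted
    at recorded 0-based offsets on recorded strands, never overlapping each
    other and never truncated at the window end (out-of-range positions are
    redrawn).  Window length is upstream + downstream (−2000/+1000 around
    the TSS by default).
    """
    up, down = window
    if up <= 0 or down <= 0:
        raise ValueError("window lengths must be positive")
    if not 0.0 < background_gc < 1.0:
        raise ValueError("background_gc must lie in (0, 1)")
    length = up + down
    by_id = {p.tf_id: p for p in pwms}
    rng = np.random.default_rng(seed)
    promoters: dict[str, str] = {}
    truth = ScenarioTruth(seed=seed)
    for gene in gene_ids:
        codes = _background(rng, length, background_gc)
        if isinstance(sites_per_gene, dict):
            tf_ids = list(sites_per_gene.get(gene, []))
        else:
            tf_ids = [
                pwms[int(rng.integers(0, len(pwms)))].tf_id for _ in range(sites_per_gene)
            ]
        occupied: list[tuple[int, int]] = []
        for tf_id in tf_ids:
            pwm = by_id[tf_id]
            site = pwm.consensus
            if mutations:
                site_arr = np.array(list(site))
                pos = rng.choice(len(site), size=min(mutations, len(site)), replace=False)
                for p_ in pos:
                    site_arr[p_] = ALPHABET[
                        int((ALPHABET.index(site_arr[p_]) + 1 + rng.integers(0, 3)) % 4)
                    ]
                site = "".join(site_arr)
            m = len(site)
            if m > length:
                raise ValueError(f"motif {tf_id} longer than the promoter window")
            for _ in range(1000):
                off = int(rng.integers(0, length - m + 1))
                if all(off + m <= s or off >= e for s, e in occupied):
                    break
            else:
                raise RuntimeError(f"could not place site {tf_id} on {gene} without overlap")
            strand = "+" if rng.random() < 0.5 else "-"
            planted = site if strand == "+" else reverse_complement(site)
            codes[off : off + m] = [ALPHABET.index(b) for b in planted]
            occupied.append((off, off + m))
            truth.planted_sites.append((tf_id, gene, off, strand))
        promoters[gene] = "".join(ALPHABET[c] for c in codes)
    return promoters, truth


def write_fasta(promoters: dict[str, str], path, window: tuple[int, int] = (2000, 1000)) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    up, down = window
    records = [
        SeqRecord(Seq(seq), id=f"{gene}|window=-{up}:+{down}|strand=+", description="")
        for gene, seq in sorted(promoters.items())
    ]
    seqio_write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    promoters = {}
    for rec in SeqIO.parse(path, "fasta"):
        gene = rec.id.split("|")[0]
        promoters[gene] = str(rec.seq).upper()
    return promoters


# ---------------------------------------------------------------------------
# Literature network
# ---------------------------------------------------------------------------

def gen_literature_network(
    tfs: list[str],
    stimulus: str = "LPS",
    depth: int = 2,
    sign_mix: float = 0.0,
    extra_edge_p: float = 0.0,
    seed: int = 0,
) -> GRN:
    """Layered signed cascade downstream of the stimulus.

    TFs are spread over ``depth`` layers; every layer-1 TF is a direct
    stimulus target, every deeper TF has one parent in the previous layer
    (plus optional extra parents from any earlier layer), so the network is
    acyclic with the stimulus as unique root (out-degree >= 1, in-degree 0).
    Each edge is inhibitory with probability ``sign_mix``.
    """
    if not tfs:
        raise ValueError("empty TF list")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    order = list(tfs)
    layers: list[list[str]] = [[] for _ in range(min(depth, len(order)))]
    for i, tf in enumerate(order):
        layers[i % len(layers)].append(tf)

    def sign() -> str:
        return "-" if rng.random() < sign_mix else "+"

    grn = GRN(nodes={stimulus})
    for tf in layers[0]:
        grn.add(Interaction(stimulus, tf, sign(), frozenset({"literature"})))
    for k in range(1, len(layers)):
        for tf in layers[k]:
            parent = layers[k - 1][int(rng.integers(0, len(layers[k - 1])))]
            grn.add(Interaction(parent, tf, sign(), frozenset({"literature"})))
            if extra_edge_p > 0:
                for earlier in range(k - 1):
                    for cand in layers[earlier]:
                        if rng.random() < extra_edge_p and (cand, tf) not in grn.edges:
                            grn.add(Interaction(cand, tf, sign(), frozenset({"literature"})))
    return grn


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def gen_expression(
    genes: list[str],
    deg_truth: dict[str, str],
    n_reps: int = 3,
    lfc_effect: float = 4.0,
    noise_sd: float = 0.25,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-condition log2-scale expression with planted differential genes.

    Genes marked "up"/"down" in ``deg_truth`` get a mean shift of
    ±``lfc_effect`` in the stimulated condition; everything else is
    unchanged.  Per-sample noise is i.i.d. Gaussian with sd ``noise_sd``.
    """
    if n_reps < 2:
        raise ValueError("need n_reps >= 2 (variance undefined below)")
    if lfc_effect < 0:
        raise ValueError("lfc_effect must be >= 0")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    baseline = rng.normal(baseline_mean, baseline_sd, size=len(genes))
    shift = np.array(
        [
            lfc_effect if deg_truth.get(g) == "up" else -lfc_effect if deg_truth.get(g) == "down" else 0.0
            for g in genes
        ]
    )
    ctrl = baseline[:, None] + rng.normal(0, noise_sd, size=(len(genes), n_reps))
    stim = (baseline + shift)[:, None] + rng.normal(0, noise_sd, size=(len(genes), n_reps))
    samples = [f"ctrl_{i + 1}" for i in range(n_reps)] + [f"lps_{i + 1}" for i in range(n_reps)]
    matrix = pd.DataFrame(np.hstack([ctrl, stim]), index=pd.Index(genes, name="gene_id"), columns=samples)
    conditions = pd.Series(
        [expr_mod.CONTROL] * n_reps + [expr_mod.STIMULATED] * n_reps, index=samples, name="condition"
    )
    return matrix, conditions


# ---------------------------------------------------------------------------
# Full scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for a full synthetic scenario.

    The defaults mirror the emulated study: a −2000/+1000 promoter window,
    three replicates per condition, a strong induction (4 log2 units over
    0.25 sd noise), an all-activating cascade relayed by a single essential
    regulator, and 200 background genes on the array.
    """

    stimulus: str = "LPS"
    target: str = "IRG1"
    n_tfs: int = 4  # first TF is the essential relay
    n_background_genes: int = 200
    n_decoy_promoters: int = 3
    window: tuple[int, int] = (2000, 1000)
    motif_len_range: tuple[int, int] = (8, 12)
    concentration: float = 20.0
    background_gc: float = 0.41
    n_reps: int = 3
    lfc_effect: float = 4.0
    noise_sd: float = 0.25
    plant_target_sites: bool = True

    def validate(self) -> None:
        if self.n_tfs < 1:
            raise ValueError("need at least one TF")
        if not self.plant_target_sites:
            raise ValueError(
                f"target gene {self.target!r} would have no planted regulator"
            )


@dataclass
class ScenarioData:
    """In-memory bundle of every pipeline input plus the planted truth."""

    config: ScenarioConfig
    pwms: list
    promoters: dict
    literature: GRN
    expression: pd.DataFrame
    conditions: pd.Series
    truth: ScenarioTruth

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "promoters": out / "promoters.fasta",
            "pwms": out / "pwms.transfac",
            "literature": out / "literature.tsv",
            "expression": out / "expression.tsv",
            "conditions": out / "conditions.tsv",
            "truth": out / "truth.json",
        }
        write_fasta(self.promoters, files["promoters"], window=self.config.window)
        write_transfac(self.pwms, files["pwms"])
        from grnctx.network import write_edge_list

        write_edge_list(self.literature, files["literature"])
        expr_mod.write_expression(
            self.expression, self.conditions, files["expression"], files["conditions"]
        )
        self.truth.to_json(files["truth"])
        return files


def gen_full_scenario(config: ScenarioConfig = ScenarioConfig(), seed: int = 0) -> ScenarioData:
    """Generate every pipeline input with a sole planted essential regulator.

    The first TF is the only direct stimulus target in the literature
    cascade and it regulates the remaining TFs, so it sits on every
    stimulus→target path of the planted network; all scenario TFs have
    consensus sites planted on the target promoter.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]

    pwms = gen_pwm_library(
        n_tf=config.n_tfs,
        motif_len_range=config.motif_len_range,
        concentration=config.concentration,
        seed=sub[0],
    )
    tf_ids = [p.tf_id for p in pwms]
    relay, others = tf_ids[0], tf_ids[1:]

    # literature cascade: stimulus -> relay -> every other TF
    literature = GRN(nodes={config.stimulus})
    literature.add(Interaction(config.stimulus, relay, "+", frozenset({"literature"})))
    for tf in others:
        literature.add(Interaction(relay, tf, "+", frozenset({"literature"})))

    decoys = [f"GENE{i + 1:03d}" for i in range(config.n_decoy_promoters)]
    plant_map: dict[str, list[str]] = {config.target: list(tf_ids)}
    promoters, truth = gen_promoters(
        [config.target] + decoys,
        pwms,
        sites_per_gene=plant_map,
        window=config.window,
        background_gc=config.background_gc,
        seed=sub[1],
    )

    background = [f"BG{i + 1:04d}" for i in range(config.n_background_genes)]
    deg_truth = {g: "up" for g in tf_ids + [config.target]}
    deg_truth.update({g: "unchanged" for g in background + decoys})
    genes = tf_ids + [config.target] + decoys + background
    expression, conditions = gen_expression(
        genes,
        deg_truth,
        n_reps=config.n_reps,
        lfc_effect=config.lfc_effect,
        noise_sd=config.noise_sd,
        seed=sub[2],
    )

    truth.true_regulators = list(tf_ids)
    truth.essential_regulator = relay
    truth.true_signs = {f"{ix.source}->{ix.target}": ix.sign for ix in literature.sorted_edges()}
    truth.true_signs.update({f"{tf}->{config.target}": "+" for tf in tf_ids})
    truth.deg_truth = deg_truth
    truth.seed = seed
    return ScenarioData(
        config=config,
        pwms=pwms,
        promoters=promoters,
        literature=literature,
        expression=expression,
        conditions=conditions,
        truth=truth,
    )
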