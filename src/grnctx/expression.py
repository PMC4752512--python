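"""Differential-expression calling and booleanization into phenotype constraints.

A gene is differentially expressed when |log2 fold change| >= 1 (closed
bound) and the two-sided equal-variance t-test p-value is < 0.01 (open
bound).  Calls are booleanized symmetrically: an up-regulated gene is
constrained 0 in the control attractor and 1 in the stimulated one, a
down-regulated gene the reverse, and unchanged genes are left unconstrained.
The stimulus node is an input, clamped 0 (control) / 1 (stimulated).

The t-test operates on a gene × sample matrix of log2 intensities with a
sample → condition map; it is a deliberately simple stand-in for moderated
array pipelines, adequate here because contextualization consumes only the
binary calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CONTROL = "control"
STIMULATED = "stimulated"
UNCONSTRAINED = None


def _split(matrix: pd.DataFrame, conditions: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    conditions = conditions.reindex(matrix.columns)
    if conditions.isna().any():
        missing = matrix.columns[conditions.isna()].tolist()
        raise ValueError(f"samples without condition labels: {missing}")
    ctrl = matrix.loc[:, conditions == CONTROL]
    stim = matrix.loc[:, conditions == STIMULATED]
    for name, part in ((CONTROL, ctrl), (STIMULATED, stim)):
        if part.shape[1] < 2:
            raise ValueError(f"need >=2 replicates in condition {name!r}, got {part.shape[1]}")
        if part.isna().any().any():
            raise ValueError("missing expression values")
    return ctrl, stim


def log_fold_change(matrix: pd.DataFrame, conditions: pd.Series) -> pd.Series:
    """Per-gene log2 fold change: mean(stimulated) − mean(control)."""
    ctrl, stim = _split(matrix, conditions)
    return (stim.mean(axis=1) - ctrl.mean(axis=1)).rename("logFC")


def deg_test(matrix: pd.DataFrame, conditions: pd.Series) -> pd.Series:
    """Two-sided equal-variance two-sample t-test p-value per gene.

    Zero pooled variance is an edge case the t statistic leaves undefined;
    the rule here is p := 0 when the group means differ and p := 1 when they
    are equal.
    """
    ctrl, stim = _split(matrix, conditions)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(stim, ctrl, axis=1, equal_var=True)
    p = pd.Series(res.pvalue, index=matrix.index, name="p")
    degenerate = p.isna()
    if degenerate.any():
        diff = (stim.mean(axis=1) - ctrl.mean(axis=1)).abs() > 0
        p[degenerate] = np.where(diff[degenerate], 0.0, 1.0)
    return p


def call_degs(
    logfc: pd.Series,
    p: pd.Series,
    lfc_min: float = 1.0,
    p_max: float = 0.01,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Differential-expression calls from aligned logFC and p-value series.

    call = "up"   iff logFC >= +lfc_min and p < p_max,
    call = "down" iff logFC <= −lfc_min and p < p_max,
    otherwise "unchanged".  Bounds are closed on logFC and open on p.
    ``adjust="bh"`` applies Benjamini–Hochberg to p first (off by default:
    the calling rule is a raw p-value cut).
    """
    if not logfc.index.equals(p.index):
        p = p.reindex(logfc.index)
        if p.isna().any():
            raise ValueError("logFC and p series are not aligned")
    p_eff = p.copy()
    if adjust == "bh":
        order = np.argsort(p.values, kind="stable")
        n = len(p)
        ranked = p.values[order] * n / (np.arange(n) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        p_eff = pd.Series(np.empty(n), index=p.index)
        p_eff.iloc[order] = np.clip(adj, 0, 1)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    sig = p_eff < p_max
    call = np.where(
        sig & (logfc >= lfc_min), "up", np.where(sig & (logfc <= -lfc_min), "down", "unchanged")
    )
    return pd.DataFrame(
        {"gene_id": logfc.index, "logFC": logfc.values, "p": p.values, "call": call}
    ).set_index("gene_id")


def collapse_probes(matrix: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Collapse redundant probe rows to gene rows by the mean value."""
    mapped = probe_map.reindex(matrix.index)
    if mapped.isna().any():
        raise ValueError("probes without a gene mapping")
    return matrix.groupby(mapped).mean()


@dataclass(frozen=True)
class BooleanPhenotype:
    """Per-condition attractor constraints: node → {0, 1}; absent nodes are
    unconstrained."""

    condition_id: str
    state: dict = field(default_factory=dict)

    def constrained_nodes(self, exclude: set | frozenset = frozenset()) -> list[str]:
        return sorted(n for n in self.state if n not in exclude)

    def to_dict(self) -> dict:
        return {"condition_id": self.condition_id, "state": dict(self.state)}

    @classmethod
    def from_dict(cls, d: dict) -> "BooleanPhenotype":
        return cls(d["condition_id"], {k: int(v) for k, v in d["state"].items()})


def booleanize(
    degs: pd.DataFrame, grn_nodes: set, stimulus: str
) -> tuple[BooleanPhenotype, BooleanPhenotype]:
    """Map DEG calls to the (control, stimulated) attractor constraints.

    up → (0, 1); down → (1, 0); unchanged or absent from the network →
    unconstrained.  The stimulus is clamped 0/1 and must not appear in the
    DEG table (it is an input, not a gene).  Idempotent in the sense that the
    constraints depend only on the calls, not on prior booleanizations.
    """
    if stimulus in degs.index:
        raise ValueError(f"stimulus {stimulus!r} listed as a DEG; it is an input, not a gene")
    control = {stimulus: 0}
    stimulated = {stimulus: 1}
    for gene, call in degs["call"].items():
        if gene not in grn_nodes:
            continue
        if call == "up":
            control[gene], stimulated[gene] = 0, 1
        elif call == "down":
            control[gene], stimulated[gene] = 1, 0
    return (
        BooleanPhenotype(CONTROL, control),
        BooleanPhenotype(STIMULATED, stimulated),
    )


def write_phenotypes(phenotypes: tuple[BooleanPhenotype, BooleanPhenotype], path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in phenotypes], fh, indent=1)


def read_phenotypes(path) -> tuple[BooleanPhenotype, BooleanPhenotype]:
    with open(path) as fh:
        items = json.load(fh)
    return tuple(BooleanPhenotype.from_dict(d) for d in items)


def read_expression(expr_path, conditions_path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a gene × sample TSV (first column gene ids) and a two-column
    sample → condition map TSV."""
    matrix = pd.read_csv(expr_path, sep="\t", index_col=0)
    cond = pd.read_csv(conditions_path, sep="\t", index_col=0).iloc[:, 0]
    return matrix, cond


def write_expression(matrix: pd.DataFrame, conditions: pd.Series, expr_path, conditions_path) -> None:
    matrix.to_csv(expr_path, sep="\t")
    conditions.rename("condition").to_frame().rename_axis("sample").to_csv(
        conditions_path, sep="\t"
    )
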