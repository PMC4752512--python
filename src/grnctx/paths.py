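"""Simple-path enumeration and the essentiality-metric ranking of regulators.

All simple directed paths from the stimulus to the target gene are the
candidate signal-transduction routes.  A gene j participating in those paths
is scored by the essentiality metric

    EM_j = (N_TP − N_jP) / N_TP,

where N_TP is the total number of simple paths and N_jP the number of paths
in which j is absent — i.e. the fraction of routes that pass through j.
EM_j = 1 means removing j disconnects stimulus from target; EM_j cannot be 0
for a gene that lies on at least one path.  Edge signs are ignored for
reachability: inhibitory routes count as paths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import networkx as nx
import pandas as pd

from grnctx.network import GRN

MAX_PATHS_DEFAULT = 10**6


@dataclass(frozen=True)
class PathSet:
    """All simple stimulus→target paths, lexicographically ordered."""

    source: str
    target: str
    paths: tuple

    def __post_init__(self) -> None:
        for p in self.paths:
            if len(set(p)) != len(p):
                raise ValueError(f"path with repeated node: {p}")
            if p[0] != self.source or p[-1] != self.target:
                raise ValueError(f"path {p} does not run {self.source} -> {self.target}")
        object.__setattr__(self, "paths", tuple(tuple(p) for p in self.paths))

    @property
    def n_total(self) -> int:
        """N_TP: the total path count."""
        return len(self.paths)

    def interior_nodes(self) -> list[str]:
        nodes = {n for p in self.paths for n in p[1:-1]}
        return sorted(nodes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"path": [";".join(p) for p in self.paths]})


class PathExplosionError(RuntimeError):
    """Raised when enumeration exceeds the safety cap on path count."""


def enumerate_simple_paths(
    grn: GRN | nx.DiGraph,
    source: str,
    target: str,
    max_len: int | None = None,
    max_paths: int = MAX_PATHS_DEFAULT,
) -> PathSet:
    """Enumerate every simple directed path source → target.

    ``max_len`` caps the number of edges per path (default unbounded);
    ``max_paths`` aborts with :class:`PathExplosionError` on pathological
    graphs.  Paths are returned in lexicographic node-sequence order, so the
    result is deterministic.  Signs are ignored.
    """
    g = grn.to_networkx() if isinstance(grn, GRN) else grn
    if source == target:
        raise ValueError("source and target must differ")
    for node in (source, target):
        if node not in g:
            raise ValueError(f"node {node!r} not in network")
    paths = []
    for p in nx.all_simple_paths(g, source, target, cutoff=max_len):
        paths.append(tuple(p))
        if len(paths) > max_paths:
            raise PathExplosionError(
                f"more than {max_paths} simple paths {source}->{target}; "
                "raise max_paths or cap max_len"
            )
    paths.sort()
    return PathSet(source=source, target=target, paths=tuple(paths))


def _round_half_away(x: Fraction, ndigits: int = 2) -> float:
    """Round a non-negative rational half away from zero, exactly."""
    scaled = x * 10**ndigits
    sign = -1 if scaled < 0 else 1
    return sign * math.floor(abs(scaled) + Fraction(1, 2)) / 10**ndigits


def essentiality(pathset: PathSet, gene: str) -> tuple[int, Fraction, float]:
    """(N_jP, exact EM_j, EM_j rounded to 2 decimals) for one gene.

    N_jP counts the paths in which the gene is absent.  A gene on zero paths
    gets EM = 0 with a warning: network genes always ride at least one path,
    so a zero flags a node outside the path system.
    """
    if pathset.n_total < 1:
        raise ValueError("empty path set")
    n_absent = sum(1 for p in pathset.paths if gene not in p)
    em = Fraction(pathset.n_total - n_absent, pathset.n_total)
    if em == 0:
        warnings.warn(f"gene {gene!r} lies on no {pathset.source}->{pathset.target} path")
    return n_absent, em, _round_half_away(em)


def rank_regulators(pathset: PathSet, include_endpoints: bool = False) -> pd.DataFrame:
    """Essentiality table over every node on at least one path.

    Columns mirror the reporting convention: regulator, total_paths (N_TP),
    paths_absent (N_jP), essentiality (EM rounded to 2 decimals), plus the
    exact rational and a dense rank by descending EM (alphabetical on ties).
    Source and target are excluded unless ``include_endpoints``.
    """
    genes = set(pathset.interior_nodes())
    if include_endpoints:
        genes |= {pathset.source, pathset.target}
    rows = []
    for gene in sorted(genes):
        n_absent, em, em_round = essentiality(pathset, gene)
        rows.append(
            {
                "regulator": gene,
                "total_paths": pathset.n_total,
                "paths_absent": n_absent,
                "essentiality": em_round,
                "essentiality_exact": em,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["regulator", "total_paths", "paths_absent", "essentiality", "essentiality_exact"],
    )
    if df.empty:
        df["rank"] = pd.Series(dtype=int)
        return df
    df = df.sort_values(
        by=["essentiality_exact", "regulator"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = df["essentiality_exact"].rank(method="dense", ascending=False).astype(int)
    return df


def write_ranking(df: pd.DataFrame, path) -> None:
    df.drop(columns=["essentiality_exact"]).to_csv(path, sep="\t", index=False)


def write_paths(pathset: PathSet, path) -> None:
    pathset.to_frame().to_csv(path, sep="\t", index=False)
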