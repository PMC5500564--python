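"""Cohort matching on exact categorical fields plus a numeric caliper.

Two patient groups are matched many-to-one: each subject of the smaller group
may be paired with up to k subjects of the larger group (each of those used at
most once), where a pair is eligible only if all exact fields (default: tumor
stage) agree and the caliper field (default: age) differs by at most the
caliper (default: 10 years). For each ratio k the maximum-cardinality
b-matching is found by max-flow; the ratio is chosen to maximize nm/(n+m),
with n and m the distinct matched subjects on either side — a proxy for
two-sample test power under unequal group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = ["MatchSpec", "MatchResult", "eligible_edges", "max_matching_at_ratio", "optimal_ratio_match"]


@dataclass(frozen=True)
class MatchSpec:
    exact_fields: tuple = ("stage",)
    caliper_field: str = "age"
    caliper: float = 10.0
    max_ratio: int = 8

    def __post_init__(self):
        if self.caliper < 0:
            raise ValueError("caliper must be >= 0")
        if self.max_ratio < 1:
            raise ValueError("max_ratio must be >= 1")


@dataclass
class MatchResult:
    pairs: list  # (id_groupA, id_groupB)
    n: int  # distinct matched subjects from the smaller group
    m: int  # distinct matched subjects from the larger group
    ratio: int
    objective: float

    @property
    def cardinality(self) -> int:
        return len(self.pairs)


def _objective(n: int, m: int) -> float:
    return 0.0 if n + m == 0 else n * m / (n + m)


def eligible_edges(group_a: pd.DataFrame, group_b: pd.DataFrame, spec: MatchSpec) -> list:
    """All (idA, idB) pairs agreeing on every exact field with |caliper diff| <= caliper."""
    needed = set(spec.exact_fields) | {spec.caliper_field, "sample_id"}
    for df, name in ((group_a, "group A"), (group_b, "group B")):
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"{name} is missing required field(s): {sorted(missing)}")
    edges = []
    b_by_key: dict = {}
    for _, row in group_b.iterrows():
        key = tuple(row[f] for f in spec.exact_fields)
        b_by_key.setdefault(key, []).append((row["sample_id"], row[spec.caliper_field]))
    for _, row in group_a.iterrows():
        key = tuple(row[f] for f in spec.exact_fields)
        va = row[spec.caliper_field]
        for idb, vb in b_by_key.get(key, ()):
            if abs(va - vb) <= spec.caliper:
                edges.append((row["sample_id"], idb))
    return sorted(edges)


def max_matching_at_ratio(edges: list, k: int, small_is_a: bool = True) -> MatchResult:
    """Maximum-cardinality many-to-one matching at ratio k, via integer max-flow.

    The smaller group's subjects have capacity k, the larger group's capacity 1.
    ``small_is_a`` says which edge endpoint belongs to the smaller group. Nodes
    are inserted in sorted id order so the result is deterministic.
    """
    if k < 1:
        raise ValueError("ratio k must be >= 1")
    if not edges:
        return MatchResult(pairs=[], n=0, m=0, ratio=k, objective=0.0)
    if not small_is_a:
        edges = [(b, a) for a, b in edges]
    small_nodes = sorted({a for a, _ in edges})
    large_nodes = sorted({b for _, b in edges})
    # Min-cost max-flow: a subject's first pair is free, repeats cost 1, so
    # among maximum-cardinality matchings the one spreading pairs over the
    # most distinct smaller-group subjects (largest n) is returned — the
    # nm/(n+m) objective is increasing in n at fixed cardinality.
    g = nx.DiGraph()
    for a in small_nodes:
        g.add_edge("__source__", ("S0", a), capacity=1, weight=0)
        g.add_edge(("S0", a), ("S", a), capacity=1, weight=0)
        if k > 1:
            g.add_edge("__source__", ("S1", a), capacity=k - 1, weight=1)
            g.add_edge(("S1", a), ("S", a), capacity=k - 1, weight=0)
    for b in large_nodes:
        g.add_edge(("L", b), "__sink__", capacity=1, weight=0)
    for a, b in sorted(edges):
        g.add_edge(("S", a), ("L", b), capacity=1, weight=0)
    flow = nx.max_flow_min_cost(g, "__source__", "__sink__")
    pairs = []
    for a in small_nodes:
        for tgt, f in sorted(flow[("S", a)].items()):
            if f > 0:
                pairs.append((a, tgt[1]))
    if not small_is_a:
        pairs = [(b, a) for a, b in pairs]
    n = len({p[0] if small_is_a else p[1] for p in pairs})
    m = len({p[1] if small_is_a else p[0] for p in pairs})
    return MatchResult(pairs=sorted(pairs), n=n, m=m, ratio=k, objective=_objective(n, m))


def optimal_ratio_match(group_a: pd.DataFrame, group_b: pd.DataFrame, spec: MatchSpec = MatchSpec()) -> MatchResult:
    """Sweep k = 1..max_ratio and return the matching maximizing nm/(n+m).

    Ties break toward smaller k. The smaller pre-matching group takes the
    multi-capacity side; size ties go to group A.
    """
    edges = eligible_edges(group_a, group_b, spec)
    small_is_a = len(group_a) <= len(group_b)
    best = None
    for k in range(1, spec.max_ratio + 1):
        res = max_matching_at_ratio(edges, k, small_is_a=small_is_a)
        if best is None or res.objective > best.objective + 1e-12:
            best = res
    return best
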