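"""Statistical validation of modules.

Two complementary checks:

* a *weight-permutation test*: with the network topology fixed, the
  multiset of edge weights is shuffled over the edges and the module's
  internal weight sum recomputed; the p-value is the fraction of
  shuffles whose internal sum reaches the observed one,

      p = count(S_m <= S_m(n)) / n_perm.

  By that literal rule p can be exactly 0; an optional pseudocount mode
  reports (count + 1) / (n_perm + 1) instead, which is the better-behaved
  estimator for calibration studies.

* a *differential co-expression* comparison: Pearson co-expression
  networks over the module's genes are built separately in case and
  control samples and their edge sets contrasted, exposing condition-
  specific rewiring of the module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .expression import ExpressionMatrix
from .netprep import WeightedNetwork, _pair

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationReport",
    "CoexpressionNetwork",
    "EdgePartition",
    "module_weight_sum",
    "permute_weights",
    "permutation_pvalue",
    "coexpression_network",
    "differential_edges",
]


@dataclass(frozen=True)
class PermutationReport:
    """Outcome of the weight-permutation test for one module."""

    module_genes: frozenset[str]
    s_observed: float
    n_perm: int
    count_ge: int  # permutations with S_m(n) >= observed S_m
    p_value: float
    seed: int
    pseudocount: bool

    def to_dict(self) -> dict:
        return {
            "module_genes": sorted(self.module_genes),
            "s_observed": self.s_observed,
            "n_perm": self.n_perm,
            "count_ge": self.count_ge,
            "p_value": self.p_value,
            "seed": self.seed,
            "pseudocount": self.pseudocount,
        }


def module_weight_sum(net: WeightedNetwork, module_genes: Iterable[str]) -> float:
    """Sum of weights of edges with both endpoints inside the module."""
    module_genes = set(module_genes)
    missing = module_genes - net.nodes
    if missing:
        raise ValueError(f"module gene {sorted(missing)[0]!r} absent from network")
    total = 0.0
    for u, v, w in net.edges():
        if u in module_genes and v in module_genes:
            total += w
    return total


def permute_weights(net: WeightedNetwork, rng: np.random.Generator) -> WeightedNetwork:
    """One permutation round as a network: identical topology, the edge
    weight multiset shuffled uniformly over the edges."""
    edges = list(net.edges())
    weights = np.array([w for _, _, w in edges])
    shuffled = weights[rng.permutation(len(weights))]
    return WeightedNetwork.from_edges(
        [(u, v, float(w)) for (u, v, _), w in zip(edges, shuffled)], name=net.name
    )


def permutation_pvalue(
    net: WeightedNetwork,
    module_genes: Iterable[str],
    n_perm: int = 10_000,
    seed: int = 0,
    pseudocount: bool = False,
) -> PermutationReport:
    """Weight-permutation significance of a module's internal weight sum.

    Each round shuffles the full multiset of edge weights over the fixed
    edge topology (a global shuffle) and recomputes the internal sum.
    ``p = count(S_m <= S_m(n)) / n_perm``; with ``pseudocount``,
    ``(count + 1) / (n_perm + 1)``.  A module with no internal edges
    trivially gets p = 1 (every shuffled sum is >= 0) and a warning.
    Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    module_genes = frozenset(module_genes)
    s_obs = module_weight_sum(net, module_genes)
    edges = list(net.edges())
    weights = np.array([w for _, _, w in edges])
    internal_idx = np.array(
        [
            i
            for i, (u, v, _) in enumerate(edges)
            if u in module_genes and v in module_genes
        ],
        dtype=int,
    )
    if internal_idx.size == 0:
        logger.warning("module has no internal edges; permutation p-value is 1")
    rng = np.random.default_rng(seed)
    count = 0
    n_edges = len(weights)
    for _ in range(n_perm):
        perm = weights[rng.permutation(n_edges)]
        if s_obs <= perm[internal_idx].sum():
            count += 1
    p = (count + 1) / (n_perm + 1) if pseudocount else count / n_perm
    return PermutationReport(
        module_genes=module_genes,
        s_observed=s_obs,
        n_perm=n_perm,
        count_ge=count,
        p_value=float(p),
        seed=seed,
        pseudocount=pseudocount,
    )


@dataclass
class CoexpressionNetwork:
    """Pearson co-expression edges among a module's genes in one condition."""

    genes: tuple[str, ...]
    condition: str
    edges: dict[tuple[str, str], float]  # sorted pair -> r
    r_threshold: float

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)


class EdgePartition(NamedTuple):
    only_in_a: set[tuple[str, str]]
    only_in_b: set[tuple[str, str]]
    shared: set[tuple[str, str]]


def coexpression_network(
    expr: ExpressionMatrix,
    module_genes: Iterable[str],
    condition: str,
    r_threshold: float = 0.8,
) -> CoexpressionNetwork:
    """Build the module's co-expression network in one condition.

    An edge joins each gene pair with |Pearson r| >= ``r_threshold``
    over the condition's samples (at least 3 required).  Zero-variance
    genes get no edges and a logged warning.
    """
    module_genes = sorted(set(str(g) for g in module_genes))
    samples = expr.condition_samples(condition)
    if len(samples) < 3:
        raise ValueError(
            f"condition {condition!r} has {len(samples)} samples; need >= 3"
        )
    known = set(expr.values.index.astype(str))
    unknown = [g for g in module_genes if g not in known]
    if unknown:
        raise ValueError(f"gene {unknown[0]!r} absent from expression matrix")
    mat = expr.values.loc[module_genes, samples].to_numpy(dtype=float)
    sd = mat.std(axis=1)
    constant = {g for g, s in zip(module_genes, sd) if s == 0}
    for g in constant:
        logger.warning("gene %s has zero variance in %s samples; no edges", g, condition)
    edges: dict[tuple[str, str], float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(mat)
    for i, gi in enumerate(module_genes):
        for j in range(i + 1, len(module_genes)):
            gj = module_genes[j]
            if gi in constant or gj in constant:
                continue
            r = float(corr[i, j])
            if abs(r) >= r_threshold:
                edges[_pair(gi, gj)] = r
    return CoexpressionNetwork(
        genes=tuple(module_genes),
        condition=condition,
        edges=edges,
        r_threshold=r_threshold,
    )


def differential_edges(
    a: CoexpressionNetwork, b: CoexpressionNetwork
) -> EdgePartition:
    """Partition the union of the two networks' edges by membership."""
    if set(a.genes) != set(b.genes):
        raise ValueError("the two co-expression networks cover different gene sets")
    ea, eb = a.edge_set(), b.edge_set()
    return EdgePartition(only_in_a=ea - eb, only_in_b=eb - ea, shared=ea & eb)
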