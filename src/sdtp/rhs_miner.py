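"""Recurrent heavy subgraph (RHS) mining on a multilayer weight tensor.

An RHS is a gene set whose induced subgraph carries high total edge
weight simultaneously in one or more layers of a multilayer network.
With indicator vectors x over genes and y over layers, the objective is
the heaviness

    H(x, y) = 1/2 * sum_{i,j,k} a[i,j,k] * x_i * x_j * y_k,

the summed weight of all internal edges across the selected layers.
Because raw heaviness grows with module size, a module's *density* —
heaviness divided by the number of internal edge slots,
``C(|genes|, 2) * |layers|`` — is the scale-free quality measure; the
miner only accepts modules whose density clears a threshold (default
0.41, the operating point chosen by scanning enrichment behaviour, see
:func:`heaviness_scan`).

The solver is a deterministic three-phase heuristic:

1. *Continuous relaxation.*  Starting from uniform positive vectors,
   alternate multiplicative updates ``x_i <- g_i^(1/(p-1))`` with
   ``g_i = sum_jk a[i,j,k] x_j y_k`` and ``y_k <- h_k`` with
   ``h_k = sum_ij a[i,j,k] x_i x_j`` (each normalised), until the
   relative change of the continuous heaviness falls below a tolerance.
   For the default sparsity exponent p = 2 this is a tensor power
   iteration that concentrates mass on the heaviest coherent subgraph.
2. *Discretization.*  Genes are ranked by x and layers by y, and two
   deterministic candidate families are scored for every layer prefix:
   the x-ranking prefixes, and the greedy peeling family (iteratively
   strip the gene with the smallest internal weighted degree — the
   classic heuristic that tracks dense subgraphs even when they are not
   prefixes of the ranking).  Among candidates whose density clears the
   threshold, the one maximising the density-weighted heaviness
   ``H^gamma * density`` (gamma = 3 by default) is kept.  Raw heaviness
   is monotone in module size, so maximising it alone pads modules with
   weak background genes; weighting by density penalises that padding,
   and the exponent gamma sets the trade-off — large gamma approaches
   pure heaviness maximisation, gamma -> 0 approaches pure density.
3. *Masking.*  The accepted module's internal entries are zeroed in its
   accepted layers and mining repeats, so overlapping modules that
   share a few genes remain discoverable.  Mining stops when a full
   round of seeded restarts yields no qualifying module.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .netprep import MultilayerTensor

__all__ = [
    "RhsModule",
    "MinerConfig",
    "heaviness",
    "density",
    "mine_rhs",
    "heaviness_scan",
    "ScanResult",
    "exhaustive_best_module",
]


@dataclass(frozen=True)
class RhsModule:
    """A mined module: gene set, layer set, heaviness and density."""

    genes: frozenset[str]
    layers: frozenset[str]
    heaviness: float
    density: float
    rank: int = 0

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("a module needs at least 2 genes")
        if len(self.layers) < 1:
            raise ValueError("a module needs at least 1 layer")

    def to_dict(self) -> dict:
        return {
            "rank": self.rank,
            "genes": sorted(self.genes),
            "layers": sorted(self.layers),
            "heaviness": self.heaviness,
            "density": self.density,
        }


@dataclass
class MinerConfig:
    """Tunables of the RHS miner.

    density_threshold : minimum mean internal edge weight for an
        accepted module (default 0.41).
    min_size : minimum module gene count (default 3).
    max_modules : stop after this many modules.
    restarts : relaxation restarts per mining round; the first start is
        the deterministic uniform vector, later ones add seeded noise.
    sparsity_exponent : p in the x-update exponent 1/(p-1); p = 2 gives
        plain power iteration, larger p sharpens x towards sparsity.
    selection_exponent : gamma in the discretization score
        ``H^gamma * density``; larger values favour total internal
        weight over compactness.
    """

    density_threshold: float = 0.41
    min_size: int = 3
    max_modules: int = 100
    restarts: int = 3
    max_iterations: int = 200
    convergence_tol: float = 1e-6
    sparsity_exponent: float = 2.0
    selection_exponent: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density_threshold <= 1:
            raise ValueError("density_threshold must be in (0, 1]")
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if self.restarts < 1 or self.max_iterations < 1 or self.max_modules < 1:
            raise ValueError("restarts, max_iterations, max_modules must be >= 1")
        if self.sparsity_exponent <= 1:
            raise ValueError("sparsity_exponent must be > 1")
        if self.selection_exponent <= 0:
            raise ValueError("selection_exponent must be positive")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


def heaviness(
    tensor: MultilayerTensor, genes: Iterable[str], layers: Iterable[str]
) -> float:
    """Summed weight of all edges internal to ``genes`` across ``layers``.

    Equals ``1/2 sum_ijk a[i,j,k] x_i x_j y_k`` with indicator vectors;
    the half cancels the symmetric double count.  Empty selections give 0.
    """
    genes = list(genes)
    layers = list(layers)
    if not genes or not layers:
        # resolve indices anyway so unknown names still raise
        tensor.gene_positions(genes)
        tensor.layer_positions(layers)
        return 0.0
    gi = tensor.gene_positions(genes)
    li = tensor.layer_positions(layers)
    return float(tensor.weights[np.ix_(gi, gi, li)].sum() / 2.0)


def density(
    tensor: MultilayerTensor, genes: Iterable[str], layers: Iterable[str]
) -> float:
    """Heaviness per internal edge slot: H / (C(|genes|, 2) * |layers|).

    Equals 1 iff every internal edge in every selected layer has weight 1.
    """
    genes = list(genes)
    layers = list(layers)
    if len(genes) < 2:
        raise ValueError("density needs at least 2 genes")
    if not layers:
        raise ValueError("density needs at least 1 layer")
    slots = math.comb(len(genes), 2) * len(layers)
    return heaviness(tensor, genes, layers) / slots


# -- solver internals -------------------------------------------------


def _relax(
    W: np.ndarray, x: np.ndarray, y: np.ndarray, cfg: MinerConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Alternate multiplicative updates until the continuous heaviness
    stabilises; returns the final (x, y)."""
    exponent = 1.0 / (cfg.sparsity_exponent - 1.0)
    x = x / np.linalg.norm(x)
    y = y / np.linalg.norm(y)
    h_prev = None
    for _ in range(cfg.max_iterations):
        My = np.tensordot(W, y, axes=([2], [0]))  # (n, n)
        g = My @ x
        if not np.any(g > 0):
            break
        x = g**exponent
        x /= np.linalg.norm(x)
        h_k = np.einsum("ij,ijk->k", np.outer(x, x), W)
        norm_h = np.linalg.norm(h_k)
        if norm_h == 0:
            break
        y = h_k / norm_h
        h_cont = 0.5 * float(h_k @ y)
        if h_prev is not None and abs(h_cont - h_prev) <= cfg.convergence_tol * max(
            h_prev, 1e-30
        ):
            break
        h_prev = h_cont
    return x, y


def _discretize(
    W: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    cfg: MinerConfig,
    gene_index: Sequence[str],
    layer_index: Sequence[str],
) -> tuple[float, float, float, tuple[str, ...], tuple[str, ...]] | None:
    """Turn the continuous (x, y) into a discrete qualifying module.

    Two deterministic candidate families are generated for each layer
    prefix along the y ranking:

    * *x-prefixes*: the top-s genes by x, for every size s;
    * *peeling sets*: starting from all genes, iteratively remove the
      gene with the smallest internal weighted degree; the surviving
      set at every size is a candidate (the classic greedy family that
      tracks dense subgraphs even when they are not x-prefixes).

    Among candidates with density >= threshold, the one maximising the
    density-weighted heaviness ``H^selection_exponent * density`` is
    returned.  Returns (score, heaviness, density, genes, layers) or
    None if nothing qualifies.  All ties are broken by identifier, so
    the outcome is deterministic.
    """
    n, m = len(gene_index), len(layer_index)
    gene_order = sorted(range(n), key=lambda i: (-x[i], gene_index[i]))
    layer_order = sorted(range(m), key=lambda k: (-y[k], layer_index[k]))

    # candidates[(s, t)] -> (H, gene index tuple); later entries overwrite
    # earlier ones only if they are heavier
    candidates: dict[tuple[int, int], tuple[float, tuple[int, ...]]] = {}

    def offer(s: int, t: int, H: float, genes_idx: tuple[int, ...]) -> None:
        if s < cfg.min_size:
            return
        prev = candidates.get((s, t))
        if prev is None or H > prev[0]:
            candidates[(s, t)] = (H, genes_idx)

    for t in range(1, m + 1):
        A = W[:, :, layer_order[:t]].sum(axis=2)
        # x-prefix family, internal sums built incrementally
        H = 0.0
        for s in range(1, n + 1):
            i = gene_order[s - 1]
            H += float(A[i, gene_order[: s - 1]].sum())
            offer(s, t, H, tuple(sorted(gene_order[:s])))
        # peeling family: strip the weakest gene (smallest internal
        # weighted degree) one at a time
        remaining = list(range(n))
        degrees = A.sum(axis=1).astype(float)
        H = float(A.sum()) / 2.0
        offer(n, t, H, tuple(remaining))
        while len(remaining) > cfg.min_size:
            victim = min(remaining, key=lambda i: (degrees[i], gene_index[i]))
            H -= float(degrees[victim])
            remaining.remove(victim)
            degrees[remaining] -= A[remaining, victim]
            offer(len(remaining), t, H, tuple(remaining))

    eps = 1e-12
    best: tuple | None = None
    for (s, t), (H, genes_idx) in candidates.items():
        d = H / (math.comb(s, 2) * t)
        if d + eps < cfg.density_threshold:
            continue
        score = H**cfg.selection_exponent * d
        genes = tuple(sorted(gene_index[i] for i in genes_idx))
        layers = tuple(sorted(layer_index[k] for k in layer_order[:t]))
        key = (score, genes, layers)
        if best is None or key > (best[0], best[3], best[4]):
            best = (score, H, d, genes, layers)
    return best


def mine_rhs(
    tensor: MultilayerTensor, config: MinerConfig | None = None
) -> list[RhsModule]:
    """Iteratively extract recurrent heavy subgraphs from the tensor.

    Each round runs ``config.restarts`` seeded relaxations, discretizes
    each, keeps the best qualifying candidate, records it, and masks its
    internal entries in its accepted layers before the next round.
    Fully deterministic given ``config.seed``.  An all-zero tensor
    yields an empty list.
    """
    cfg = config or MinerConfig()
    W = tensor.weights.astype(float).copy()
    n, m = tensor.n_genes, tensor.n_layers
    if n < cfg.min_size:
        return []
    rng = np.random.default_rng(cfg.seed)
    gene_pos = {g: i for i, g in enumerate(tensor.gene_index)}
    layer_pos = {l: k for k, l in enumerate(tensor.layer_index)}
    modules: list[RhsModule] = []

    while len(modules) < cfg.max_modules:
        best: tuple | None = None
        for r in range(cfg.restarts):
            if r == 0:
                x0 = np.ones(n)
                y0 = np.ones(m)
            else:
                x0 = 1.0 + 0.25 * rng.random(n)
                y0 = 1.0 + 0.25 * rng.random(m)
            x, y = _relax(W, x0, y0, cfg)
            cand = _discretize(W, x, y, cfg, tensor.gene_index, tensor.layer_index)
            if cand is not None and (
                best is None or (cand[0], cand[3], cand[4]) > (best[0], best[3], best[4])
            ):
                best = cand
        if best is None:
            break
        _, H, d, genes, layers = best
        modules.append(
            RhsModule(
                genes=frozenset(genes),
                layers=frozenset(layers),
                heaviness=H,
                density=d,
                rank=len(modules) + 1,
            )
        )
        gi = np.array([gene_pos[g] for g in genes])
        li = np.array([layer_pos[l] for l in layers])
        W[np.ix_(gi, gi, li)] = 0.0
    return modules


def exhaustive_best_module(
    tensor: MultilayerTensor,
    density_threshold: float = 0.41,
    min_size: int = 3,
    max_size: int | None = None,
) -> tuple[float, frozenset[str], frozenset[str]] | None:
    """Brute-force reference: the maximum-heaviness (gene-subset,
    layer-subset) pair with density >= threshold, over *all* subsets.

    Exponential in the gene count; intended for small instances as an
    independent oracle against the heuristic miner.  Returns
    (heaviness, genes, layers), or None if nothing qualifies.
    """
    n, m = tensor.n_genes, tensor.n_layers
    best: tuple | None = None
    eps = 1e-12
    top = n if max_size is None else min(max_size, n)
    for size in range(min_size, top + 1):
        for gene_combo in itertools.combinations(range(n), size):
            gi = np.array(gene_combo)
            slots_g = math.comb(size, 2)
            per_layer = tensor.weights[np.ix_(gi, gi)].sum(axis=(0, 1)) / 2.0
            for t in range(1, m + 1):
                for layer_combo in itertools.combinations(range(m), t):
                    H = float(per_layer[list(layer_combo)].sum())
                    if H / (slots_g * t) + eps < density_threshold:
                        continue
                    if best is None or H > best[0]:
                        best = (H, gene_combo, layer_combo)
    if best is None:
        return None
    H, gene_combo, layer_combo = best
    return (
        H,
        frozenset(tensor.gene_index[i] for i in gene_combo),
        frozenset(tensor.layer_index[k] for k in layer_combo),
    )


# -- parameter scan ---------------------------------------------------


@dataclass
class ScanResult:
    """Density-threshold scan output.

    ``table`` has one row per threshold: module count (Na), count of
    modules with at least one significantly enriched term (Ne), their
    ratio Rea (NaN where Na = 0, flagged in ``ratio_defined``), and the
    per-layer count of genes shared between mined modules and that
    layer's drug-affected gene set.  ``modules`` maps each threshold to
    the mined module list.
    """

    table: pd.DataFrame
    modules: dict[float, list[RhsModule]]


def heaviness_scan(
    tensor: MultilayerTensor,
    thresholds: Sequence[float],
    annotation: "AnnotationMap",
    drug_gene_sets: Mapping[str, set[str]],
    config: MinerConfig | None = None,
    alpha: float = 0.05,
) -> ScanResult:
    """Mine at each density threshold and tabulate enrichment behaviour.

    Mirrors the operating-point selection procedure: as the threshold
    rises, fewer modules survive but a larger fraction of them is
    functionally enriched; the drug-overlap columns track how many
    drug-affected genes the surviving modules still cover per layer.
    """
    from .filters import enrich_terms  # local import to avoid a cycle

    cfg = config or MinerConfig()
    rows = []
    modules_by_thr: dict[float, list[RhsModule]] = {}
    namespaces = sorted({ns for terms in annotation.gene_terms.values() for ns, _ in terms})
    for thr in thresholds:
        if not 0 < thr <= 1:
            raise ValueError(f"threshold {thr} outside (0, 1]")
        mods = mine_rhs(tensor, replace(cfg, density_threshold=thr))
        modules_by_thr[thr] = mods
        na = len(mods)
        ne = 0
        for mod in mods:
            query = set(mod.genes) & annotation.background
            enriched = False
            for ns in namespaces:
                if not query:
                    break
                results = enrich_terms(query, annotation, ns, alpha=alpha)
                if any(r.p_adjusted <= alpha for r in results):
                    enriched = True
                    break
            ne += enriched
        union_genes: set[str] = set()
        for mod in mods:
            union_genes |= mod.genes
        row = {
            "threshold": thr,
            "n_modules": na,
            "n_enriched": ne,
            "ratio": (ne / na) if na else float("nan"),
            "ratio_defined": na > 0,
        }
        for layer in tensor.layer_index:
            drug = drug_gene_sets.get(layer, set())
            row[f"overlap_{layer}"] = len(union_genes & drug)
        rows.append(row)
    return ScanResult(table=pd.DataFrame(rows), modules=modules_by_thr)
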