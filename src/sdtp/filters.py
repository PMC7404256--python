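"""The module-selection cascade.

Mined candidate modules are whittled down in stages: a minimum-size
rule, removal of near-duplicate modules by overlap coefficient, a
requirement that a module contain drug-responsive (concordant) genes,
functional-term filters against the drug's known targets and against
disease gene sets, and finally a first-order-neighbour analysis whose
pathway overlap with the drug's targets ranks the survivors.

Term enrichment is a local hypergeometric engine over a user-supplied
gene -> (namespace, term) annotation table (namespaces BP / MF / CC for
gene-ontology-style terms, PATHWAY for pathway memberships), with
Benjamini--Hochberg adjustment within each namespace.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .netprep import WeightedNetwork
from .rhs_miner import RhsModule

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMap",
    "EnrichmentResult",
    "overlap_coefficient",
    "is_overlapped",
    "size_filter",
    "deg_containment_filter",
    "enrich_terms",
    "significant_terms",
    "term_overlap_filter",
    "disease_term_filter",
    "first_order_neighbors",
    "neighbor_score",
    "neighbor_threshold",
    "conserved_neighbors",
    "pathway_overlap_count",
    "top_k_modules",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "write_annotation",
]

GO_NAMESPACES = ("BP", "MF", "CC")
KNOWN_NAMESPACES = ("BP", "MF", "CC", "PATHWAY")


# -- annotation container ---------------------------------------------


@dataclass
class AnnotationMap:
    """Gene -> set of (namespace, term-id) pairs over a background.

    Every annotated gene must belong to ``background``; the background
    is the statistical universe of the hypergeometric test.
    """

    gene_terms: dict[str, set[tuple[str, str]]]
    background: set[str]

    def __post_init__(self) -> None:
        stray = set(self.gene_terms) - self.background
        if stray:
            raise ValueError(
                f"annotated genes outside the background: {sorted(stray)[:5]}"
            )

    def term_to_genes(self, namespace: str) -> dict[str, set[str]]:
        """Invert the map for one namespace: term-id -> annotated genes."""
        index: dict[str, set[str]] = {}
        for gene, terms in self.gene_terms.items():
            for ns, term in terms:
                if ns == namespace:
                    index.setdefault(term, set()).add(gene)
        return index

    def namespaces(self) -> list[str]:
        return sorted({ns for terms in self.gene_terms.values() for ns, _ in terms})


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's enrichment in a query gene set.

    k of the n query genes carry the term; K of the N background genes
    do.  ``p_raw`` is the hypergeometric upper tail P(X >= k);
    ``p_adjusted`` is Benjamini--Hochberg within the namespace.
    """

    term: str
    namespace: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adjusted: float


# -- set similarity ---------------------------------------------------


def overlap_coefficient(a: Iterable[str], b: Iterable[str]) -> float:
    """|a n b| / min(|a|, |b|); symmetric, in [0, 1]."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("overlap_coefficient requires two non-empty sets")
    return len(a & b) / min(len(a), len(b))


def is_overlapped(a: Iterable[str], b: Iterable[str]) -> bool:
    """True iff the overlap coefficient reaches 2/3 (exact rational
    comparison, so the 2-of-3 boundary case counts as overlapped)."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("is_overlapped requires two non-empty sets")
    return 3 * len(a & b) >= 2 * min(len(a), len(b))


# -- simple module filters --------------------------------------------


def size_filter(modules: Sequence[RhsModule], min_size: int = 3) -> list[RhsModule]:
    """Keep modules with at least ``min_size`` genes, order preserved."""
    return [m for m in modules if len(m.genes) >= min_size]


def deg_containment_filter(
    modules: Sequence[RhsModule],
    concordant: Mapping[str, set[str]],
    mode: str = "any",
) -> list[RhsModule]:
    """Keep modules containing drug-responsive differential genes.

    ``concordant`` maps each disease to its concordant gene set.  With
    ``mode='any'`` (default) a module must share at least one gene with
    the union of the sets; with ``mode='all'`` it must hit every set.
    """
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    sets = list(concordant.values())
    kept = []
    for mod in modules:
        if mode == "any":
            union = set().union(*sets) if sets else set()
            ok = bool(mod.genes & union)
        else:
            ok = all(mod.genes & s for s in sets)
        if ok:
            kept.append(mod)
    return kept


# -- enrichment -------------------------------------------------------


def enrich_terms(
    query: Iterable[str],
    annotation: AnnotationMap,
    namespace: str,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric term enrichment of a query gene set.

    One result per term with at least one query gene; ``p_raw`` is the
    upper-tail P(X >= k) of Hypergeom(N, K, n) and ``p_adjusted`` the
    BH-adjusted value across the namespace's tested terms.  Terms with
    ``p_adjusted <= alpha`` are significant.  Sorted by raw p-value,
    then term id.
    """
    query = set(query)
    if not query:
        raise ValueError("query gene set is empty")
    outside = query - annotation.background
    if outside:
        raise ValueError(
            f"query gene {sorted(outside)[0]!r} is not in the annotation background"
        )
    N = len(annotation.background)
    n = len(query)
    index = annotation.term_to_genes(namespace)
    rows = []
    for term in sorted(index):
        term_genes = index[term]
        k = len(query & term_genes)
        if k == 0:
            continue
        K = len(term_genes)
        p_raw = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, min(p_raw, 1.0)))
    if not rows:
        return []
    _, p_adj, _, _ = multipletests([r[3] for r in rows], alpha=alpha, method="fdr_bh")
    results = [
        EnrichmentResult(
            term=term,
            namespace=namespace,
            k=k,
            K=K,
            n=n,
            N=N,
            p_raw=p_raw,
            p_adjusted=float(max(adj, p_raw)),
        )
        for (term, k, K, p_raw), adj in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.term))
    return results


def significant_terms(
    query: Iterable[str],
    annotation: AnnotationMap,
    namespace: str,
    alpha: float = 0.05,
) -> set[str]:
    """Term ids significant at BH-adjusted level ``alpha``."""
    return {
        r.term
        for r in enrich_terms(query, annotation, namespace, alpha=alpha)
        if r.p_adjusted <= alpha
    }


# -- term-based module filters ----------------------------------------


def term_overlap_filter(
    modules: Sequence[RhsModule],
    reference_terms: set[tuple[str, str]],
    annotation: AnnotationMap,
    min_proportion: float = 0.2,
    alpha: float = 0.05,
) -> tuple[list[RhsModule], list[dict]]:
    """Filter modules by shared significant terms with a reference set.

    For each module and each of BP / MF / CC, the module's genes are
    enriched, the significant terms collected, and the proportion
    |common with reference| / |module terms| computed.  A module is kept
    when the proportion reaches ``min_proportion`` in all three
    namespaces; a namespace with zero significant terms leaves the
    proportion undefined and drops the module (logged).  Returns
    (kept modules, per-module report rows).
    """
    if not reference_terms:
        raise ValueError("reference_terms must be non-empty")
    ref_by_ns = {
        ns: {t for s, t in reference_terms if s == ns} for ns in GO_NAMESPACES
    }
    kept: list[RhsModule] = []
    report: list[dict] = []
    for mod in modules:
        query = set(mod.genes) & annotation.background
        row: dict = {"module": mod, "kept": False, "reason": ""}
        ok = True
        for ns in GO_NAMESPACES:
            sig = significant_terms(query, annotation, ns, alpha=alpha) if query else set()
            if not sig:
                row[ns] = float("nan")
                row["reason"] = f"no significant {ns} terms"
                logger.info(
                    "module rank %d dropped: no significant %s terms", mod.rank, ns
                )
                ok = False
                continue
            prop = len(sig & ref_by_ns[ns]) / len(sig)
            row[ns] = prop
            if prop < min_proportion:
                ok = False
                if not row["reason"]:
                    row["reason"] = f"{ns} overlap proportion {prop:.3f} < {min_proportion}"
        row["kept"] = ok
        report.append(row)
        if ok:
            kept.append(mod)
    return kept, report


def disease_term_filter(
    modules: Sequence[RhsModule],
    disease_term_lists: Mapping[str, set[tuple[str, str]]],
    annotation: AnnotationMap,
    alpha: float = 0.05,
) -> list[RhsModule]:
    """Keep modules sharing at least one significant BP, MF and CC term
    with *every* disease term list (a conjunction over diseases and
    namespaces)."""
    if not disease_term_lists:
        raise ValueError("at least one disease term list is required")
    kept = []
    for mod in modules:
        query = set(mod.genes) & annotation.background
        sig_by_ns = {
            ns: (significant_terms(query, annotation, ns, alpha=alpha) if query else set())
            for ns in GO_NAMESPACES
        }
        ok = True
        for terms in disease_term_lists.values():
            for ns in GO_NAMESPACES:
                disease_ns = {t for s, t in terms if s == ns}
                if not sig_by_ns[ns] & disease_ns:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            kept.append(mod)
    return kept


# -- first-order neighbours -------------------------------------------


def first_order_neighbors(net: WeightedNetwork, module_genes: Iterable[str]) -> set[str]:
    """Genes outside the module with at least one edge into it."""
    module_genes = set(module_genes)
    out: set[str] = set()
    for g in module_genes:
        if net.has_node(g):
            out |= net.neighbors(g)
    return out - module_genes


def neighbor_score(
    net: WeightedNetwork, module_genes: Iterable[str], gene: str
) -> float:
    """Connection strength of an outside gene to a module: the sum of
    its edge weights into the module (missing edges contribute 0)."""
    module_genes = set(module_genes)
    if gene in module_genes:
        raise ValueError(f"gene {gene!r} is inside the module")
    return float(sum(net.weight(g, gene) for g in module_genes))


def neighbor_threshold(
    net: WeightedNetwork,
    module_genes: Iterable[str],
    n_samples: int = 1_000_000,
    rank: int = 50,
    seed: int = 0,
) -> float:
    """Sampling threshold on first-order connection strengths.

    Draws ``n_samples`` first-order neighbours uniformly with
    replacement, scores each, sorts descending and returns the
    ``rank``-th value.  With replacement is the only consistent reading
    when the sample size far exceeds the neighbour count.  Deterministic
    given ``seed``.
    """
    module_genes = set(module_genes)
    if rank < 1 or rank > n_samples:
        raise ValueError(f"rank must be in [1, n_samples], got {rank}")
    neighbors = sorted(first_order_neighbors(net, module_genes))
    if not neighbors:
        raise ValueError("module has no first-order neighbors")
    scores = np.array([neighbor_score(net, module_genes, g) for g in neighbors])
    rng = np.random.default_rng(seed)
    draws = scores[rng.integers(0, len(neighbors), size=n_samples)]
    draws.sort()  # ascending; rank-th largest is index n_samples - rank
    return float(draws[n_samples - rank])


def conserved_neighbors(
    net: WeightedNetwork, module_genes: Iterable[str], threshold: float
) -> set[str]:
    """First-order neighbours whose score strictly exceeds the threshold."""
    module_genes = set(module_genes)
    return {
        g
        for g in first_order_neighbors(net, module_genes)
        if neighbor_score(net, module_genes, g) > threshold
    }


def pathway_overlap_count(terms_a: Iterable[str], terms_b: Iterable[str]) -> int:
    """Number of shared pathway terms between two term sets."""
    return len(set(terms_a) & set(terms_b))


def top_k_modules(
    scored: Sequence[tuple[RhsModule, float]], k: int = 2
) -> list[RhsModule]:
    """Keep the k modules with the highest score (e.g. total pathway
    overlap across tissues); ties broken by discovery rank."""
    ranked = sorted(scored, key=lambda pair: (-pair[1], pair[0].rank))
    return [mod for mod, _ in ranked[:k]]


# -- file formats -----------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: set-name <tab> description <tab> gene..."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(set(sets[name])))
            fh.write(f"{name}\tna\t{genes}\n")


def read_annotation(path: str | Path, background: set[str] | None = None) -> AnnotationMap:
    """Three-column TSV: gene-id, namespace, term-id.

    The background defaults to the genes appearing in the file; pass an
    explicit superset to widen the statistical universe.
    """
    gene_terms: dict[str, set[tuple[str, str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
        gene, ns, term = parts
        gene_terms.setdefault(gene, set()).add((ns, term))
    bg = set(gene_terms) if background is None else set(background) | set(gene_terms)
    return AnnotationMap(gene_terms=gene_terms, background=bg)


def write_annotation(annotation: AnnotationMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gene in sorted(annotation.gene_terms):
            for ns, term in sorted(annotation.gene_terms[gene]):
                fh.write(f"{gene}\t{ns}\t{term}\n")
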