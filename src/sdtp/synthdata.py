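"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the pipeline can be exercised without external downloads:
multilayer networks with dense modules planted over a sparse noisy
background, log2 expression matrices in which a module co-varies in
case samples only, paired disease/drug logFC tables with a known
concordant gene set, and annotation maps with terms planted to be
significantly enriched in designated modules.  All generators are
bit-reproducible under a fixed seed.

Also packaged here is a small published fixture: the 26 candidate
drug-target modules (Entrez gene ids) selected for the histone
deacetylase inhibitor trichostatin A, used as ground truth for the
overlap-coefficient worked examples.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import CASE, CONTROL, DifferentialTable, ExpressionMatrix
from .filters import AnnotationMap
from .netprep import MultilayerTensor

__all__ = [
    "PlantedModule",
    "PlantedTruth",
    "simulate_multilayer",
    "simulate_expression",
    "simulate_logfc_tables",
    "simulate_annotation",
    "table1_fixture",
    "TABLE1_SHA256",
]


@dataclass(frozen=True)
class PlantedModule:
    genes: frozenset[str]
    layers: frozenset[str]
    internal_range: tuple[float, float]


@dataclass
class PlantedTruth:
    """Ground truth of a simulated multilayer tensor."""

    modules: list[PlantedModule]
    background_range: tuple[float, float]
    n_genes: int
    n_layers: int
    edge_prob: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "modules": [
                    {
                        "genes": sorted(m.genes),
                        "layers": sorted(m.layers),
                        "internal_range": list(m.internal_range),
                    }
                    for m in self.modules
                ],
                "background_range": list(self.background_range),
                "n_genes": self.n_genes,
                "n_layers": self.n_layers,
                "edge_prob": self.edge_prob,
                "seed": self.seed,
            },
            indent=2,
        )


def _check_range(rng_pair: tuple[float, float], label: str) -> None:
    lo, hi = rng_pair
    if not (0 < lo <= hi <= 1):
        raise ValueError(f"{label} {rng_pair} must satisfy 0 < lo <= hi <= 1")


def simulate_multilayer(
    n_genes: int = 200,
    n_layers: int = 3,
    background_range: tuple[float, float] = (0.05, 0.2),
    edge_prob: float = 0.1,
    planted: Sequence[tuple[int, Sequence[int] | None, tuple[float, float]]] = (
        (8, None, (0.8, 1.0)),
    ),
    seed: int = 0,
    allow_overlap: bool = False,
    allow_weak: bool = False,
) -> tuple[MultilayerTensor, PlantedTruth]:
    """Multilayer tensor with dense planted modules over a noisy background.

    Background edges appear independently with probability ``edge_prob``
    and weights uniform in ``background_range``; each planted module
    ``(size, layer_indices, internal_range)`` becomes a complete
    subgraph with uniform weights in ``internal_range`` on its layers
    (``None`` = all layers).  Planted gene sets are disjoint unless
    ``allow_overlap``; an internal range at or below the background
    range is rejected unless ``allow_weak`` (contrast enforcement).
    Deterministic given ``seed``.
    """
    _check_range(background_range, "background_range")
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    layers = [f"layer{k}" for k in range(n_layers)]
    weights = np.zeros((n_genes, n_genes, n_layers))

    iu = np.triu_indices(n_genes, k=1)
    for k in range(n_layers):
        present = rng.random(len(iu[0])) < edge_prob
        w = rng.uniform(*background_range, size=len(iu[0])) * present
        mat = np.zeros((n_genes, n_genes))
        mat[iu] = w
        weights[:, :, k] = mat + mat.T

    pool = list(range(n_genes))
    modules: list[PlantedModule] = []
    for size, layer_sel, internal_range in planted:
        _check_range(internal_range, "internal_range")
        if size > n_genes:
            raise ValueError(f"planted size {size} exceeds n_genes {n_genes}")
        if internal_range[0] <= background_range[1] and not allow_weak:
            raise ValueError(
                "planted internal_range does not exceed the background range; "
                "pass allow_weak=True to plant a weak module"
            )
        source = pool if not allow_overlap else list(range(n_genes))
        if len(source) < size:
            raise ValueError("not enough unassigned genes for disjoint planting")
        chosen = sorted(rng.choice(source, size=size, replace=False).tolist())
        if not allow_overlap:
            pool = [i for i in pool if i not in set(chosen)]
        layer_idx = list(range(n_layers)) if layer_sel is None else sorted(layer_sel)
        if any(k < 0 or k >= n_layers for k in layer_idx):
            raise ValueError(f"planted layer indices {layer_idx} out of range")
        for k in layer_idx:
            for a_pos, i in enumerate(chosen):
                for j in chosen[a_pos + 1 :]:
                    w = rng.uniform(*internal_range)
                    weights[i, j, k] = weights[j, i, k] = w
        modules.append(
            PlantedModule(
                genes=frozenset(genes[i] for i in chosen),
                layers=frozenset(layers[k] for k in layer_idx),
                internal_range=tuple(internal_range),
            )
        )
    tensor = MultilayerTensor(genes, layers, weights)
    truth = PlantedTruth(
        modules=modules,
        background_range=tuple(background_range),
        n_genes=n_genes,
        n_layers=n_layers,
        edge_prob=edge_prob,
        seed=seed,
    )
    return tensor, truth


def simulate_expression(
    module_genes: Sequence[str],
    n_genes: int = 100,
    n_case: int = 50,
    n_control: int = 50,
    within_module_r: float = 0.8,
    seed: int = 0,
    base_mean: float = 8.0,
    noise_sd: float = 1.0,
) -> ExpressionMatrix:
    """Expression matrix with case-only module co-expression.

    In case samples the module genes share a latent factor giving
    pairwise correlation about ``within_module_r`` (single-factor model:
    value = sqrt(r) * factor + sqrt(1 - r) * noise); control samples and
    non-module genes are independent noise.  Values are on the log2
    scale around ``base_mean``.
    """
    if not 0 <= within_module_r < 1:
        raise ValueError("within_module_r must be in [0, 1)")
    if n_case < 3 or n_control < 3:
        raise ValueError("need at least 3 case and 3 control samples")
    module_genes = [str(g) for g in module_genes]
    if len(set(module_genes)) != len(module_genes):
        raise ValueError("duplicate module genes")
    rng = np.random.default_rng(seed)
    filler = [f"x{i:04d}" for i in range(max(0, n_genes - len(module_genes)))]
    genes = module_genes + filler
    samples = [f"case{i:03d}" for i in range(n_case)] + [
        f"ctrl{i:03d}" for i in range(n_control)
    ]
    labels = pd.Series(
        [CASE] * n_case + [CONTROL] * n_control, index=samples
    )
    values = base_mean + noise_sd * rng.standard_normal((len(genes), len(samples)))
    # shared factor for module genes in case samples only
    factor = rng.standard_normal(n_case)
    loading = np.sqrt(within_module_r)
    resid = np.sqrt(1.0 - within_module_r)
    for gi in range(len(module_genes)):
        eps = rng.standard_normal(n_case)
        values[gi, :n_case] = base_mean + noise_sd * (loading * factor + resid * eps)
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), labels, name="synthetic"
    )


def simulate_logfc_tables(
    concordant_genes: Sequence[str],
    all_genes: Sequence[str],
    effect_size: float = 1.0,
    seed: int = 0,
) -> tuple[DifferentialTable, DifferentialTable]:
    """Paired disease/drug logFC tables with a planted concordant set.

    Concordant genes receive nonzero logFC of random sign (magnitude
    uniform in [0.5, 1.5] x ``effect_size``) in *both* tables; every
    other gene is zero in at least one table, so selecting genes that
    are differential in both recovers exactly the planted set at
    threshold 0.  ``effect_size = 0`` collapses everything to zero.
    """
    concordant = {str(g) for g in concordant_genes}
    genes = [str(g) for g in all_genes]
    if not concordant <= set(genes):
        raise ValueError("concordant_genes must be a subset of all_genes")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    rng = np.random.default_rng(seed)
    disease: dict[str, float] = {}
    drug: dict[str, float] = {}

    def draw() -> float:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return float(sign * effect_size * rng.uniform(0.5, 1.5))

    for g in genes:
        if g in concordant:
            disease[g] = draw()
            drug[g] = draw()
        else:
            kind = rng.integers(0, 3)
            disease[g] = draw() if kind == 0 else 0.0
            drug[g] = draw() if kind == 1 else 0.0
    return (
        DifferentialTable(disease, condition_label="disease"),
        DifferentialTable(drug, condition_label="drug"),
    )


def simulate_annotation(
    modules: dict[str, Sequence[str]],
    enriched_terms_per_module: int = 2,
    n_background_genes: int = 500,
    n_noise_terms: int = 20,
    seed: int = 0,
    namespaces: Sequence[str] = ("BP", "MF", "CC", "PATHWAY"),
    background_annotation_frac: float = 0.01,
) -> AnnotationMap:
    """Annotation map with terms planted to be enriched in each module.

    Every designated module gets ``enriched_terms_per_module`` planted
    terms per namespace, each annotating all of the module's genes plus
    a small random background fraction — a configuration whose
    hypergeometric tail is far below conventional significance for
    modules of three or more genes.  Noise terms annotate random
    background subsets.
    """
    rng = np.random.default_rng(seed)
    module_genes = sorted({str(g) for gs in modules.values() for g in gs})
    filler = [f"b{i:04d}" for i in range(n_background_genes)]
    background = sorted(set(module_genes) | set(filler))
    gene_terms: dict[str, set[tuple[str, str]]] = {g: set() for g in background}

    for mod_id in sorted(modules):
        genes = [str(g) for g in modules[mod_id]]
        for ns in namespaces:
            for t in range(enriched_terms_per_module):
                term = f"{ns}:{mod_id}:planted{t}"
                extra_n = max(1, int(background_annotation_frac * len(filler)))
                extras = rng.choice(filler, size=extra_n, replace=False)
                for g in list(genes) + list(extras):
                    gene_terms[g].add((ns, term))

    for t in range(n_noise_terms):
        ns = namespaces[int(rng.integers(0, len(namespaces)))]
        term = f"{ns}:noise{t}"
        size = int(rng.integers(3, max(4, len(background) // 10)))
        for g in rng.choice(background, size=size, replace=False):
            gene_terms[str(g)].add((ns, term))

    gene_terms = {g: ts for g, ts in gene_terms.items() if ts}
    return AnnotationMap(gene_terms=gene_terms, background=set(background))


# -- published fixture -------------------------------------------------

_TABLE1_RAW = {
    "M1": "890 7153 4085 6241 701 22974 6790 3161 11130 10403 6240 10051 51203 "
    "1434 1719 3832 7298 5984 10592 4173 891 9319 2237 3838 990 47 90 87",
    "M2": "7520 142 1019 5111 5591 6749 2237 5036 4522 6241 4175 10606 5982 1736",
    "M3": "22948 10213 10969 471 1434 3329 5686 1503 9221 908 5901 5036 3838 7371",
    "M4": "5901 7334 7520 7443 10576 7153 10213 26135 6636 6427 5902 6428 6240",
    "M5": "22948 7203 6950 10574 11222 1164 4830 7334",
    "M6": "4172 6627 1503 10528 11130 2237 7398 9521 5985",
    "M7": "6426 4436 10772 10236 3838 26135 1665 23165 10576 7520",
    "M8": "7153 5557 6790 672 8317 10733 4001 1736",
    "M9": "6426 9221 6434 7334 3015 1736 2237 3184 2956 6427",
    "M10": "10574 158 7965 142 1503 7411 4176 1736 8607 7203 5901 5902",
    "M11": "6637 5111 3148 3182 6434",
    "M12": "1434 3308 908 4869 6950 7203 3336 3838",
    "M13": "10492 1503 3182",
    "M14": "3276 5725 3609 6597 4176 6627",
    "M15": "6194 6124 6201 6137 11224 6143 6193 6217 6152 6139 6136 6161 23521 "
    "6133 6175 4736 6207 6218 6135 6128 6146 3646 1933 47 87 39 29 90 95",
    "M16": "3014 84823 6597 5036",
    "M17": "3065 142 1786 6597",
    "M18": "3066 3065 5928 2146 6597",
    "M19": "86 6597 10856",
    "M20": "6597 6599 5591 4173 4172",
    "M21": "6597 23246 8662",
    "M22": "5036 10574 3182",
    "M23": "3329 7203 6428",
    "M24": "10606 6950 4691 3183 6741 3843 5901",
    "M25": "890 7371 3251 1665",
    "M26": "5557 990 9493 9833 1060",
}

# checksum of the canonical serialization, committed with the fixture
TABLE1_SHA256 = "d8fc846721e885ad322143e9dc32a1a294ffc60c10b3f5f20cb5137ec0037d1f"


def table1_fixture() -> dict[str, list[str]]:
    """The 26 published candidate drug-target modules (Entrez id lists)."""
    return {mod: raw.split() for mod, raw in _TABLE1_RAW.items()}


def table1_checksum() -> str:
    """SHA-256 of the fixture's canonical serialization (integrity check)."""
    canonical = json.dumps(table1_fixture(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
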