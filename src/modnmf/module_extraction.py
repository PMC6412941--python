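"""Turn a fitted joint factorization into discrete multi-layer modules.

Each factorization component k defines a module. Factor loadings are
Z-score normalized (each W column over its M mRNAs, each H_I row over its
N_I entities), and module members are the top-k% ranked entities per axis.
The percentage k is chosen per module from 1..10 by maximizing the number
of GO BP terms enriched (BH-adjusted p < 0.05) in the top-k% mRNAs; the
same chosen k is then applied to the circRNA, miRNA and pathway axes.
Modules with more than ``functional_min_terms`` enriched terms are flagged
functional; only those feed candidate scoring downstream. Modules may
overlap — an entity can belong to several components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .enrichment import EnrichmentResult, hypergeom_enrich
from .io_formats import GeneSetCollection
from .joint_nmf import JointFactorization
from .preprocess import BinaryRelationMatrix

__all__ = [
    "Module",
    "ModuleSet",
    "zscore_normalize",
    "assign_members",
    "collect_edges",
    "screen_functional",
]

_KINDS = ("mRNA", "circRNA", "miRNA", "pathway")


@dataclass
class Module:
    index: int
    members: dict[str, list[tuple[str, float]]]  # kind -> [(id, z_score)]
    chosen_top_percent: int
    enriched_terms: list[EnrichmentResult] = field(default_factory=list)
    edges: list[tuple[str, str]] = field(default_factory=list)
    is_functional: bool = False

    def member_ids(self, kind: str) -> set[str]:
        return {mid for mid, _ in self.members.get(kind, [])}

    @property
    def n_enriched(self) -> int:
        return sum(1 for t in self.enriched_terms if t.adjusted_p < 0.05)


@dataclass
class ModuleSet:
    modules: list[Module]
    universe: dict[str, list[str]]  # kind -> all IDs on that axis

    @property
    def functional(self) -> list[Module]:
        return [m for m in self.modules if m.is_functional]


def zscore_normalize(fact: JointFactorization
                     ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Standardize each W column over its M entries and each H_I row over
    its N_I entries, using the sample standard deviation (ddof=1).

    A zero-variance column/row yields all-zero z-scores (never NaN), which
    keeps those entities out of the top ranks.
    """
    def _std(mat: np.ndarray, axis: int) -> np.ndarray:
        mu = mat.mean(axis=axis, keepdims=True)
        n = mat.shape[axis]
        sd = mat.std(axis=axis, ddof=1, keepdims=True) if n > 1 else np.zeros_like(mu)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mat - mu) / sd
        return np.where(sd == 0, 0.0, z)

    Zw = _std(fact.W, axis=0)
    Zh = [_std(Hi, axis=1) for Hi in fact.H]
    return Zw, Zh


def _top_ids(z: np.ndarray, ids: list[str], n: int) -> list[str]:
    """Top-n IDs by z descending; rank ties broken lexicographically by ID."""
    order = sorted(range(len(ids)), key=lambda i: (-z[i], ids[i]))
    return [ids[i] for i in order[:n]]


def assign_members(
    fact: JointFactorization,
    annotation: GeneSetCollection,
    percents: range = range(1, 11),
    enrichment_fdr: float = 0.05,
    min_set_size: int = 3,
    max_set_size: int = 2000,
) -> ModuleSet:
    """Assign top-k% members to each module, choosing k per module by the
    enrichment of its top-k% mRNAs against the GO BP ``annotation``.

    For each component, every k in ``percents`` is tried: the ceil(k% x M)
    highest-z mRNAs are tested with :func:`hypergeom_enrich` and the k with
    the most terms at adjusted_p < ``enrichment_fdr`` wins (ties toward
    smaller k). Member counts per axis are ceil(k% x axis size), minimum 1.
    """
    if not annotation.sets:
        raise ValueError("empty annotation collection")
    if not fact.mrna_ids:
        raise ValueError("factorization carries no entity IDs; fit it on "
                         "BinaryRelationMatrix inputs")
    Zw, Zh = zscore_normalize(fact)
    mrna_ids = fact.mrna_ids
    universe = set(mrna_ids)
    annotation = annotation.restricted_to(universe)
    if not annotation.sets:
        raise ValueError("annotation has no overlap with the mRNA universe")
    M = len(mrna_ids)

    kind_of_layer = {layer: layer for layer in fact.layers}
    modules: list[Module] = []
    for k_idx in range(fact.K):
        z_col = Zw[:, k_idx]
        best_k = None
        best_count = -1
        best_results: list[EnrichmentResult] = []
        best_mrnas: list[str] = []
        for pct in percents:
            n_top = max(1, math.ceil(pct / 100 * M))
            top = _top_ids(z_col, mrna_ids, n_top)
            results = hypergeom_enrich(set(top), annotation, universe,
                                       min_set_size=min_set_size,
                                       max_set_size=max_set_size)
            count = sum(1 for r in results if r.adjusted_p < enrichment_fdr)
            if count > best_count:
                best_k, best_count, best_results, best_mrnas = pct, count, results, top
        assert best_k is not None

        z_of = dict(zip(mrna_ids, z_col))
        members: dict[str, list[tuple[str, float]]] = {
            "mRNA": [(m, float(z_of[m])) for m in best_mrnas]}
        for layer, ids, Zi in zip(fact.layers, fact.entity_ids, Zh):
            z_row = Zi[k_idx, :]
            n_top = max(1, math.ceil(best_k / 100 * len(ids)))
            top = _top_ids(z_row, ids, n_top)
            zr = dict(zip(ids, z_row))
            members[kind_of_layer[layer]] = [(e, float(zr[e])) for e in top]

        modules.append(Module(
            index=k_idx,
            members=members,
            chosen_top_percent=best_k,
            enriched_terms=sorted(best_results, key=lambda r: (r.raw_p, r.term_id)),
        ))

    uni = {"mRNA": list(mrna_ids)}
    for layer, ids in zip(fact.layers, fact.entity_ids):
        uni[layer] = list(ids)
    return ModuleSet(modules=modules, universe=uni)


def collect_edges(mods: ModuleSet, X: list[BinaryRelationMatrix]) -> ModuleSet:
    """Record, per module, every 1-cell of the relation layers whose entity
    and mRNA are both module members (the within-module bipartite edges)."""
    for mod in mods.modules:
        mrnas = mod.member_ids("mRNA")
        edges: list[tuple[str, str]] = []
        for x in X:
            entities = mod.member_ids(x.layer)
            col_idx = {c: j for j, c in enumerate(x.col_ids)}
            wanted_cols = sorted(mrnas & set(x.col_ids))
            for e in sorted(entities):
                if e not in x.row_ids:
                    continue
                row = x.cells[x.row_ids.index(e), :]
                for m in wanted_cols:
                    if row[col_idx[m]] == 1:
                        edges.append((e, m))
        mod.edges = edges
    return mods


def screen_functional(mods: ModuleSet, min_terms: int = 10,
                      enrichment_fdr: float = 0.05) -> ModuleSet:
    """Flag modules with strictly more than ``min_terms`` enriched terms
    (adjusted_p < ``enrichment_fdr``) as functional. Non-functional modules
    stay in the set but are excluded from candidate scoring."""
    for mod in mods.modules:
        n = sum(1 for t in mod.enriched_terms if t.adjusted_p < enrichment_fdr)
        mod.is_functional = n > min_terms
    return mods
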