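"""NTO similarity between circRNAs and pathways/miRNAs, and prioritization
of disease-candidate circRNAs.

The normalized term overlap of two mRNA sets is

    NTO(E_G, E_T) = |E_G n E_T| / min(|E_G|, |E_T|)

where E_G is the mRNA partner set of a circRNA (its co-expression row) and
E_T the mRNA set of a pathway or the target set of a miRNA, all restricted
to the common mRNA axis. A circRNA in a functional module is a disease
candidate when it has strictly more than ``min_partners`` (default 4)
direct partners, pooled across functional modules: co-member known disease
genes linked by a co-expression edge, co-member known disease miRNAs with
NTO >= 0.5, and co-member pathways with NTO >= 0.5 (optionally restricted
to a known-pathway list).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .module_extraction import ModuleSet
from .preprocess import BinaryRelationMatrix

__all__ = ["NtoScore", "CandidateReport", "nto", "score_pairs",
           "prioritize_candidates"]

logger = logging.getLogger(__name__)


@dataclass
class NtoScore:
    circ_id: str
    partner_id: str
    partner_kind: str  # pathway or miRNA
    nto: float
    overlap: int


@dataclass
class CandidateReport:
    circ_id: str
    module_indices: list[int]
    partners: list[tuple[str, str]]  # (partner_id, kind)
    partner_count: int
    is_candidate: bool


def nto(eg: set[str], et: set[str]) -> float:
    """|eg n et| / min(|eg|, |et|); both sets must be non-empty."""
    if not eg or not et:
        raise ValueError("NTO is undefined for an empty mRNA set")
    return len(eg & et) / min(len(eg), len(et))


def _partner_sets(X: list[BinaryRelationMatrix]) -> dict[str, dict[str, set[str]]]:
    """layer -> entity -> set of linked mRNAs, on the common axis."""
    out: dict[str, dict[str, set[str]]] = {}
    for x in X:
        cols = np.asarray(x.col_ids, dtype=object)
        out[x.layer] = {
            r: set(cols[x.cells[i, :] == 1]) for i, r in enumerate(x.row_ids)}
    return out


def score_pairs(mods: ModuleSet, X: list[BinaryRelationMatrix],
                min_nto: float = 0.5) -> list[NtoScore]:
    """NTO scores for every within-module (circRNA, pathway) and
    (circRNA, miRNA) co-member pair, keeping pairs with nto >= ``min_nto``
    (inclusive). Pairs where either mRNA set is empty are skipped and
    logged. Each (circRNA, partner) pair is reported once even if the pair
    co-occurs in several modules."""
    psets = _partner_sets(X)
    seen: set[tuple[str, str]] = set()
    scores: list[NtoScore] = []
    n_skipped = 0
    for mod in mods.modules:
        circs = sorted(mod.member_ids("circRNA"))
        for kind in ("miRNA", "pathway"):
            partners = sorted(mod.member_ids(kind))
            for c in circs:
                eg = psets.get("circRNA", {}).get(c, set())
                for p in partners:
                    if (c, p) in seen:
                        continue
                    seen.add((c, p))
                    et = psets.get(kind, {}).get(p, set())
                    if not eg or not et:
                        n_skipped += 1
                        continue
                    val = nto(eg, et)
                    if val >= min_nto:
                        scores.append(NtoScore(
                            circ_id=c, partner_id=p, partner_kind=kind,
                            nto=val, overlap=len(eg & et)))
    if n_skipped:
        logger.info("score_pairs: skipped %d pairs with an empty mRNA set",
                    n_skipped)
    scores.sort(key=lambda s: (s.circ_id, s.partner_kind, s.partner_id))
    return scores


def prioritize_candidates(
    mods: ModuleSet,
    X: list[BinaryRelationMatrix],
    ntos: list[NtoScore],
    known_genes: set[str],
    known_mirnas: set[str],
    min_partners: int = 4,
    known_pathways: set[str] | None = None,
    per_module: bool = False,
) -> list[CandidateReport]:
    """Rank circRNAs of functional modules by their direct-partner counts.

    Partners of a circRNA are (i) co-member known disease genes it is
    linked to by a circRNA-mRNA edge, (ii) co-member known disease miRNAs
    with NTO >= the score threshold, (iii) co-member pathways with NTO >=
    the threshold (restricted to ``known_pathways`` when given). Partners
    are pooled and deduplicated across functional modules by default;
    ``per_module=True`` instead requires the count within a single module
    to clear ``min_partners``. A circRNA is a candidate when its partner
    count strictly exceeds ``min_partners``.
    """
    if not known_genes and not known_mirnas:
        logger.warning("prioritize_candidates: empty known-gene and known-miRNA "
                       "lists; candidates judged on pathway partners only")
    psets = _partner_sets(X)
    nto_ok = {(s.circ_id, s.partner_id, s.partner_kind) for s in ntos}

    per_circ_modules: dict[str, list[int]] = {}
    per_circ_partners: dict[str, dict[int, set[tuple[str, str]]]] = {}
    for mod in mods.functional:
        mrna_members = mod.member_ids("mRNA")
        mirna_members = mod.member_ids("miRNA")
        path_members = mod.member_ids("pathway")
        if known_pathways is not None:
            path_members &= known_pathways
        for c in sorted(mod.member_ids("circRNA")):
            per_circ_modules.setdefault(c, []).append(mod.index)
            partners = per_circ_partners.setdefault(c, {}).setdefault(mod.index, set())
            linked = psets.get("circRNA", {}).get(c, set())
            for g in sorted(known_genes & mrna_members & linked):
                partners.add((g, "known_gene"))
            for mi in sorted(known_mirnas & mirna_members):
                if (c, mi, "miRNA") in nto_ok:
                    partners.add((mi, "known_miRNA"))
            for p in sorted(path_members):
                if (c, p, "pathway") in nto_ok:
                    partners.add((p, "pathway"))

    reports: list[CandidateReport] = []
    for c in sorted(per_circ_modules):
        by_module = per_circ_partners[c]
        pooled: set[tuple[str, str]] = set().union(*by_module.values())
        if per_module:
            count = max(len(p) for p in by_module.values())
        else:
            count = len(pooled)
        reports.append(CandidateReport(
            circ_id=c,
            module_indices=sorted(per_circ_modules[c]),
            partners=sorted(pooled),
            partner_count=count,
            is_candidate=count > min_partners,
        ))
    reports.sort(key=lambda r: (-r.partner_count, r.circ_id))
    return reports
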