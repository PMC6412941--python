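"""Filter cascade turning expression tables and edge lists into aligned
binary relation matrices over a common mRNA axis.

The cascade mirrors the usual construction of multi-layer incidence data
for joint factorization:

1. keep features expressed (value > 0) in strictly more than half the
   samples;
2. keep differentially expressed features by fold change (case/control
   mean ratio outside [fc_low, fc_high]), optionally with a rank-based
   two-sample test on top (used for the miRNA layer);
3. link circRNAs to mRNAs by Pearson co-expression (r > 0.4, p < 0.05);
4. binarize each relation layer and drop mRNAs with fewer than
   ``min_degree`` partners (strictly "more than three" => degree >= 4);
5. restrict all three layers to their common mRNA columns.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import EdgeList, ExpressionMatrix

__all__ = [
    "DifferentialResult",
    "BinaryRelationMatrix",
    "CoexpressionEdge",
    "expressed_fraction_filter",
    "differential_screen",
    "coexpression_edges",
    "degree_filter",
    "align_common_mrnas",
]

logger = logging.getLogger(__name__)


@dataclass
class DifferentialResult:
    feature_id: str
    fold_change: float
    p_value: float | None
    expressed_fraction: float
    passed: bool


@dataclass
class CoexpressionEdge:
    circ_id: str
    mrna_id: str
    pcc: float
    p_value: float


@dataclass
class BinaryRelationMatrix:
    """0/1 incidence matrix between one entity layer and the mRNA axis."""

    row_ids: list[str]
    col_ids: list[str]
    cells: np.ndarray
    layer: str  # circRNA, miRNA or pathway

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"cells shape {self.cells.shape} does not match "
                f"{len(self.row_ids)} x {len(self.col_ids)}"
            )
        if not np.isin(self.cells, (0.0, 1.0)).all():
            raise ValueError("cells must be 0/1")

    def row_partners(self, row_id: str) -> set[str]:
        """mRNAs linked to ``row_id``."""
        i = self.row_ids.index(row_id)
        return {self.col_ids[j] for j in np.nonzero(self.cells[i, :])[0]}


def expressed_fraction_filter(m: ExpressionMatrix, min_fraction: float = 0.5) -> list[str]:
    """Features whose fraction of samples with value > 0 strictly exceeds
    ``min_fraction``."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    frac = (m.values > 0).mean(axis=1)
    return [f for f, fr in zip(m.feature_ids, frac) if fr > min_fraction]


def differential_screen(
    m: ExpressionMatrix,
    fc_low: float = 0.5,
    fc_high: float = 2.0,
    p_cut: float | None = None,
    pseudocount: float = 0.25,
    min_expressed_fraction: float = 0.5,
    paired: bool = False,
) -> list[DifferentialResult]:
    """Fold-change (and optional rank-test) screen of case vs control.

    fold_change = (mean case + pseudocount) / (mean control + pseudocount).
    A feature passes when FC > fc_high or FC < fc_low, its expressed
    fraction is >= min_expressed_fraction, and — if ``p_cut`` is given —
    its two-sample rank test p-value is below ``p_cut``.  The default test
    is the unpaired Mann-Whitney rank-sum; ``paired=True`` switches to the
    Wilcoxon signed-rank test (requires equal group sizes).
    """
    if fc_low >= fc_high:
        raise ValueError("fc_low must be < fc_high")
    case_cols = m.case_columns
    ctrl_cols = m.control_columns
    if case_cols.size == 0 or ctrl_cols.size == 0:
        raise ValueError("both groups must have at least one sample")
    if paired and case_cols.size != ctrl_cols.size:
        raise ValueError("paired test requires equal group sizes")

    case = m.values[:, case_cols]
    ctrl = m.values[:, ctrl_cols]
    fc = (case.mean(axis=1) + pseudocount) / (ctrl.mean(axis=1) + pseudocount)
    frac = (m.values > 0).mean(axis=1)

    results = []
    for i, fid in enumerate(m.feature_ids):
        p: float | None = None
        if p_cut is not None:
            if paired:
                diff = case[i] - ctrl[i]
                if np.all(diff == 0):
                    p = 1.0
                else:
                    p = float(stats.wilcoxon(case[i], ctrl[i]).pvalue)
            else:
                p = float(stats.mannwhitneyu(case[i], ctrl[i],
                                             alternative="two-sided").pvalue)
        passed = (fc[i] > fc_high or fc[i] < fc_low) and frac[i] >= min_expressed_fraction
        if p_cut is not None:
            passed = passed and p < p_cut
        results.append(DifferentialResult(
            feature_id=fid,
            fold_change=float(fc[i]),
            p_value=p,
            expressed_fraction=float(frac[i]),
            passed=bool(passed),
        ))
    return results


def _pearson_p_exact(x: np.ndarray, y: np.ndarray, r: float) -> float:
    """Two-sided exact permutation p-value for Pearson r (tiny n only)."""
    n = len(x)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rp = np.corrcoef(x, y[list(perm)])[0, 1]
        if abs(rp) >= abs(r) - 1e-12:
            count += 1
        total += 1
    return count / total


def coexpression_edges(
    circ: ExpressionMatrix,
    mrna: ExpressionMatrix,
    pcc_cut: float = 0.4,
    p_cut: float = 0.05,
    method: str = "t",
) -> list[CoexpressionEdge]:
    """Pearson co-expression edges between circRNAs and mRNAs.

    Retains pairs with r > ``pcc_cut`` (positive co-expression only) and
    p < ``p_cut``.  p is two-sided from the t transform
    t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom, or an exact
    permutation p with ``method='permutation'`` (intended for n < 8).
    Constant (zero-variance) features yield undefined r; those pairs are
    skipped and counted in a diagnostics log entry.
    """
    if circ.sample_ids != mrna.sample_ids:
        raise ValueError("circRNA and mRNA matrices must share an identical, "
                         "identically ordered sample set")
    n = len(circ.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")

    c = circ.values - circ.values.mean(axis=1, keepdims=True)
    g = mrna.values - mrna.values.mean(axis=1, keepdims=True)
    c_sd = np.sqrt((c ** 2).sum(axis=1))
    g_sd = np.sqrt((g ** 2).sum(axis=1))
    const_circ = c_sd == 0
    const_mrna = g_sd == 0
    n_skipped = int(const_circ.sum()) * len(mrna.feature_ids) + \
        int(const_mrna.sum()) * int((~const_circ).sum())
    if n_skipped:
        logger.info("coexpression_edges: skipped %d pairs with a constant feature",
                    n_skipped)

    with np.errstate(divide="ignore", invalid="ignore"):
        r = (c @ g.T) / np.outer(c_sd, g_sd)
    r = np.clip(r, -1.0, 1.0)

    edges = []
    cand = np.argwhere(r > pcc_cut)
    for i, j in cand:
        if const_circ[i] or const_mrna[j]:
            continue
        rij = float(r[i, j])
        if method == "permutation":
            p = _pearson_p_exact(circ.values[i], mrna.values[j], rij)
        else:
            if rij >= 1.0:
                p = 0.0
            else:
                t = rij * math.sqrt((n - 2) / (1 - rij ** 2))
                p = 2 * float(stats.t.sf(abs(t), n - 2))
        if p < p_cut:
            edges.append(CoexpressionEdge(
                circ_id=circ.feature_ids[i],
                mrna_id=mrna.feature_ids[j],
                pcc=rij,
                p_value=p,
            ))
    return edges


def degree_filter(
    edges: EdgeList | list[CoexpressionEdge],
    min_degree: int = 4,
    layer: str | None = None,
) -> BinaryRelationMatrix:
    """Build the 0/1 incidence matrix and drop mRNA columns whose degree is
    below ``min_degree`` (the default 4 encodes "more than three partners").

    The filter is a single pass over the mRNA axis; entity rows are kept even
    if they lose all partners (they are pruned later at the intersection
    step).
    """
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    if isinstance(edges, EdgeList):
        pairs = sorted(edges.pairs)
        layer = layer or edges.source_kind
    else:
        pairs = sorted((e.circ_id, e.mrna_id) for e in edges)
        layer = layer or "circRNA"
    row_ids = sorted({s for s, _ in pairs})
    col_ids = sorted({t for _, t in pairs})
    ri = {r: i for i, r in enumerate(row_ids)}
    ci = {c: j for j, c in enumerate(col_ids)}
    cells = np.zeros((len(row_ids), len(col_ids)))
    for s, t in pairs:
        cells[ri[s], ci[t]] = 1.0
    keep = cells.sum(axis=0) >= min_degree
    if not keep.any():
        raise ValueError("no mRNAs survive degree filter")
    return BinaryRelationMatrix(
        row_ids=row_ids,
        col_ids=[c for c, k in zip(col_ids, keep) if k],
        cells=cells[:, keep],
        layer=layer,
    )


def expand_columns(x: BinaryRelationMatrix, universe: list[str]) -> BinaryRelationMatrix:
    """Re-index ``x`` onto the full mRNA ``universe`` (missing columns become
    all-zero). Used when a serialized edge list cannot carry zero-degree
    mRNAs that are still part of the analysis axis."""
    missing = set(x.col_ids) - set(universe)
    if missing:
        raise ValueError(f"matrix has mRNAs outside the universe: "
                         f"{', '.join(sorted(missing)[:5])}")
    ci = {c: j for j, c in enumerate(x.col_ids)}
    cells = np.zeros((len(x.row_ids), len(universe)))
    for j, m in enumerate(universe):
        if m in ci:
            cells[:, j] = x.cells[:, ci[m]]
    return BinaryRelationMatrix(row_ids=list(x.row_ids), col_ids=list(universe),
                                cells=cells, layer=x.layer)


def align_common_mrnas(
    x1: BinaryRelationMatrix,
    x2: BinaryRelationMatrix,
    x3: BinaryRelationMatrix,
) -> tuple[BinaryRelationMatrix, BinaryRelationMatrix, BinaryRelationMatrix]:
    """Restrict all three relation layers to their common mRNA columns, in one
    canonical sorted order, dropping entity rows that become all-zero."""
    common = sorted(set(x1.col_ids) & set(x2.col_ids) & set(x3.col_ids))
    if not common:
        raise ValueError("empty mRNA intersection across the three layers")
    out = []
    for x in (x1, x2, x3):
        ci = {c: j for j, c in enumerate(x.col_ids)}
        cols = [ci[c] for c in common]
        cells = x.cells[:, cols]
        keep = cells.sum(axis=1) > 0
        out.append(BinaryRelationMatrix(
            row_ids=[r for r, k in zip(x.row_ids, keep) if k],
            col_ids=list(common),
            cells=cells[keep, :],
            layer=x.layer,
        ))
    return out[0], out[1], out[2]
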