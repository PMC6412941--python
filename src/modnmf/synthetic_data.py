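"""Synthetic instances with known ground truth for every pipeline stage.

Three generators cover the statistical structure the pipeline consumes:

* :func:`generate_expression` — group-labeled log-normal expression with
  planted differential features, for the fold-change / rank-test screens;
* :func:`generate_joint_layers` — three Bernoulli block-model relation
  layers over a shared mRNA axis (within-block edge probability ``p_in``,
  background ``p_out``), with an optional planted candidate circRNA wired
  to a set of known disease genes;
* :func:`generate_annotation` — a GO-BP-like gene-set collection per
  planted block: one broad near-block set plus many small granular subsets
  (mimicking specific GO terms), so that covering more of a block enriches
  more terms, plus random noise sets.

All generators are pure functions of their parameters and seed, and every
parameter needed to regenerate an instance is stored in the returned
:class:`SyntheticTruth`.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import EdgeList, ExpressionMatrix, GeneSetCollection
from .preprocess import BinaryRelationMatrix

__all__ = [
    "SyntheticTruth",
    "generate_expression",
    "generate_joint_layers",
    "generate_annotation",
    "generate_bundle",
]


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic instance."""

    mrna_blocks: list[list[str]] = field(default_factory=list)
    circ_blocks: list[list[str]] = field(default_factory=list)
    mirna_blocks: list[list[str]] = field(default_factory=list)
    pathway_blocks: list[list[str]] = field(default_factory=list)
    de_circs: list[str] = field(default_factory=list)
    de_mirnas: list[str] = field(default_factory=list)
    known_genes: list[str] = field(default_factory=list)
    known_mirnas: list[str] = field(default_factory=list)
    planted_candidates: list[str] = field(default_factory=list)
    seed: int = 0
    generator_params: dict = field(default_factory=dict)

    def block_of(self, axis: str) -> dict[str, int]:
        """Map entity ID -> planted block index for one axis."""
        blocks = getattr(self, f"{axis}_blocks")
        return {e: b for b, members in enumerate(blocks) for e in members}

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def generate_expression(
    n_features: int,
    n_case: int = 15,
    n_control: int = 18,
    n_de: int = 0,
    effect_fc: float = 4.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    feature_prefix: str = "feat",
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Log-normal expression with ``n_de`` planted differential features.

    Each feature i has values exp(mu_i + N(0, noise_sd)); the first half of
    the DE features have case values multiplied by ``effect_fc``, the second
    half by 1/``effect_fc``. Truth records the DE IDs under ``de_circs``.
    """
    if n_de > n_features:
        raise ValueError("n_de must be <= n_features")
    if effect_fc <= 1:
        raise ValueError("effect_fc must be > 1")
    rng = np.random.default_rng(seed)
    feature_ids = [f"{feature_prefix}_{i:04d}" for i in range(n_features)]
    n_samples = n_case + n_control
    sample_ids = [f"case_{i:02d}" for i in range(n_case)] + \
        [f"ctrl_{i:02d}" for i in range(n_control)]
    group_of = {s: ("case" if s.startswith("case") else "control")
                for s in sample_ids}

    mu = rng.normal(2.0, 1.0, size=n_features)
    values = np.exp(mu[:, None] + rng.normal(0.0, noise_sd, (n_features, n_samples)))
    de_ids = feature_ids[:n_de]
    n_up = (n_de + 1) // 2
    values[:n_up, :n_case] *= effect_fc
    values[n_up:n_de, :n_case] /= effect_fc

    truth = SyntheticTruth(
        de_circs=list(de_ids),
        seed=seed,
        generator_params={
            "n_features": n_features, "n_case": n_case, "n_control": n_control,
            "n_de": n_de, "effect_fc": effect_fc, "noise_sd": noise_sd,
        },
    )
    m = ExpressionMatrix(feature_ids=feature_ids, sample_ids=sample_ids,
                         values=values, group_of=group_of)
    return m, truth


def _partition(ids: list[str], k: int, block_size: int) -> list[list[str]]:
    """First k*block_size IDs split into k blocks; the rest is background."""
    if k * block_size > len(ids):
        raise ValueError("blocks do not fit on the axis")
    return [ids[b * block_size:(b + 1) * block_size] for b in range(k)]


def generate_joint_layers(
    M: int = 300,
    n_circ: int = 33,
    n_mirna: int = 27,
    n_pathway: int = 18,
    K_true: int = 3,
    p_in: float = 0.8,
    p_out: float = 0.02,
    seed: int = 0,
    mrna_block_size: int | None = None,
    plant_candidate: bool = True,
    n_known_genes: int = 8,
    n_known_mirnas: int = 2,
    min_degree: int = 4,
) -> tuple[BinaryRelationMatrix, BinaryRelationMatrix, BinaryRelationMatrix,
           SyntheticTruth]:
    """Three Bernoulli block-model relation layers over a shared mRNA axis.

    ``K_true`` planted blocks partition part of each axis (mRNA blocks of
    ``mrna_block_size``, default 10% of M; entity blocks of floor(0.9*n/K)
    each, remainder background); a cell (entity, mRNA) is 1 with probability
    ``p_in`` inside a block and ``p_out`` elsewhere.

    With ``plant_candidate``, one circRNA of block 0 is wired to every
    block-0 mRNA, ``n_known_genes`` block-0 mRNAs are declared known disease
    genes, and every other circRNA's edges to those genes are removed — so
    the planted circRNA is the only one that can accumulate known-gene
    partners. ``n_known_mirnas`` background miRNAs are declared known
    disease miRNAs (they carry no block structure and therefore exercise the
    miRNA-partner code path without creating partners).

    A parameter combination whose expected within-block mRNA degree falls
    below ``min_degree`` triggers a warning, since such columns would not
    survive the pipeline's degree filter.
    """
    if p_in < p_out:
        raise ValueError("p_in must be >= p_out")
    rng = np.random.default_rng(seed)
    if mrna_block_size is None:
        mrna_block_size = max(1, round(0.10 * M))

    mrna_ids = [f"mRNA_{i:04d}" for i in range(M)]
    circ_ids = [f"circ_{i:03d}" for i in range(n_circ)]
    mirna_ids = [f"miR_{i:03d}" for i in range(n_mirna)]
    path_ids = [f"path_{i:03d}" for i in range(n_pathway)]

    mrna_blocks = _partition(mrna_ids, K_true, mrna_block_size)
    circ_blocks = _partition(circ_ids, K_true, max(2, int(0.9 * n_circ / K_true)))
    mirna_blocks = _partition(mirna_ids, K_true, max(2, int(0.9 * n_mirna / K_true)))
    path_blocks = _partition(path_ids, K_true, max(2, n_pathway // K_true))

    min_block_entities = min(len(b) for bl in (circ_blocks, mirna_blocks)
                             for b in bl)
    if min_block_entities * p_in < min_degree:
        import warnings
        warnings.warn(
            f"expected within-block mRNA degree {min_block_entities * p_in:.1f} "
            f"is below min_degree={min_degree}; block mRNAs may not survive "
            "the degree filter", stacklevel=2)

    def _layer(entity_ids: list[str], entity_blocks: list[list[str]],
               layer: str) -> BinaryRelationMatrix:
        eb = {e: b for b, members in enumerate(entity_blocks) for e in members}
        mb = {m: b for b, members in enumerate(mrna_blocks) for m in members}
        prob = np.full((len(entity_ids), M), p_out)
        for i, e in enumerate(entity_ids):
            if e in eb:
                for j, m in enumerate(mrna_ids):
                    if mb.get(m) == eb[e]:
                        prob[i, j] = p_in
        cells = (rng.random((len(entity_ids), M)) < prob).astype(float)
        return BinaryRelationMatrix(row_ids=list(entity_ids),
                                    col_ids=list(mrna_ids),
                                    cells=cells, layer=layer)

    x1 = _layer(circ_ids, circ_blocks, "circRNA")
    x2 = _layer(mirna_ids, mirna_blocks, "miRNA")
    x3 = _layer(path_ids, path_blocks, "pathway")

    known_genes: list[str] = []
    known_mirnas: list[str] = []
    candidates: list[str] = []
    if plant_candidate:
        cand = circ_blocks[0][0]
        candidates = [cand]
        known_genes = mrna_blocks[0][:n_known_genes]
        ci = {c: i for i, c in enumerate(circ_ids)}
        mj = {m: j for j, m in enumerate(mrna_ids)}
        # the candidate covers its whole block ...
        for m in mrna_blocks[0]:
            x1.cells[ci[cand], mj[m]] = 1.0
        # ... and is the only circRNA linked to the known genes
        for c in circ_ids:
            if c != cand:
                for g in known_genes:
                    x1.cells[ci[c], mj[g]] = 0.0
        in_blocks = {e for bl in mirna_blocks for e in bl}
        known_mirnas = [m for m in mirna_ids if m not in in_blocks][:n_known_mirnas]

    truth = SyntheticTruth(
        mrna_blocks=mrna_blocks,
        circ_blocks=circ_blocks,
        mirna_blocks=mirna_blocks,
        pathway_blocks=path_blocks,
        known_genes=list(known_genes),
        known_mirnas=list(known_mirnas),
        planted_candidates=candidates,
        seed=seed,
        generator_params={
            "M": M, "n_circ": n_circ, "n_mirna": n_mirna,
            "n_pathway": n_pathway, "K_true": K_true, "p_in": p_in,
            "p_out": p_out, "mrna_block_size": mrna_block_size,
            "plant_candidate": plant_candidate,
            "n_known_genes": n_known_genes, "n_known_mirnas": n_known_mirnas,
        },
    )
    return x1, x2, x3, truth


def generate_annotation(
    truth: SyntheticTruth,
    n_noise_sets: int = 20,
    seed: int = 0,
    n_granular: int = 12,
    padding_frac: float = 0.1,
) -> GeneSetCollection:
    """GO-BP-like annotation matched to the planted mRNA blocks.

    Per block: one broad set (the block plus ~``padding_frac`` random
    outside genes) and ``n_granular`` small granular sets of 3-4 genes
    subsampled from the block (a fourth outside gene on every other set).
    Small sets only turn significant once the query covers essentially all
    of their genes, so the number of enriched terms grows as a module's
    top-k% sweep covers more of its block — which is what drives the
    top-percent choice. ``n_noise_sets`` random sets model unrelated terms.
    """
    if not truth.mrna_blocks:
        raise ValueError("truth carries no planted mRNA blocks")
    rng = np.random.default_rng(seed)
    universe = sorted({m for b in truth.mrna_blocks for m in b})
    all_ids = universe
    # outside pool: regenerate the full axis from generator params if present
    M = truth.generator_params.get("M")
    if M:
        all_ids = [f"mRNA_{i:04d}" for i in range(M)]
    outside = sorted(set(all_ids) - set(universe))

    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for b, block in enumerate(truth.mrna_blocks):
        n_pad = max(1, round(padding_frac * len(block)))
        pad = list(rng.choice(outside, size=min(n_pad, len(outside)),
                              replace=False)) if outside else []
        sets[f"GO_B{b}_BROAD"] = set(block) | set(pad)
        desc[f"GO_B{b}_BROAD"] = f"broad term for planted block {b}"
        for j in range(n_granular):
            core = list(rng.choice(block, size=3, replace=False))
            members = set(core)
            if j % 2 == 1 and outside:
                members.add(str(rng.choice(outside)))
            sets[f"GO_B{b}_G{j:02d}"] = members
            desc[f"GO_B{b}_G{j:02d}"] = f"granular term {j} for block {b}"
    for j in range(n_noise_sets):
        size = int(rng.integers(5, 26))
        sets[f"GO_NOISE_{j:02d}"] = set(rng.choice(all_ids, size=size,
                                                   replace=False))
        desc[f"GO_NOISE_{j:02d}"] = "random noise term"
    return GeneSetCollection(sets=sets, description=desc)


def _bundle_expression(truth: SyntheticTruth, x2_rows: list[str], seed: int,
                       n_case: int = 15, n_control: int = 18,
                       effect_fc: float = 4.0, noise_sd: float = 0.3,
                       latent_weight: float = 0.8,
                       ) -> tuple[ExpressionMatrix, ExpressionMatrix,
                                  ExpressionMatrix, SyntheticTruth]:
    """Expression matrices whose co-expression structure realizes the planted
    blocks: mRNAs and circRNAs of block b share a per-sample latent factor,
    the known genes and the planted candidate share an extra latent, and all
    block circRNAs/miRNAs are differentially expressed so they survive the
    fold-change screens."""
    rng = np.random.default_rng(seed)
    n_samples = n_case + n_control
    sample_ids = [f"case_{i:02d}" for i in range(n_case)] + \
        [f"ctrl_{i:02d}" for i in range(n_control)]
    group_of = {s: ("case" if s.startswith("case") else "control")
                for s in sample_ids}
    case_mask = np.array([1.0] * n_case + [0.0] * n_control)

    K = len(truth.mrna_blocks)
    latents = rng.normal(0.0, 1.0, (K + 1, n_samples))  # last row: marker latent
    lshift = float(np.log(effect_fc))

    M = truth.generator_params["M"]
    mrna_ids = [f"mRNA_{i:04d}" for i in range(M)]
    mrna_block = truth.block_of("mrna")
    known = set(truth.known_genes)

    def _expr(ids, latent_of, de_sign):
        mu = rng.normal(2.0, 0.5, len(ids))
        vals = np.empty((len(ids), n_samples))
        for i, fid in enumerate(ids):
            log_v = mu[i] + rng.normal(0.0, noise_sd, n_samples)
            lat = latent_of(fid)
            if lat is not None:
                log_v = log_v + latent_weight * lat
            s = de_sign(fid)
            if s:
                log_v = log_v + s * lshift * case_mask
            vals[i] = np.exp(log_v)
        return vals

    mrna_vals = _expr(
        mrna_ids,
        lambda m: latents[K] if m in known
        else (latents[mrna_block[m]] if m in mrna_block else None),
        lambda m: 0,
    )
    mrna = ExpressionMatrix(mrna_ids, sample_ids, mrna_vals, dict(group_of))

    circ_block = truth.block_of("circ")
    cand = set(truth.planted_candidates)
    n_boost = 5
    circ_ids = [c for b in truth.circ_blocks for c in b]
    boosters = [f"circ_b{i:02d}" for i in range(n_boost)]
    decoys = [f"circ_d{i:02d}" for i in range(4)]
    all_circ = circ_ids + boosters + decoys
    # the candidate splits its loading between its block's latent and the
    # marker latent; a mild boost keeps both correlations above the PCC cut
    mix = 1.3 / np.sqrt(2.0)

    def circ_latent(c):
        if c in cand:
            return mix * (latents[0] + latents[K])
        if c.startswith("circ_b"):
            return latents[K]
        if c in circ_block:
            return latents[circ_block[c]]
        return None

    de_dir = {c: (1 if i % 2 == 0 else -1)
              for i, c in enumerate(circ_ids + boosters)}
    circ_vals = _expr(all_circ, circ_latent, lambda c: de_dir.get(c, 0))
    # decoys: not expressed in most samples, to exercise the fraction filter
    for i, c in enumerate(all_circ):
        if c in decoys:
            off = rng.choice(n_samples, size=int(0.6 * n_samples), replace=False)
            circ_vals[i, off] = 0.0
    circ = ExpressionMatrix(all_circ, sample_ids, circ_vals, dict(group_of))

    mirna_block = truth.block_of("mirna")
    mirna_vals = _expr(
        x2_rows,
        lambda m: latents[mirna_block[m]] if m in mirna_block else None,
        lambda m: (1 if m in mirna_block else 0),
    )
    mirna = ExpressionMatrix(list(x2_rows), sample_ids, mirna_vals,
                             dict(group_of))

    truth.de_circs = sorted(de_dir)
    truth.de_mirnas = sorted(mirna_block)
    return circ, mirna, mrna, truth


def generate_bundle(out_dir: str | os.PathLike, seed: int = 0,
                    **layer_kwargs) -> SyntheticTruth:
    """Write a complete input bundle (expression + relations + annotation +
    known lists + truth JSON + a ready-to-run config) to ``out_dir``.

    The relation layers carry the canonical planted-module and candidate
    structure; the expression matrices realize the same blocks as latent-
    factor co-expression with planted differential features, so the screen
    stages of the pipeline can be run on the bundle as well.
    """
    from . import io_formats as iof

    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    x1, x2, x3, truth = generate_joint_layers(seed=seed, **layer_kwargs)
    annotation = generate_annotation(truth, seed=seed + 1)
    circ, mirna, mrna, truth = _bundle_expression(truth, x2.row_ids, seed + 2)

    iof.write_expression(circ, os.path.join(out_dir, "circ_expr.tsv"))
    iof.write_expression(mirna, os.path.join(out_dir, "mirna_expr.tsv"))
    iof.write_expression(mrna, os.path.join(out_dir, "mrna_expr.tsv"))
    with open(os.path.join(out_dir, "groups.tsv"), "w") as fh:
        for s in circ.sample_ids:
            fh.write(f"{s}\t{circ.group_of[s]}\n")

    for x, name in ((x1, "x1_edges.tsv"), (x2, "mirna_targets.tsv")):
        with open(os.path.join(out_dir, name), "w") as fh:
            for i, r in enumerate(x.row_ids):
                for j in np.nonzero(x.cells[i])[0]:
                    fh.write(f"{r}\t{x.col_ids[j]}\n")
    pathway_sets = GeneSetCollection(
        sets={r: set(np.asarray(x3.col_ids, dtype=object)[x3.cells[i] == 1])
              for i, r in enumerate(x3.row_ids)
              if x3.cells[i].sum() > 0},
        description={r: "synthetic pathway" for r in x3.row_ids},
    )
    iof.write_gmt(pathway_sets, os.path.join(out_dir, "pathways.gmt"))
    iof.write_gmt(annotation, os.path.join(out_dir, "go_bp.gmt"))
    iof.write_id_list(set(truth.known_genes),
                      os.path.join(out_dir, "known_genes.txt"))
    iof.write_id_list(set(truth.known_mirnas),
                      os.path.join(out_dir, "known_mirnas.txt"))
    iof.write_id_list(set(x1.col_ids), os.path.join(out_dir, "mrna_universe.txt"))
    truth.to_json(os.path.join(out_dir, "truth.json"))

    config = {
        "inputs": {
            "x1_edges": "x1_edges.tsv",
            "mirna_targets": "mirna_targets.tsv",
            "pathways_gmt": "pathways.gmt",
            "go_bp_gmt": "go_bp.gmt",
            "known_genes": "known_genes.txt",
            "known_mirnas": "known_mirnas.txt",
            "mrna_universe": "mrna_universe.txt",
        },
        "k": truth.generator_params["K_true"],
        "n_restarts": 20,
        "relation_min_degree": 0,
        "seed": seed,
    }
    import yaml
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return truth
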