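"""Readers and writers for every external file the pipeline touches.

All parsing and validation happens here so the analysis modules only ever
see validated in-memory domain types: :class:`ExpressionMatrix` (feature x
sample table with case/control labels), :class:`EdgeList` (binary relations
such as miRNA->target edges) and :class:`GeneSetCollection` (GMT gene sets,
used both for pathways and for GO BP annotation).

Identifiers are compared case-sensitively; no symbol mapping is attempted —
ID harmonization is upstream curation, not pipeline logic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "EdgeList",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_edge_list",
    "read_gmt",
    "write_gmt",
    "read_id_list",
    "write_id_list",
    "write_module_report",
]

# group labels accepted in the sample-group file, normalized to case/control
_GROUP_ALIASES = {
    "case": "case",
    "tumor": "case",
    "tumour": "case",
    "disease": "case",
    "control": "control",
    "normal": "control",
}


@dataclass
class ExpressionMatrix:
    """Feature x sample expression table with a case/control label per sample.

    Values are non-negative expression units (e.g. RPKM or array intensity).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"unlabeled sample(s): {', '.join(missing)}")
        groups = {self.group_of[s] for s in self.sample_ids}
        if not groups <= {"case", "control"}:
            raise ValueError(f"unknown group label(s): {groups - {'case', 'control'}}")
        if groups != {"case", "control"}:
            raise ValueError("both case and control groups must be non-empty")
        if np.isnan(self.values).any():
            raise ValueError("NaN values in expression matrix")
        if (self.values < 0).any():
            raise ValueError("negative values in expression matrix")

    @property
    def case_columns(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.group_of[s] == "case"]
        )

    @property
    def control_columns(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.group_of[s] == "control"]
        )

    def subset_features(self, keep: list[str]) -> "ExpressionMatrix":
        """Restrict to ``keep`` features, preserving the given order."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[f] for f in keep]
        return ExpressionMatrix(
            feature_ids=list(keep),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
            group_of=dict(self.group_of),
        )


@dataclass
class EdgeList:
    """Set of (source, target) relations from one entity layer to mRNAs."""

    pairs: set[tuple[str, str]]
    source_kind: str  # miRNA, circRNA or pathway
    target_kind: str = "mRNA"

    def __post_init__(self) -> None:
        for s, t in self.pairs:
            if s == t:
                raise ValueError(f"self-pair {s!r}")

    @property
    def sources(self) -> set[str]:
        return {s for s, _ in self.pairs}

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.pairs}


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways or GO BP terms) with free-text descriptions."""

    sets: dict[str, set[str]]
    description: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, members in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set {sid!r}")

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping emptied sets."""
        sets = {}
        desc = {}
        for sid, members in self.sets.items():
            inter = members & universe
            if inter:
                sets[sid] = inter
                desc[sid] = self.description.get(sid, "")
        return GeneSetCollection(sets=sets, description=desc)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets


def read_expression(path: str | os.PathLike, groups_path: str | os.PathLike,
                    impute_zero: bool = False) -> ExpressionMatrix:
    """Load a TSV expression matrix (header = sample IDs, one feature per row)
    together with its sample-group file.

    Missing entries are a hard error unless ``impute_zero`` is set, in which
    case they become 0. Duplicate feature IDs, samples absent from the groups
    file and negative values are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ID(s) in {path}: {', '.join(map(str, dups))}")
    if df.isna().any().any():
        if impute_zero:
            df = df.fillna(0.0)
        else:
            raise ValueError(f"missing values in {path} (use impute_zero to convert to 0)")
    groups = _read_groups(groups_path)
    missing = [s for s in df.columns if s not in groups]
    if missing:
        raise ValueError(f"unlabeled sample(s) in {path}: {', '.join(missing)}")
    return ExpressionMatrix(
        feature_ids=[str(f) for f in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        group_of={s: groups[s] for s in df.columns},
    )


def _read_groups(path: str | os.PathLike) -> dict[str, str]:
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>group'")
            sample, label = fields
            norm = _GROUP_ALIASES.get(label.strip().lower())
            if norm is None:
                raise ValueError(f"{path}:{lineno}: unknown group label {label!r}")
            groups[sample] = norm
    return groups


def write_expression(m: ExpressionMatrix, path: str | os.PathLike,
                     float_format: str = "%.10g") -> None:
    df = pd.DataFrame(m.values, index=m.feature_ids, columns=m.sample_ids)
    df.to_csv(path, sep="\t", float_format=float_format)


def read_edge_list(path: str | os.PathLike, source_kind: str = "miRNA") -> EdgeList:
    """Read a two-column TSV of (source, target mRNA) pairs; duplicates collapse."""
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'source<TAB>target'")
            pairs.add((fields[0], fields[1]))
    return EdgeList(pairs=pairs, source_kind=source_kind)


def write_edge_list(edges: EdgeList, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s, t in sorted(edges.pairs):
            fh.write(f"{s}\t{t}\n")


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read an MSigDB-style GMT file: set_id TAB description TAB member...

    The description field is kept but ignored for membership. Duplicate
    members within one line are deduplicated; a line with fewer than three
    fields is a hard error reported with its line number.
    """
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            sid = fields[0]
            if sid in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set ID {sid!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {sid!r} has no members")
            sets[sid] = members
            desc[sid] = fields[1]
    return GeneSetCollection(sets=sets, description=desc)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sid in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[sid]))
            fh.write(f"{sid}\t{collection.description.get(sid, '')}\t{members}\n")


def read_id_list(path: str | os.PathLike) -> set[str]:
    """Read a one-ID-per-line text file (known disease genes / miRNAs)."""
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line)
    return ids


def write_id_list(ids: set[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i in sorted(ids):
            fh.write(i + "\n")


def write_module_report(modules, out_dir: str | os.PathLike) -> None:
    """Write one member TSV per module, a summary TSV of per-module node/edge
    counts, and a GraphML file of the within-module bipartite edges.

    ``modules`` is a :class:`modnmf.module_extraction.ModuleSet`.
    """
    os.makedirs(out_dir, exist_ok=True)
    summary_rows = []
    for mod in modules.modules:
        rows = []
        for kind in ("mRNA", "circRNA", "miRNA", "pathway"):
            for mid, z in mod.members.get(kind, []):
                rows.append((mid, kind, z))
        df = pd.DataFrame(rows, columns=["member_id", "member_kind", "z_score"])
        df.to_csv(
            os.path.join(out_dir, f"module_{mod.index}_members.tsv"),
            sep="\t", index=False, float_format="%.6g",
        )
        counts = {k: len(mod.members.get(k, [])) for k in
                  ("mRNA", "circRNA", "miRNA", "pathway")}
        summary_rows.append({
            "module": mod.index,
            "nodes": sum(counts.values()),
            "circRNAs": counts["circRNA"],
            "mRNAs": counts["mRNA"],
            "miRNAs": counts["miRNA"],
            "pathways": counts["pathway"],
            "edges": len(mod.edges),
            "functional": int(mod.is_functional),
        })
    summary = pd.DataFrame(
        summary_rows,
        columns=["module", "nodes", "circRNAs", "mRNAs", "miRNAs",
                 "pathways", "edges", "functional"],
    )
    summary.to_csv(os.path.join(out_dir, "module_summary.tsv"), sep="\t", index=False)

    graph = nx.Graph()
    for mod in modules.modules:
        for kind in ("mRNA", "circRNA", "miRNA", "pathway"):
            for mid, _ in mod.members.get(kind, []):
                graph.add_node(mid, kind=kind)
        for entity, mrna in mod.edges:
            graph.add_edge(entity, mrna, module=mod.index)
    nx.write_graphml(graph, os.path.join(out_dir, "module_edges.graphml"))
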