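"""Run configuration: every threshold and seed of the pipeline in one
validated object, loadable from YAML.

Defaults are the pipeline's canonical operating point: fold-change bounds
2 and 0.5, miRNA rank-test p < 0.005, expressed fraction > 50%,
PCC > 0.4 at p < 0.05, mRNA degree >= 4 ("more than three partners"),
K scanned over 5..20 with 100 random restarts, top-percent range 1..10,
functional screen at > 10 enriched GO BP terms (FDR < 0.05), NTO >= 0.5
and candidate threshold of > 4 direct partners.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["RunConfig"]

_EXPRESSION_KEYS = ("circ_expr", "mirna_expr", "mrna_expr", "groups",
                    "mirna_targets", "pathways_gmt")
_RELATION_KEYS = ("x1_edges", "mirna_targets", "pathways_gmt")


@dataclass
class RunConfig:
    inputs: dict[str, str] = field(default_factory=dict)

    # differential / co-expression screens
    fc_high: float = 2.0
    fc_low: float = 0.5
    mirna_p_cut: float = 0.005
    min_expressed_fraction: float = 0.5
    pseudocount: float = 0.25
    paired_test: bool = False
    impute_zero: bool = False
    pcc_cut: float = 0.4
    pcc_p_cut: float = 0.05
    min_degree: int = 4
    pathway_min_degree: int = 1
    # matrices supplied directly are taken as already characterized
    relation_min_degree: int = 0

    # factorization
    k: int | None = None  # fixed K bypasses the scan
    k_min: int = 5
    k_max: int = 20
    n_restarts: int = 100
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    # module extraction / enrichment
    top_percent_min: int = 1
    top_percent_max: int = 10
    functional_min_terms: int = 10
    enrichment_fdr: float = 0.05
    min_set_size: int = 3
    max_set_size: int = 2000

    # scoring
    min_nto: float = 0.5
    min_partners: int = 4
    per_module_partners: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (self.fc_low < self.fc_high, "fc_low must be < fc_high"),
            (0 < self.min_expressed_fraction <= 1,
             "min_expressed_fraction must be in (0, 1]"),
            (0 < self.mirna_p_cut <= 1, "mirna_p_cut must be in (0, 1]"),
            (self.pseudocount >= 0, "pseudocount must be >= 0"),
            (-1 <= self.pcc_cut <= 1, "pcc_cut must be in [-1, 1]"),
            (0 < self.pcc_p_cut <= 1, "pcc_p_cut must be in (0, 1]"),
            (self.min_degree >= 0, "min_degree must be >= 0"),
            (self.k is None or self.k >= 1, "k must be >= 1"),
            (1 <= self.k_min <= self.k_max, "need 1 <= k_min <= k_max"),
            (self.n_restarts >= 1, "n_restarts must be >= 1"),
            (self.max_iter >= 1, "max_iter must be >= 1"),
            (self.tol > 0, "tol must be > 0"),
            (1 <= self.top_percent_min <= self.top_percent_max <= 100,
             "need 1 <= top_percent_min <= top_percent_max <= 100"),
            (self.functional_min_terms >= 0,
             "functional_min_terms must be >= 0"),
            (0 < self.enrichment_fdr < 1, "enrichment_fdr must be in (0, 1)"),
            (0 <= self.min_nto <= 1, "min_nto must be in [0, 1]"),
            (self.min_partners >= 0, "min_partners must be >= 0"),
            (self.seed >= 0, "seed must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    @property
    def has_expression_inputs(self) -> bool:
        return all(k in self.inputs for k in _EXPRESSION_KEYS)

    @property
    def has_relation_inputs(self) -> bool:
        return all(k in self.inputs for k in _RELATION_KEYS) and \
            "x1_edges" in self.inputs

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**raw)
        base = os.path.dirname(os.path.abspath(path))
        cfg.inputs = {k: v if os.path.isabs(v) else os.path.join(base, v)
                      for k, v in cfg.inputs.items()}
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
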