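"""Joint non-negative matrix factorization of three binary relation layers
sharing a common mRNA axis.

The model factorizes X_I ~ W H_I for I = 1..3 with one shared basis
W (M mRNAs x K components) and per-layer coefficient matrices
H_I (K x N_I), minimizing the summed Frobenius objective

    F(W, H) = sum_I || X_I - W H_I ||_F^2

by multiplicative updates.  The W update is the Lee-Seung rule on the
column-concatenated problem, so every sweep is non-increasing in F:

    W   <- W  * (X_1 H_1' + X_2 H_2' + X_3 H_3') / (W (H_1 H_1' + H_2 H_2' + H_3 H_3'))
    H_I <- H_I * (W' X_I) / (W' W H_I)

No regularization terms are used (penalization weights fixed at zero).
Because WH_I is invariant under the diagonal rescaling (WD, D^-1 H_I),
fitted factorizations are reported with W columns normalized to sum to 1
and the scale compensated into the H_I, so restarts are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import BinaryRelationMatrix

__all__ = [
    "JointFactorization",
    "KScanResult",
    "objective",
    "update_step",
    "fit_joint_nmf",
    "scan_k",
]

_EPS = 1e-12  # denominator floor; prevents 0/0 without biasing updates


@dataclass
class JointFactorization:
    """Shared basis W, per-layer coefficients H_I, and the descent trace."""

    W: np.ndarray                 # M x K
    H: list[np.ndarray]           # three K x N_I matrices
    K: int
    objective_trace: list[float]
    restart_seed: int
    mrna_ids: list[str] = field(default_factory=list)
    entity_ids: list[list[str]] = field(default_factory=list)
    layers: list[str] = field(default_factory=list)

    @property
    def final_objective(self) -> float:
        return self.objective_trace[-1]


@dataclass
class KScanResult:
    per_k: dict[int, float]
    chosen_k: int
    chosen_factorization: JointFactorization


def _as_arrays(X) -> list[np.ndarray]:
    """Relation layers are stored entity x mRNA; the factorization lives on
    mRNA x entity, so :class:`BinaryRelationMatrix` inputs are transposed.
    Plain arrays are taken as already being mRNA x entity."""
    brms = [x for x in X if isinstance(x, BinaryRelationMatrix)]
    if len(brms) > 1:
        cols = brms[0].col_ids
        for b in brms[1:]:
            if b.col_ids != cols:
                raise ValueError("relation layers do not share an identical, "
                                 "identically ordered mRNA axis")
    return [x.cells.T if isinstance(x, BinaryRelationMatrix)
            else np.asarray(x, float) for x in X]


def objective(X, W: np.ndarray, H: list[np.ndarray]) -> float:
    """F(W, H) = sum_I ||X_I - W H_I||_F^2 over the three layers."""
    Xs = _as_arrays(X)
    if len(Xs) != len(H):
        raise ValueError("need one H per layer")
    total = 0.0
    for Xi, Hi in zip(Xs, H):
        if W.shape[0] != Xi.shape[0] or Hi.shape != (W.shape[1], Xi.shape[1]):
            raise ValueError(
                f"dimension mismatch: X {Xi.shape}, W {W.shape}, H {Hi.shape}")
        total += float(np.linalg.norm(Xi - W @ Hi) ** 2)
    return total


def _objective_arrays(Xs: list[np.ndarray], W: np.ndarray, H: list[np.ndarray]) -> float:
    return float(sum(np.linalg.norm(Xi - W @ Hi) ** 2 for Xi, Hi in zip(Xs, H)))


def update_step(X, W: np.ndarray, H: list[np.ndarray],
                eps: float = _EPS) -> tuple[np.ndarray, list[np.ndarray]]:
    """One full multiplicative sweep (W then every H_I).

    Preserves non-negativity by construction and never increases the
    objective.  Raises on NaN/Inf in the updated factors.
    """
    Xs = _as_arrays(X)
    num = sum(Xi @ Hi.T for Xi, Hi in zip(Xs, H))
    den = W @ sum(Hi @ Hi.T for Hi in H)
    W_new = W * num / np.maximum(den, eps)
    H_new = []
    WtW = W_new.T @ W_new
    for Xi, Hi in zip(Xs, H):
        Hi_new = Hi * (W_new.T @ Xi) / np.maximum(WtW @ Hi, eps)
        H_new.append(Hi_new)
    for mat in [W_new, *H_new]:
        if not np.isfinite(mat).all():
            raise FloatingPointError("non-finite entry in updated factors")
    return W_new, H_new


def _normalize_columns(W: np.ndarray, H: list[np.ndarray]
                       ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Fix the diagonal scaling ambiguity: W columns sum to 1, scale moved
    into the H_I, leaving every product W H_I unchanged."""
    scale = W.sum(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return W / scale, [Hi * scale[:, None] for Hi in H]


def fit_joint_nmf(
    X,
    K: int,
    n_restarts: int = 100,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> JointFactorization:
    """Fit the joint factorization, keeping the best of ``n_restarts``
    random initializations.

    Restart r draws W, H i.i.d. uniform(0, 1] from a generator seeded with
    ``seed + r`` (recorded in the result), iterates :func:`update_step`
    until the relative objective change drops below ``tol`` or ``max_iter``
    sweeps, and the restart with the smallest final objective wins.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    Xs = _as_arrays(X)
    M = Xs[0].shape[0]
    Ns = [Xi.shape[1] for Xi in Xs]

    best: JointFactorization | None = None
    for r in range(n_restarts):
        rseed = int(seed + r) % (2 ** 31)
        rng = np.random.default_rng(rseed)
        # uniform over (0, 1]: strictly positive so no entry is locked at 0
        W = 1.0 - rng.random((M, K))
        H = [1.0 - rng.random((K, N)) for N in Ns]
        trace = [_objective_arrays(Xs, W, H)]
        for it in range(max_iter):
            try:
                W, H = update_step(Xs, W, H)
            except FloatingPointError as exc:
                raise FloatingPointError(
                    f"restart {r}, iteration {it}: {exc}") from exc
            f = _objective_arrays(Xs, W, H)
            trace.append(f)
            prev = trace[-2]
            if prev > 0 and (prev - f) / prev < tol:
                break
        if best is None or trace[-1] < best.final_objective:
            best = JointFactorization(
                W=W, H=H, K=K, objective_trace=trace, restart_seed=rseed)

    assert best is not None
    best.W, best.H = _normalize_columns(best.W, best.H)
    if all(isinstance(x, BinaryRelationMatrix) for x in X):
        best.mrna_ids = list(X[0].col_ids)
        best.entity_ids = [list(x.row_ids) for x in X]
        best.layers = [x.layer for x in X]
    return best


def scan_k(
    X,
    k_min: int = 5,
    k_max: int = 20,
    n_restarts: int = 100,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> KScanResult:
    """Fit the factorization for every K in [k_min, k_max] and pick the K
    with the smallest best-restart objective (ties toward smaller K).

    The residual of an unregularized Frobenius fit typically decreases with
    K, so the full per-K curve is returned for elbow inspection; callers can
    bypass the scan with a fixed K.
    """
    if k_min > k_max:
        raise ValueError("k_min must be <= k_max")
    per_k: dict[int, float] = {}
    fits: dict[int, JointFactorization] = {}
    for k in range(k_min, k_max + 1):
        fit = fit_joint_nmf(X, k, n_restarts=n_restarts, max_iter=max_iter,
                            tol=tol, seed=seed)
        per_k[k] = fit.final_objective
        fits[k] = fit
    chosen = min(per_k, key=lambda k: (per_k[k], k))
    return KScanResult(per_k=per_k, chosen_k=chosen, chosen_factorization=fits[chosen])
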