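"""Nonnegative matrix factorization Y ~= H U under the Frobenius objective.

The fit minimizes ``||Y - HU||_F^2`` with Lee--Seung multiplicative
updates, which keep both factors nonnegative and never increase the
objective.  Rank selection follows the consensus-clustering recipe:
dyad columns are assigned to their dominant factor across repeated
seeded runs, the pairwise co-assignment frequencies form a consensus
matrix, and the cophenetic correlation of its complement measures
cluster stability per candidate rank.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.io
import scipy.sparse
import scipy.spatial.distance as ssd

from proxnet.contacts import ContactMatrix

logger = logging.getLogger(__name__)

EPS = 1e-9


def _as_array(Y) -> np.ndarray:
    if isinstance(Y, ContactMatrix):
        Y = Y.Y
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be a 2-D matrix")
    if np.any(Y < 0):
        raise ValueError("Y must be nonnegative")
    return Y


@dataclass
class FactorModel:
    """A fitted factorization: H (epoch x factor), U (factor x dyad)."""

    H: np.ndarray
    U: np.ndarray
    K: int
    objective: float
    n_iter: int
    seed: int
    converged: bool
    objective_history: list[float] = field(default_factory=list, repr=False)

    def reconstruct(self) -> np.ndarray:
        return self.H @ self.U


def rss(Y, model: FactorModel) -> float:
    """Residual sum of squares sum_ij (y_ij - (HU)_ij)^2."""
    Y = _as_array(Y)
    if (Y.shape[0] != model.H.shape[0]) or (Y.shape[1] != model.U.shape[1]):
        raise ValueError(f"shape mismatch: Y {Y.shape} vs H {model.H.shape}, "
                         f"U {model.U.shape}")
    resid = Y - model.H @ model.U
    return float(np.sum(resid * resid))


def _normalize_model(H: np.ndarray, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Canonical form: each U row scaled to unit maximum (compensated in H),
    factors ordered by descending total activity of H columns."""
    H = H.copy()
    U = U.copy()
    scale = U.max(axis=1)
    pos = scale > 0
    U[pos] /= scale[pos, None]
    H[:, pos] *= scale[pos]
    order = np.argsort(-H.sum(axis=0), kind="stable")
    return H[:, order], U[order]


def nmf_frobenius(Y, K: int, seed: int = 0, max_iter: int = 2000,
                  tol: float = 1e-5, track_objective: bool = False) -> FactorModel:
    """Fit Y ~= HU by multiplicative updates for the Frobenius objective.

    Stops when the relative objective decrease falls below ``tol`` or
    after ``max_iter`` iterations; deterministic given ``seed``.  The
    returned factors are in canonical form (unit-max U rows, factors
    sorted by total activity).

    Raises on an all-zero Y or a rank exceeding ``min(I, J)``.
    """
    Y = _as_array(Y)
    I, J = Y.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > min(I, J):
        raise ValueError(f"K={K} exceeds min(I, J)={min(I, J)}")
    if not np.any(Y > 0):
        raise ValueError("Y is all-zero; factorization is degenerate")

    rng = np.random.default_rng(seed)
    # uniform init scaled so E[(HU)_ij] is on the order of mean(Y)
    scale = np.sqrt(Y.mean() / K)
    H = rng.uniform(0.0, 1.0, size=(I, K)) * scale
    U = rng.uniform(0.0, 1.0, size=(K, J)) * scale

    yss = float(np.sum(Y * Y))

    obj = float(np.sum((Y - H @ U) ** 2))
    history = [obj] if track_objective else []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H *= (Y @ U.T) / (H @ (U @ U.T) + EPS)
        HtY = H.T @ Y
        HtH = H.T @ H
        U *= HtY / (HtH @ U + EPS)
        # exact objective via the trace expansion; avoids forming H @ U
        new_obj = max(yss - 2.0 * float(np.sum(HtY * U))
                      + float(np.sum((HtH @ U) * U)), 0.0)
        if track_objective:
            history.append(new_obj)
        if obj > 0 and (obj - new_obj) / obj < tol:
            obj = new_obj
            converged = True
            break
        obj = new_obj
    H, U = _normalize_model(H, U)
    return FactorModel(H=H, U=U, K=K, objective=obj, n_iter=it, seed=seed,
                       converged=converged, objective_history=history)


def multistart_fit(Y, K: int, n_starts: int = 10, base_seed: int = 0,
                   **fit_kwargs) -> FactorModel:
    """Best-of-``n_starts`` fit with seeds ``base_seed .. base_seed+n_starts-1``."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    best: FactorModel | None = None
    for s in range(n_starts):
        model = nmf_frobenius(Y, K, seed=base_seed + s, **fit_kwargs)
        logger.debug("multistart_fit: K=%d seed=%d objective=%.6g",
                     K, base_seed + s, model.objective)
        if best is None or model.objective < best.objective:
            best = model
    assert best is not None
    return best


def dominant_factor_labels(U: np.ndarray) -> np.ndarray:
    """Per-column argmax factor assignment; all-zero columns get label -1."""
    labels = np.argmax(U, axis=0)
    labels[U.max(axis=0) <= 0] = -1
    return labels


def consensus_matrix(Y, K: int, n_runs: int = 30, base_seed: int = 0,
                     **fit_kwargs) -> np.ndarray:
    """J x J co-assignment frequency matrix over ``n_runs`` seeded fits.

    Each run assigns every dyad column to its dominant factor
    (``argmax_k u_kj``, ties to the lowest k); entry (j, j') is the
    fraction of runs in which the two columns share an assignment.
    All-zero columns get a null label that never matches a real factor.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    Y = _as_array(Y)
    J = Y.shape[1]
    C = np.zeros((J, J))
    for r in range(n_runs):
        model = nmf_frobenius(Y, K, seed=base_seed + r, **fit_kwargs)
        labels = dominant_factor_labels(model.U)
        same = labels[:, None] == labels[None, :]
        C += same
    C /= n_runs
    np.fill_diagonal(C, 1.0)
    return C


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the consensus-derived distances.

    Distances ``d = 1 - consensus`` are clustered by average linkage; the
    return value is the Pearson correlation between the original
    condensed distances and the dendrogram's cophenetic distances.
    Returns NaN when the distance vector is constant (undefined).
    """
    consensus = np.asarray(consensus, dtype=float)
    if consensus.shape[0] != consensus.shape[1]:
        raise ValueError("consensus matrix must be square")
    if not np.allclose(consensus, consensus.T, atol=1e-12):
        raise ValueError("consensus matrix must be symmetric")
    if consensus.min() < -1e-12 or consensus.max() > 1 + 1e-12:
        raise ValueError("consensus entries must lie in [0, 1]")
    D = np.clip(1.0 - consensus, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    d = ssd.squareform(D, checks=False)
    if d.size == 0 or np.ptp(d) == 0:
        return float("nan")
    Z = sch.linkage(d, method="average")
    coph = sch.cophenet(Z)
    if np.ptp(coph) == 0:
        return float("nan")
    return float(np.corrcoef(d, coph)[0, 1])


@dataclass
class RankSelectionResult:
    """Per-rank stability and fit table for human rank selection."""

    K_range: list[int]
    rss_by_K: dict[int, float]
    cophenetic_by_K: dict[int, float]
    consensus_by_K: dict[int, np.ndarray]
    chosen_K: int | None = None

    def as_rows(self) -> list[tuple[int, float, float]]:
        return [(K, self.rss_by_K[K], self.cophenetic_by_K[K])
                for K in self.K_range]


def select_rank(Y, K_range: list[int], n_runs: int = 30, n_starts: int = 10,
                base_seed: int = 0, auto: bool = False,
                cophenetic_threshold: float = 0.95,
                **fit_kwargs) -> RankSelectionResult:
    """Compute the rank-selection table over candidate ranks.

    For each K: the best-of-``n_starts`` residual sum of squares and the
    cophenetic correlation of the ``n_runs``-run consensus matrix.
    ``chosen_K`` stays unset unless ``auto`` is enabled; the auto rule
    picks the largest K whose cophenetic stays at or above the threshold
    before the first drop (falling back to the maximal-cophenetic K when
    no candidate clears the threshold), but the full table is always
    emitted so interpretability can override.
    """
    if not K_range:
        raise ValueError("K_range must be non-empty")
    Ks = sorted(K_range)
    rss_by_K: dict[int, float] = {}
    coph_by_K: dict[int, float] = {}
    cons_by_K: dict[int, np.ndarray] = {}
    for K in Ks:
        best = multistart_fit(Y, K, n_starts=n_starts, base_seed=base_seed,
                              **fit_kwargs)
        rss_by_K[K] = best.objective
        C = consensus_matrix(Y, K, n_runs=n_runs, base_seed=base_seed + 1000,
                             **fit_kwargs)
        cons_by_K[K] = C
        coph_by_K[K] = cophenetic_coefficient(C)
        logger.info("select_rank: K=%d rss=%.6g cophenetic=%.4f",
                    K, rss_by_K[K], coph_by_K[K])
    for a, b in zip(Ks, Ks[1:]):
        if rss_by_K[b] > rss_by_K[a] * (1 + 1e-9):
            logger.warning("select_rank: rss increased from K=%d to K=%d; "
                           "consider more restarts", a, b)
    chosen: int | None = None
    if auto:
        prefix = []
        for K in Ks:
            c = coph_by_K[K]
            if np.isnan(c) or c < cophenetic_threshold:
                break
            prefix.append(K)
        if prefix:
            chosen = prefix[-1]
        else:
            finite = [K for K in Ks if not np.isnan(coph_by_K[K])]
            chosen = max(finite, key=lambda K: coph_by_K[K]) if finite else Ks[0]
    return RankSelectionResult(Ks, rss_by_K, coph_by_K, cons_by_K, chosen)


# ---------------------------------------------------------------------------
# persistence

def save_model(model: FactorModel, prefix: str | Path) -> None:
    """Persist H and U as MTX plus a JSON metadata sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix.parent / (prefix.name + ".H.mtx")),
                     scipy.sparse.coo_matrix(model.H))
    scipy.io.mmwrite(str(prefix.parent / (prefix.name + ".U.mtx")),
                     scipy.sparse.coo_matrix(model.U))
    meta = {
        "K": model.K,
        "objective": model.objective,
        "n_iter": model.n_iter,
        "seed": model.seed,
        "converged": model.converged,
        "normalization": "unit-max U rows, factors by descending H activity",
    }
    with open(prefix.parent / (prefix.name + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(prefix: str | Path) -> FactorModel:
    prefix = Path(prefix)
    def _read(path: Path) -> np.ndarray:
        M = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(M):
            M = M.toarray()
        return np.atleast_2d(np.asarray(M, dtype=float))

    H = _read(prefix.parent / (prefix.name + ".H.mtx"))
    U = _read(prefix.parent / (prefix.name + ".U.mtx"))
    with open(prefix.parent / (prefix.name + ".meta.json")) as fh:
        meta = json.load(fh)
    return FactorModel(H=H, U=U, K=int(meta["K"]),
                       objective=float(meta["objective"]),
                       n_iter=int(meta["n_iter"]), seed=int(meta["seed"]),
                       converged=bool(meta["converged"]))
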