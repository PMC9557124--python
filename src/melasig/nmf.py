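"""De novo signature extraction by KL-divergence NMF, and exposure clustering.

The factorization V ~= W H (V: 96 x samples context counts, W: 96 x k
column-stochastic signatures, H: k x samples non-negative exposures) is
fitted with the Brunet multiplicative updates minimizing the generalized
Kullback-Leibler divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ].

Multi-restart selects the lowest-objective run; pooled per-run signatures
drive the rank-selection metrics (average sample cosine distance and
average silhouette width over ranks).  Samples are then clustered on their
normalized exposures with k-means into UV-high / UV-low, named by the mean
weight of the UV-like signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .contexts import CONTEXT_LABELS
from .errors import AmbiguityError, DegenerateInputError, ParameterError
from .io import ReferenceSignatureSet

logger = logging.getLogger(__name__)

_EPS = 1e-12


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(a, b) = a.b / (|a||b|); in [0, 1] for non-negative vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ParameterError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


@dataclass
class NMFResult:
    """One NMF factorization of a cohort context matrix."""

    signatures: np.ndarray          # 96 x k, columns sum to 1
    exposures: np.ndarray           # k x n_samples, non-negative
    sample_ids: list[str]
    objective: float                # final generalized KL divergence
    n_iter: int
    seed: int
    objective_trace: np.ndarray = field(repr=False, default=None)
    run_signatures: list[np.ndarray] | None = field(repr=False, default=None)

    @property
    def rank(self) -> int:
        return self.signatures.shape[1]

    def exposure_fractions(self) -> np.ndarray:
        """Exposures normalized per sample to proportions (k x n)."""
        sums = self.exposures.sum(axis=0, keepdims=True)
        return self.exposures / np.maximum(sums, _EPS)

    def reconstruction(self) -> np.ndarray:
        return self.signatures @ self.exposures

    def signatures_frame(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        names = list(names) if names else [f"Sig{i}" for i in range(self.rank)]
        return pd.DataFrame(self.signatures, index=list(CONTEXT_LABELS), columns=names)


def _as_count_matrix(V) -> tuple[np.ndarray, list[str]]:
    """Accept a samples x 96 DataFrame/array; return (96 x n array, sample ids)."""
    if isinstance(V, pd.DataFrame):
        ids = [str(s) for s in V.index]
        X = V.to_numpy(dtype=float).T
    else:
        X = np.asarray(V, dtype=float).T
        ids = [f"S{i}" for i in range(X.shape[1])]
    if X.shape[0] != 96:
        raise ParameterError(f"expected 96 context columns, got {X.shape[0]}")
    if (X < 0).any():
        raise ParameterError("context matrix must be non-negative")
    return X, ids


def _kl_divergence(X: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    pos = X > 0
    return float(np.sum(X[pos] * np.log(X[pos] / WH[pos])) - X.sum() + WH.sum())


def nmf_brunet(
    V,
    rank: int,
    *,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> NMFResult:
    """Fit one seeded Brunet (KL multiplicative-update) NMF.

    ``V`` is the samples x 96 context matrix; it is transposed internally.
    Stops when the relative objective decrease falls below ``tol`` or after
    ``max_iter`` iterations.  W is rescaled column-stochastic with the
    compensating row scaling applied to H, which leaves WH unchanged.
    """
    X, sample_ids = _as_count_matrix(V)
    n = X.shape[1]
    if rank < 1 or rank >= min(X.shape):
        raise ParameterError(f"rank must be in [1, {min(X.shape) - 1}], got {rank}")
    zero_cols = np.flatnonzero(X.sum(axis=0) == 0)
    if zero_cols.size:
        raise ParameterError(f"all-zero sample column(s) at index {zero_cols[:3]}")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / rank)
    W = rng.uniform(size=(96, rank)) * scale + _EPS
    H = rng.uniform(size=(rank, n)) * scale + _EPS

    trace = np.empty(max_iter)
    prev = np.inf
    n_iter = max_iter
    for it in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (X / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((X / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        obj = _kl_divergence(X, W @ H)
        trace[it] = obj
        if prev - obj < tol * max(abs(prev), 1.0) and it > 0:
            n_iter = it + 1
            break
        prev = obj
    obj = trace[n_iter - 1]

    col = np.maximum(W.sum(axis=0), _EPS)
    W = W / col
    H = H * col[:, None]
    return NMFResult(W, H, sample_ids, obj, n_iter, seed, objective_trace=trace[:n_iter])


def derive_run_seeds(seed: int, nrun: int) -> np.ndarray:
    """Deterministic per-run seeds (< 2**31) from a master seed."""
    return np.random.SeedSequence(seed).generate_state(nrun) % np.uint32(2**31)


def nmf_multistart(
    V,
    rank: int,
    nrun: int = 10,
    *,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> NMFResult:
    """Run ``nrun`` seeded restarts of :func:`nmf_brunet`; keep the best.

    The returned result is the lowest-objective run (a genuine single
    factorization, not a consensus average); the column-stochastic
    signature matrices of *all* runs are kept in ``run_signatures`` for
    rank-selection metrics.
    """
    if nrun < 1:
        raise ParameterError("nrun must be >= 1")
    best: NMFResult | None = None
    run_sigs: list[np.ndarray] = []
    for run_seed in derive_run_seeds(seed, nrun):
        res = nmf_brunet(V, rank, max_iter=max_iter, tol=tol, seed=int(run_seed))
        run_sigs.append(res.signatures)
        if best is None or res.objective < best.objective:
            best = res
    best.run_signatures = run_sigs
    return best


def _cosine_distance_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise 1 - cosine between columns of A (96 x p) and B (96 x q)."""
    An = A / np.maximum(np.linalg.norm(A, axis=0), _EPS)
    Bn = B / np.maximum(np.linalg.norm(B, axis=0), _EPS)
    return 1.0 - An.T @ Bn


def rank_survey(
    V,
    ranks: Iterable[int] = range(2, 9),
    nrun: int = 5,
    *,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> pd.DataFrame:
    """Evaluate candidate factorization ranks.

    For each rank: ``avg_sample_cosine_distance`` is the mean over samples
    of 1 - cos(observed spectrum, best-run reconstruction);
    ``avg_silhouette_width`` pools the rank x nrun signatures extracted
    across restarts, groups each run's signatures by Hungarian matching to
    the best run's signatures under cosine distance, and averages the
    silhouette widths (cosine metric).  Stable ranks reproduce the same
    signatures across restarts and score high.
    """
    if nrun < 2:
        raise ParameterError("rank_survey needs nrun >= 2 for the silhouette metric")
    X, _ = _as_count_matrix(V)
    rows = []
    for i, rank in enumerate(ranks):
        best = nmf_multistart(
            V, rank, nrun, seed=int(np.random.SeedSequence([seed, rank]).generate_state(1)[0] % 2**31),
            max_iter=max_iter, tol=tol,
        )
        recon = best.reconstruction()
        cosines = [
            cosine_similarity(X[:, j], recon[:, j]) for j in range(X.shape[1])
        ]
        avg_dist = float(1.0 - np.mean(cosines))
        points, labels = [], []
        for sig in best.run_signatures:
            cost = _cosine_distance_matrix(sig, best.signatures)
            ri, ci = linear_sum_assignment(cost)
            for r, c in zip(ri, ci):
                points.append(sig[:, r])
                labels.append(c)
        sil = float(silhouette_score(np.array(points), np.array(labels), metric="cosine"))
        rows.append(
            {"rank": rank, "avg_sample_cosine_distance": avg_dist, "avg_silhouette_width": sil}
        )
    return pd.DataFrame(rows)


def identify_uv_signature(
    result: NMFResult | np.ndarray, reference: ReferenceSignatureSet | None = None
) -> int:
    """Index of the extracted signature most similar to SBS7a/SBS7b (``SigB``).

    ``reference`` must contain SBS7a and SBS7b; by default the package's
    synthetic COSMIC-like set is used.  Returns the column index maximizing
    max(cos(., SBS7a), cos(., SBS7b)); an exact tie raises
    :class:`AmbiguityError`, and a best similarity below 0.5 logs a
    low-confidence warning but still returns the argmax.
    """
    W = result.signatures if isinstance(result, NMFResult) else np.asarray(result)
    if reference is None:
        from .references import synthetic_cosmic_like

        reference = synthetic_cosmic_like()
    for need in ("SBS7a", "SBS7b"):
        if need not in reference.names:
            raise ParameterError(f"reference set lacks {need}")
    uv_refs = np.column_stack([reference["SBS7a"], reference["SBS7b"]])
    scores = np.array(
        [max(cosine_similarity(W[:, j], uv_refs[:, r]) for r in range(2)) for j in range(W.shape[1])]
    )
    order = np.argsort(scores)[::-1]
    if W.shape[1] > 1 and scores[order[0]] - scores[order[1]] < 1e-9:
        raise AmbiguityError("two extracted signatures are equally UV-like")
    if scores[order[0]] < 0.5:
        warnings.warn(
            f"best UV similarity is only {scores[order[0]]:.2f}; UV assignment is low-confidence",
            stacklevel=2,
        )
    return int(order[0])


@dataclass
class ClusterAssignment:
    """UV-high / UV-low labels from k-means on normalized exposures."""

    sample_ids: list[str]
    labels: np.ndarray          # "UV-high" / "UV-low" per sample
    sigb_weight: np.ndarray     # normalized exposure of the UV-like signature

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": self.labels, "sigb_weight": self.sigb_weight},
            index=list(self.sample_ids),
        ).rename_axis("sample_id")

    def label_of(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.labels))


def kmeans_exposures(
    result: NMFResult,
    k: int = 2,
    *,
    n_init: int = 50,
    seed: int = 0,
    uv_index: int | None = None,
) -> ClusterAssignment:
    """Cluster samples into UV-high / UV-low on normalized exposures.

    Exposures are normalized per sample to proportions (burden must not
    dominate the distance) and clustered by seeded k-means (k-means++
    initialisation, ``n_init`` restarts, best inertia kept).  The cluster
    with the strictly greater mean weight of the UV-like signature is
    labelled UV-high.  ``uv_index`` names the UV-like exposure row; when
    None it is found with :func:`identify_uv_signature` against the
    packaged synthetic reference set.
    """
    if k != 2:
        raise ParameterError("UV-high/UV-low labelling is defined for k = 2")
    points = result.exposure_fractions().T  # n x k_sig
    if np.unique(points, axis=0).shape[0] < k:
        raise DegenerateInputError("fewer distinct exposure vectors than clusters")
    if uv_index is None:
        uv_index = identify_uv_signature(result)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(points)
    sigb = points[:, uv_index]
    means = [sigb[km.labels_ == c].mean() for c in range(k)]
    high = int(np.argmax(means))
    labels = np.where(km.labels_ == high, "UV-high", "UV-low")
    return ClusterAssignment(list(result.sample_ids), labels, sigb)
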