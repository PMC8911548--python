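"""Bivariate Gaussian-mixture clustering of the phasor cloud.

The phasor cloud is modelled as a K-component mixture

    p(x) = sum_i f_i N(x; mu_i, Sigma_i),   x = (g, s),

fitted by expectation-maximization: the E-step computes per-point
responsibilities under the current parameters, the M-step re-estimates the
fractions, means and full covariances from responsibility-weighted moments.
The log-likelihood is non-decreasing over iterations; convergence is
declared when its relative change drops below a tolerance.  Points are then
hard-assigned to the cluster of maximal responsibility ("hard edges"), and
each cluster is summarized by the mean and standard deviation of its
members' phase lifetimes — the per-population lifetime report.

K is fixed by the user (default 2: one component per known paint mixture at
the measured interface); automatic model selection is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateDataError, DomainError, InsufficientDataError
from .phasor import PhasorCloud, TauPhaseMap, tau_phase

__all__ = [
    "GMMParams",
    "FitResult",
    "ClusterSummary",
    "gmm_density",
    "fit_gmm",
    "hard_assign",
    "order_clusters",
    "cluster_summary",
    "save_fit_report",
    "summaries_to_frame",
]

_RIDGE = 1e-10  # eigenvalue floor for M-step covariances; prevents singular
                # collapse on numerically tight (noiseless) clusters


@dataclass(frozen=True)
class GMMParams:
    """Parameters of a K-component bivariate Gaussian mixture."""

    fractions: np.ndarray  # (K,), non-negative, sums to 1
    means: np.ndarray      # (K, 2) as (g, s)
    covariances: np.ndarray  # (K, 2, 2) symmetric positive definite

    def __post_init__(self) -> None:
        fractions = np.asarray(self.fractions, dtype=float)
        means = np.asarray(self.means, dtype=float)
        covariances = np.asarray(self.covariances, dtype=float)
        object.__setattr__(self, "fractions", fractions)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covariances", covariances)
        k = len(fractions)
        if means.shape != (k, 2) or covariances.shape != (k, 2, 2):
            raise DomainError("inconsistent GMM parameter shapes")
        if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-12:
            raise DomainError("fractions must be non-negative and sum to 1")
        for sigma in covariances:
            if not np.allclose(sigma, sigma.T, atol=1e-12):
                raise DomainError("covariance must be symmetric")
            if np.linalg.eigvalsh(sigma).min() <= 0:
                raise DomainError("covariance must be positive definite")

    @property
    def k(self) -> int:
        return len(self.fractions)


@dataclass
class FitResult:
    """EM fit output: parameters, responsibilities and likelihood trace."""

    params: GMMParams
    responsibilities: np.ndarray  # (n, K), rows sum to 1
    log_likelihood_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def log_likelihood(self) -> float:
        return float(self.log_likelihood_trace[-1])


@dataclass(frozen=True)
class ClusterSummary:
    """Per-cluster lifetime report: n, mixture fraction, mean +/- SD
    tau-phase (ns) over member pixels with a finite lifetime, and the
    cluster centroid in phasor coordinates."""

    cluster_id: int
    n_points: int
    fraction: float
    mean_tau_ns: float  # NaN when no member has a finite tau
    sd_tau_ns: float
    mean_g: float
    mean_s: float

    @property
    def tau_defined(self) -> bool:
        return math.isfinite(self.mean_tau_ns)


def _log_gauss2(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log bivariate normal density at points x (n, 2)."""
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
    if det <= 0:
        raise DomainError("covariance must be positive definite")
    inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[1, 0], cov[0, 0]]]) / det
    d = x - mean
    maha = d[:, 0] ** 2 * inv[0, 0] + 2 * d[:, 0] * d[:, 1] * inv[0, 1] + d[:, 1] ** 2 * inv[1, 1]
    return -0.5 * maha - math.log(2.0 * math.pi) - 0.5 * math.log(det)


def gmm_density(x, params: GMMParams) -> np.ndarray:
    """Mixture probability density sum_i f_i N(x; mu_i, Sigma_i).

    Accepts a single (g, s) point or an (n, 2) array; returns a scalar or
    an (n,) array accordingly.
    """
    pts = np.atleast_2d(np.asarray(x, dtype=float))
    if pts.shape[1] != 2:
        raise DomainError("points must be 2-D (g, s)")
    dens = np.zeros(len(pts))
    for f, mu, sigma in zip(params.fractions, params.means, params.covariances):
        dens += f * np.exp(_log_gauss2(pts, mu, sigma))
    return float(dens[0]) if np.asarray(x).ndim == 1 else dens


def _log_responsibilities(
    x: np.ndarray, params: GMMParams
) -> Tuple[np.ndarray, float]:
    """Log responsibilities (n, K) and total log-likelihood."""
    k = params.k
    log_p = np.empty((len(x), k))
    for i in range(k):
        log_p[:, i] = np.log(params.fractions[i] + 1e-300) + _log_gauss2(
            x, params.means[i], params.covariances[i]
        )
    m = log_p.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(log_p - m).sum(axis=1))
    return log_p - lse[:, None], float(lse.sum())


def _m_step(x: np.ndarray, resp: np.ndarray) -> GMMParams:
    n, k = resp.shape
    nk = resp.sum(axis=0)
    fractions = nk / n
    means = (resp.T @ x) / nk[:, None]
    covariances = np.empty((k, 2, 2))
    for i in range(k):
        d = x - means[i]
        cov = (resp[:, i, None] * d).T @ d / nk[i]
        # regularize only near-singular components: an unconditional ridge
        # would break the exact monotonicity of the likelihood trace
        tr = cov[0, 0] + cov[1, 1]
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
        min_eig = 0.5 * (tr - math.sqrt(max(tr * tr - 4.0 * det, 0.0)))
        if min_eig < _RIDGE:
            cov = cov + _RIDGE * np.eye(2)
        covariances[i] = cov
    return GMMParams(fractions=fractions, means=means, covariances=covariances)


def _farthest_point_init(
    x: np.ndarray, k: int, rng: np.random.Generator
) -> GMMParams:
    """Seeded farthest-point start: a random first centre, each next centre
    the point farthest from all chosen ones; shared spherical covariance
    from the global spread."""
    n = len(x)
    centers = [x[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            [((x - c) ** 2).sum(axis=1) for c in centers], axis=0
        )
        centers.append(x[int(np.argmax(d2))])
    means = np.array(centers)
    var = max(float(x.var(axis=0).mean()), _RIDGE)
    covariances = np.tile(var * np.eye(2), (k, 1, 1))
    fractions = np.full(k, 1.0 / k)
    return GMMParams(fractions=fractions, means=means, covariances=covariances)


def fit_gmm(
    cloud,
    k: int = 2,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_starts: int = 5,
) -> FitResult:
    """Fit a K-component Gaussian mixture to the (g, s) cloud by EM.

    Runs ``n_starts`` independently initialized EM fits (seeded
    farthest-point starts) and keeps the one with the highest final
    log-likelihood.  Deterministic for a given seed.

    Parameters
    ----------
    cloud : PhasorCloud or (n, 2) array
        Phasor coordinates to cluster.
    k : int
        Number of mixture components (default 2).
    tol : float
        Relative log-likelihood change declaring convergence.
    """
    x = cloud.coords if isinstance(cloud, PhasorCloud) else np.asarray(cloud, float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise DomainError("cloud must provide (n, 2) coordinates")
    n = len(x)
    if k < 1:
        raise DomainError("k must be >= 1")
    if n < 3 * k:
        raise InsufficientDataError(
            f"need at least {3 * k} phasors for k={k}, got {n}"
        )
    if np.allclose(x, x[0], atol=1e-15) and k > 1:
        raise DegenerateDataError("all phasors identical; mixture not identifiable")

    root = np.random.SeedSequence(seed)
    best: Optional[FitResult] = None
    for child in root.spawn(n_starts):
        rng = np.random.default_rng(child)
        params = _farthest_point_init(x, k, rng)
        trace: List[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            log_resp, ll = _log_responsibilities(x, params)
            trace.append(ll)
            resp = np.exp(log_resp)
            params = _m_step(x, resp)
            if len(trace) >= 2:
                prev = trace[-2]
                if abs(ll - prev) <= tol * max(abs(prev), 1.0):
                    converged = True
                    break
        log_resp, ll = _log_responsibilities(x, params)
        trace.append(ll)
        result = FitResult(
            params=params,
            responsibilities=np.exp(log_resp),
            log_likelihood_trace=np.asarray(trace),
            n_iter=it,
            converged=converged,
        )
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    assert best is not None
    return best


def hard_assign(result: FitResult) -> np.ndarray:
    """Cluster labels in 1..K by maximal responsibility; ties go to the
    lower cluster index (argmax takes the first maximum)."""
    return np.argmax(result.responsibilities, axis=1) + 1


def order_clusters(result: FitResult, cloud) -> FitResult:
    """Relabel components in canonical order: descending phase lifetime of
    the component mean, ties broken by descending fraction then mean g.

    Depends only on the fitted parameters, so the ordering is stable across
    runs and seeds that reach the same fit.
    """
    config = cloud.config if isinstance(cloud, PhasorCloud) else None
    f = config.repetition_rate if config is not None else 2.0e7
    params = result.params
    taus = np.array(
        [
            tau_phase((mu[0], mu[1]), f) if mu[0] != 0 else -np.inf
            for mu in params.means
        ]
    )
    order = sorted(
        range(params.k),
        key=lambda i: (-taus[i], -params.fractions[i], -params.means[i, 0]),
    )
    order = np.asarray(order)
    return FitResult(
        params=GMMParams(
            fractions=params.fractions[order],
            means=params.means[order],
            covariances=params.covariances[order],
        ),
        responsibilities=result.responsibilities[:, order],
        log_likelihood_trace=result.log_likelihood_trace,
        n_iter=result.n_iter,
        converged=result.converged,
    )


def cluster_summary(
    cloud: PhasorCloud, tau_map: TauPhaseMap, labels: np.ndarray
) -> List[ClusterSummary]:
    """Mean +/- SD tau-phase per cluster over member pixels.

    Uses the population SD (n denominator).  A cluster whose members all
    lack a finite lifetime (g <= 0) gets NaN lifetime statistics and is
    flagged via ``tau_defined``.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cloud):
        raise DomainError("labels must align with the phasor cloud")
    taus = tau_map.values[cloud.pixels[:, 0], cloud.pixels[:, 1]]
    summaries = []
    for cid in sorted(int(v) for v in np.unique(labels)):
        member = labels == cid
        n_points = int(member.sum())
        t = taus[member]
        t = t[np.isfinite(t)]
        if len(t) > 0:
            mean_tau, sd_tau = float(t.mean()), float(t.std())  # population SD
        else:
            mean_tau, sd_tau = float("nan"), float("nan")
        summaries.append(
            ClusterSummary(
                cluster_id=cid,
                n_points=n_points,
                fraction=n_points / len(cloud),
                mean_tau_ns=mean_tau,
                sd_tau_ns=sd_tau,
                mean_g=float(cloud.g[member].mean()),
                mean_s=float(cloud.s[member].mean()),
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[ClusterSummary]):
    """Cluster summaries as a DataFrame with the report column order."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cluster": s.cluster_id,
                "n": s.n_points,
                "fraction": s.fraction,
                "mean_tau_ns": s.mean_tau_ns,
                "sd_tau_ns": s.sd_tau_ns,
                "mean_g": s.mean_g,
                "mean_s": s.mean_s,
            }
            for s in summaries
        ]
    )


def save_fit_report(result: FitResult, path) -> None:
    """Serialize a fit as a flat key-value text report."""
    params = result.params
    lines = [
        f"k = {params.k}",
        f"n_iter = {result.n_iter}",
        f"converged = {result.converged}",
        f"log_likelihood = {result.log_likelihood!r}",
    ]
    for i in range(params.k):
        mu = params.means[i]
        sigma = params.covariances[i]
        lines.append(f"fraction_{i + 1} = {params.fractions[i]!r}")
        lines.append(f"mean_{i + 1} = {mu[0]!r}, {mu[1]!r}")
        lines.append(
            f"cov_{i + 1} = {sigma[0, 0]!r}, {sigma[0, 1]!r}, {sigma[1, 1]!r}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
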