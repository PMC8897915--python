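"""Poisson log-linear latent-factor normalization of coverage.

The expected CNV-free coverage is modeled as

    lambda_ij = N_j * beta_i * exp(f(GC_i)) * exp(sum_t G_it H_jt)

with sample size factors N_j, region effects beta_i, a smooth GC-bias
curve f, and a rank-K latent term absorbing systematic artifacts. The fit
is block-coordinate ascent: exact conditional Poisson MLE updates for
beta and N, a LOESS refit of f against GC, and a truncated SVD of the
log-residual matrix for (G, H). Iterations that would increase the
Poisson deviance are rolled back, so the deviance path is non-increasing
by construction.

Normalization can run once globally, or independently per region: each
region is fit together with its k background neighbors and only its own
row of the fitted expectation is kept (fork-join; the result does not
depend on worker count or scheduling).
"""

from __future__ import annotations

import logging
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.nonparametric.smoothers_lowess import lowess

from .background import NeighborAssignment
from .io_coverage import CoverageMatrix

logger = logging.getLogger(__name__)

_DEV_EPS = 1e-12


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class LatentFactorConfig:
    K: int | str = "auto"  # latent rank, or "auto" for BIC selection
    K_max: int = 5
    max_iter: int = 100
    tol: float = 1e-6
    pseudocount: float = 0.5
    gc_span: float = 0.75

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.K != "auto" and (not isinstance(self.K, int) or self.K < 0):
            raise ValueError("K must be a non-negative integer or 'auto'")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class NormalizationModel:
    N: np.ndarray  # (m,) sample size factors, geometric mean 1
    beta: np.ndarray  # (n,) region effects
    f_gc: np.ndarray  # (n,) fitted GC curve at each region's GC, mean 0
    G: np.ndarray  # (n, K) latent loadings
    H: np.ndarray  # (m, K) latent scores
    K_used: int
    converged: bool
    n_iter: int
    final_deviance: float
    loglik: float
    deviance_path: list[float] = field(default_factory=list)
    flagged_regions: list[int] = field(default_factory=list)

    @property
    def lambda_hat(self) -> np.ndarray:
        gh = self.G @ self.H.T if self.K_used > 0 else 0.0
        return (
            self.N[None, :]
            * self.beta[:, None]
            * np.exp(self.f_gc)[:, None]
            * np.exp(gh)
        )


@dataclass
class NormalizedMatrix:
    lambda_hat: np.ndarray  # (n, m) strictly positive expectations
    region_ids: list[str]
    sample_ids: list[str]
    provenance: pd.DataFrame  # region_id, k_used, converged, n_iter, failed

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.lambda_hat)) or np.any(self.lambda_hat <= 0):
            raise NormalizationError("lambda_hat must be finite and positive")


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def _init_params(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    row_med = np.median(y, axis=1)
    row_med = np.where(row_med <= 0, 1.0, row_med)
    ratios = y / row_med[:, None]
    n_col = np.median(ratios, axis=0)
    n_col = np.where(n_col <= 0, 1.0, n_col)
    n_col = n_col / np.exp(np.mean(np.log(n_col)))
    beta = np.mean(y / n_col[None, :], axis=1)
    return n_col, beta


def fit_poisson_latent(
    sub_matrix: CoverageMatrix | np.ndarray,
    gc: np.ndarray,
    lengths: np.ndarray | None = None,
    config: LatentFactorConfig | None = None,
    K: int | None = None,
) -> NormalizationModel:
    """Fit the latent-factor model by block-coordinate ascent.

    ``lengths`` is accepted for interface stability; static length effects
    are absorbed by the region terms beta.
    """
    config = config or LatentFactorConfig()
    if K is None:
        if config.K == "auto":
            return select_K_model(sub_matrix, gc, lengths, config)
        K = int(config.K)
    y = sub_matrix.counts if isinstance(sub_matrix, CoverageMatrix) else sub_matrix
    y = np.asarray(y, dtype=float)
    n, m = y.shape
    if n < 2:
        raise NormalizationError("need at least 2 regions")
    if m < 3:
        raise NormalizationError("need at least 3 samples")
    if np.any(y.sum(axis=0) == 0):
        raise NormalizationError("all-zero sample column")
    gc = np.asarray(gc, dtype=float)
    if gc.shape[0] != n:
        raise NormalizationError("gc vector does not match region count")
    K = min(K, min(n, m) - 1)
    if n < 10 and K > 0:
        cap = n // 5
        if K > cap:
            logger.warning(
                "subgroup of %d regions is small; capping latent rank at %d", n, cap
            )
            K = cap
    c = config.pseudocount

    flagged = [int(i) for i in np.flatnonzero(y.sum(axis=1) == 0)]
    n_col, beta = _init_params(y)
    beta = np.where(beta <= 0, c / np.mean(n_col), beta)
    f_gc = np.zeros(n)
    gh = np.zeros((n, m))
    g_mat = np.zeros((n, K))
    h_mat = np.zeros((m, K))

    def mu_of(n_col, beta, f_gc, gh):
        return n_col[None, :] * beta[:, None] * np.exp(f_gc)[:, None] * np.exp(gh)

    dev_prev = poisson_deviance(y, mu_of(n_col, beta, f_gc, gh))
    path = [dev_prev]
    converged = False
    n_iter = 0
    for it in range(1, config.max_iter + 1):
        snapshot = (n_col.copy(), beta.copy(), f_gc.copy(), gh.copy(),
                    g_mat.copy(), h_mat.copy())
        e_gh = np.exp(gh)
        # exact conditional MLE for region effects
        denom = (n_col[None, :] * np.exp(f_gc)[:, None] * e_gh).sum(axis=1)
        beta = y.sum(axis=1) / denom
        beta = np.where(beta <= 0, c / np.mean(n_col), beta)
        # exact conditional MLE for sample factors, gmean fixed to 1
        denom = (beta[:, None] * np.exp(f_gc)[:, None] * e_gh).sum(axis=0)
        n_col = y.sum(axis=0) / denom
        scale = np.exp(np.mean(np.log(n_col)))
        n_col /= scale
        beta *= scale
        # smooth GC curve: the exact beta update above makes the region-level
        # residual vanish, so beta and f are confounded there. Decompose the
        # total region log-effect instead: its LOESS-vs-GC fit is f (centered),
        # the remainder stays in beta; lambda and the deviance are unchanged.
        total = np.log(beta) + f_gc
        f_raw = lowess(total, gc, frac=config.gc_span, return_sorted=False)
        f_gc = f_raw - float(np.mean(f_raw))
        beta = np.exp(total - f_gc)
        # rank-K SVD of log residuals for the latent term
        if K > 0:
            base = mu_of(n_col, beta, f_gc, np.zeros((n, m)))
            l_mat = np.log((y + c) / (base + c))
            u, s, vt = np.linalg.svd(l_mat, full_matrices=False)
            root = np.sqrt(s[:K])
            g_mat = u[:, :K] * root[None, :]
            h_mat = vt[:K, :].T * root[None, :]
            gh = g_mat @ h_mat.T
        dev = poisson_deviance(y, mu_of(n_col, beta, f_gc, gh))
        if dev > dev_prev * (1.0 + _DEV_EPS) + _DEV_EPS:
            # roll back the sweep; keep the best (monotone) state
            n_col, beta, f_gc, gh, g_mat, h_mat = snapshot
            converged = True
            n_iter = it
            break
        path.append(dev)
        n_iter = it
        rel = abs(dev_prev - dev) / max(dev_prev, _DEV_EPS)
        dev_prev = dev
        if rel < config.tol:
            converged = True
            break
    if not converged:
        logger.warning("normalization did not converge in %d iterations", n_iter)
    mu = mu_of(n_col, beta, f_gc, gh)
    return NormalizationModel(
        N=n_col,
        beta=beta,
        f_gc=f_gc,
        G=g_mat,
        H=h_mat,
        K_used=K,
        converged=converged,
        n_iter=n_iter,
        final_deviance=path[-1],
        loglik=poisson_loglik(y, mu),
        deviance_path=path,
        flagged_regions=flagged,
    )


def select_K_model(
    sub_matrix: CoverageMatrix | np.ndarray,
    gc: np.ndarray,
    lengths: np.ndarray | None,
    config: LatentFactorConfig,
) -> NormalizationModel:
    """Fit K = 0..K_max and return the model minimizing BIC."""
    y = sub_matrix.counts if isinstance(sub_matrix, CoverageMatrix) else sub_matrix
    n, m = y.shape
    best = None
    best_bic = np.inf
    for k in range(0, min(config.K_max, min(n, m) - 1) + 1):
        model = fit_poisson_latent(sub_matrix, gc, lengths, config, K=k)
        bic = -2.0 * model.loglik + k * (n + m) * np.log(n * m)
        if bic < best_bic:
            best, best_bic = model, bic
        if model.K_used < k:
            break  # rank was capped; higher k would refit the same model
    return best


def select_K(
    sub_matrix: CoverageMatrix | np.ndarray,
    gc: np.ndarray,
    lengths: np.ndarray | None = None,
    config: LatentFactorConfig | None = None,
) -> int:
    config = config or LatentFactorConfig()
    return select_K_model(sub_matrix, gc, lengths, config).K_used


def _fallback_row(y: np.ndarray, i: int) -> np.ndarray:
    """Rank-1 product estimate for a failed subgroup fit (kept positive)."""
    total = y.sum()
    row = y[i].sum() * y.sum(axis=0) / max(total, 1.0)
    return np.maximum(row, 0.5)


def _fit_subgroup(args) -> tuple[int, np.ndarray, dict]:
    i, y_sub, gc_sub, config = args
    try:
        model = fit_poisson_latent(y_sub, gc_sub, None, config)
        info = {
            "k_used": model.K_used,
            "converged": model.converged,
            "n_iter": model.n_iter,
            "failed": False,
        }
        return i, model.lambda_hat[0], info
    except Exception as exc:  # noqa: BLE001 - per-region isolation
        logger.warning("normalization failed for region %d: %s", i, exc)
        row = y_sub[0].astype(float)
        info = {"k_used": -1, "converged": False, "n_iter": 0, "failed": True}
        return i, np.maximum(row, 0.5), info


def normalize_region_independent(
    matrix: CoverageMatrix,
    gc: np.ndarray,
    neighbors: NeighborAssignment,
    config: LatentFactorConfig | None = None,
    workers: int = 1,
    max_failure_fraction: float = 0.1,
) -> NormalizedMatrix:
    """Fork-join independent normalization of every region.

    Region i is fit together with its k neighbors (subgroup of k+1 rows,
    region i first) and only row i of the subgroup expectation is kept.
    Output is identical for any worker count.
    """
    config = config or LatentFactorConfig()
    n = matrix.n_regions
    if neighbors.indices.shape[0] != n:
        raise NormalizationError("neighbor assignment does not cover the matrix")
    gc = np.asarray(gc, dtype=float)
    y = matrix.counts
    tasks = []
    for i in range(n):
        idx = np.concatenate([[i], neighbors.indices[i]])
        tasks.append((i, y[idx, :], gc[idx], config))
    lam = np.empty((n, matrix.n_samples))
    infos: list[dict] = [None] * n  # type: ignore[list-item]
    if workers > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            chunk = max(1, n // (workers * 4))
            results = pool.map(_fit_subgroup, tasks, chunksize=chunk)
            for i, row, info in results:
                lam[i] = row
                infos[i] = info
    else:
        done = 0
        for task in tasks:
            i, row, info = _fit_subgroup(task)
            lam[i] = row
            infos[i] = info
            done += 1
            if done % 100 == 0:
                logger.info("normalized %d/%d regions", done, n)
    n_failed = sum(1 for info in infos if info["failed"])
    if n_failed:
        logger.warning("%d/%d subgroup normalizations failed", n_failed, n)
    if n_failed > max_failure_fraction * n:
        raise NormalizationError(
            f"{n_failed}/{n} subgroup normalizations failed (> "
            f"{max_failure_fraction:.0%})"
        )
    # failed rows fall back to a rank-1 product estimate
    for i, info in enumerate(infos):
        if info["failed"]:
            lam[i] = _fallback_row(y.astype(float), i)
    provenance = pd.DataFrame(
        {
            "region_id": matrix.region_ids,
            "k_used": [info["k_used"] for info in infos],
            "converged": [info["converged"] for info in infos],
            "n_iter": [info["n_iter"] for info in infos],
            "failed": [info["failed"] for info in infos],
        }
    )
    return NormalizedMatrix(lam, list(matrix.region_ids), list(matrix.sample_ids), provenance)


def normalize_global(
    matrix: CoverageMatrix,
    gc: np.ndarray,
    config: LatentFactorConfig | None = None,
) -> NormalizedMatrix:
    """Single fit over all regions (chromosome-at-once baseline)."""
    config = config or LatentFactorConfig()
    model = fit_poisson_latent(matrix, np.asarray(gc, dtype=float), None, config)
    provenance = pd.DataFrame(
        {
            "region_id": matrix.region_ids,
            "k_used": model.K_used,
            "converged": model.converged,
            "n_iter": model.n_iter,
            "failed": False,
        }
    )
    return NormalizedMatrix(
        model.lambda_hat,
        list(matrix.region_ids),
        list(matrix.sample_ids),
        provenance,
    )


def write_normalized_tsv(norm: NormalizedMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(norm.lambda_hat, index=norm.region_ids, columns=norm.sample_ids)
    df.index.name = "region_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_normalized_tsv(path: str | os.PathLike) -> NormalizedMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    provenance = pd.DataFrame(
        {
            "region_id": list(df.index),
            "k_used": -1,
            "converged": True,
            "n_iter": 0,
            "failed": False,
        }
    )
    return NormalizedMatrix(
        df.to_numpy(dtype=float), list(df.index), list(df.columns), provenance
    )
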