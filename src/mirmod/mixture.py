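"""Shared-variance diagonal Gaussian mixture with missing-data marginalization.

The model clusters patients from the expression of co-module transcripts.
Given cluster k, features are conditionally independent univariate normals
with cluster-specific means and exactly two standard deviations: one shared by
all genes and one shared by all miRNAs.  Sharing the scale across features
keeps the parameter count small (stable clustering on cohorts of ~100-200
patients) and damps the influence of low-variance noisy features.  Missing
cells are marginalized exactly: a patient's likelihood is the product over its
*observed* cells only, which is the correct EM treatment of a diagonal model
under missing-at-random.

The estimator follows sklearn conventions (get_params/set_params, fit /
predict / predict_proba, trailing-underscore fitted attributes) and composes
with sklearn model-selection utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

_LOG2PI = np.log(2 * np.pi)


def _check_X(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (patients x features)")
    return X


class SharedVarianceGMM(BaseEstimator):
    """Gaussian mixture with one sd per feature block, NaN-aware EM.

    Parameters
    ----------
    n_components : number of patient subgroups K.
    n_gene_features : how many leading columns of X are genes; the remaining
        columns are miRNAs.  ``None`` treats every column as a gene.
    n_restarts : EM restarts from random responsibilities; the run with the
        best final log-likelihood wins.
    tol : relative log-likelihood change declaring convergence.
    max_iter : iteration cap per restart.
    var_floor : lower bound on each shared variance, preventing degenerate
        collapse on small cohorts.
    random_state : seed for the restart initializations.

    Attributes (after ``fit``)
    --------------------------
    weights_ : (K,) mixing coefficients.
    means_ : (K, D) cluster mean matrix (gene columns then miRNA columns).
    sigma_gene_, sigma_mirna_ : the two shared standard deviations
        (``sigma_mirna_`` is None when there are no miRNA columns).
    log_likelihood_ : best final log-likelihood on the training data.
    n_iter_, converged_, loglik_path_ : diagnostics of the winning run.
    """

    def __init__(
        self,
        n_components: int = 2,
        n_gene_features: int | None = None,
        n_restarts: int = 20,
        tol: float = 1e-6,
        max_iter: int = 500,
        var_floor: float = 1e-4,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.n_gene_features = n_gene_features
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.var_floor = var_floor
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _blocks(self, D: int) -> list[np.ndarray]:
        G = D if self.n_gene_features is None else self.n_gene_features
        if not 0 <= G <= D:
            raise ValueError(f"n_gene_features={G} out of range for D={D}")
        cols = np.arange(D)
        blocks = [cols[:G], cols[G:]]
        return [b for b in blocks if b.size]

    def _log_density(self, X0, W, means, variances, blocks):
        """(N, K) per-patient per-cluster log density over observed cells."""
        N = X0.shape[0]
        K = means.shape[0]
        out = np.zeros((N, K))
        for b, var in zip(blocks, variances):
            Xb, Wb = X0[:, b], W[:, b]
            n_obs = Wb.sum(axis=1)
            for k in range(K):
                resid = ((Xb - means[k, b]) ** 2 * Wb).sum(axis=1)
                out[:, k] += -0.5 * n_obs * (_LOG2PI + np.log(var)) - resid / (2 * var)
        return out

    def _m_step(self, X0, W, resp, blocks):
        Nk = resp.sum(axis=0)
        weights = Nk / resp.shape[0]
        denom = resp.T @ W  # (K, D) responsibility mass on observed cells
        numer = resp.T @ (X0 * W)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = numer / denom
        if np.any(denom == 0):  # empty cluster-feature cell: fall back to pooled mean
            pooled = (X0 * W).sum(axis=0) / W.sum(axis=0)
            means = np.where(denom == 0, pooled[None, :], means)
        variances = []
        for b in blocks:
            resid = 0.0
            for k in range(means.shape[0]):
                resid += (resp[:, k][:, None] * (X0[:, b] - means[k, b]) ** 2 * W[:, b]).sum()
            variances.append(max(resid / W[:, b].sum(), self.var_floor))
        return weights, means, variances

    def _fit_once(self, X0, W, rng, blocks):
        N = X0.shape[0]
        K = self.n_components
        resp = rng.dirichlet(np.ones(K), size=N)
        weights, means, variances = self._m_step(X0, W, resp, blocks)
        path = []
        prev = -np.inf
        converged = False
        for it in range(1, self.max_iter + 1):
            log_dens = self._log_density(X0, W, means, variances, blocks)
            weighted = log_dens + np.log(weights)[None, :]
            norm = logsumexp(weighted, axis=1)
            loglik = float(norm.sum())
            path.append(loglik)
            if np.isfinite(prev) and abs(loglik - prev) <= self.tol * max(abs(prev), 1.0):
                converged = True
                break  # loglik matches the current (returned) parameters
            resp = np.exp(weighted - norm[:, None])
            weights, means, variances = self._m_step(X0, W, resp, blocks)
            prev = loglik
        if not converged:  # parameters moved after the last evaluation
            log_dens = self._log_density(X0, W, means, variances, blocks)
            loglik = float(
                logsumexp(log_dens + np.log(weights)[None, :], axis=1).sum()
            )
            path.append(loglik)
        return loglik, weights, means, variances, path, it, converged

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None) -> "SharedVarianceGMM":
        X = _check_X(X)
        N, D = X.shape
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_components > N:
            raise ValueError(f"n_components={self.n_components} exceeds N={N}")
        W = ~np.isnan(X)
        if not W.any(axis=1).all():
            raise ValueError("every patient needs at least one observed value")
        empty = np.flatnonzero(~W.any(axis=0))
        if empty.size:
            raise ValueError(f"features with zero observed cells: {empty.tolist()}")
        blocks = self._blocks(D)
        X0 = np.nan_to_num(X)
        Wf = W.astype(float)
        ss = np.random.SeedSequence(self.random_state)
        best = None
        for child in ss.spawn(max(1, self.n_restarts)):
            run = self._fit_once(X0, Wf, np.random.default_rng(child), blocks)
            if best is None or run[0] > best[0]:
                best = run
        loglik, weights, means, variances, path, n_iter, converged = best
        self.weights_ = weights
        self.means_ = means
        self.variances_ = variances
        G = D if self.n_gene_features is None else self.n_gene_features
        vit = iter(variances)
        self.sigma_gene_ = float(np.sqrt(next(vit))) if G else None
        self.sigma_mirna_ = float(np.sqrt(next(vit))) if G < D else None
        self.log_likelihood_ = loglik
        self.loglik_path_ = path
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_features_in_ = D
        return self

    def _log_resp(self, X):
        X = _check_X(X)
        W = (~np.isnan(X)).astype(float)
        log_dens = self._log_density(
            np.nan_to_num(X), W, self.means_, self.variances_, self._blocks(X.shape[1])
        )
        weighted = log_dens + np.log(self.weights_)[None, :]
        return weighted - logsumexp(weighted, axis=1)[:, None]

    def predict_proba(self, X) -> np.ndarray:
        """Responsibilities; rows sum to 1, missing cells marginalized out."""
        return np.exp(self._log_resp(X))

    def predict(self, X) -> np.ndarray:
        """Cluster index per patient (ties resolved to the lowest index)."""
        return np.argmax(self.predict_proba(X), axis=1)

    def log_likelihood(self, X) -> float:
        X = _check_X(X)
        W = (~np.isnan(X)).astype(float)
        log_dens = self._log_density(
            np.nan_to_num(X), W, self.means_, self.variances_, self._blocks(X.shape[1])
        )
        return float(logsumexp(log_dens + np.log(self.weights_)[None, :], axis=1).sum())

    @property
    def n_parameters_(self) -> int:
        """(K-1) mixing weights + K*D means + one sd per feature block."""
        K, D = self.means_.shape
        return (K - 1) + K * D + len(self.variances_)

    def bic(self, X) -> float:
        """2*loglik - n_params*ln(N); larger is better under this convention."""
        X = _check_X(X)
        return 2 * self.log_likelihood(X) - self.n_parameters_ * np.log(X.shape[0])


@dataclass
class ClusteringResult:
    assignments: pd.Series  # patient -> cluster index
    responsibilities: pd.DataFrame  # patients x K
    loglik: float
    bic: float
    n_params: int


def _stack(X_gene, X_mirna):
    X_gene = np.asarray(X_gene, dtype=float)
    if X_mirna is None or np.size(X_mirna) == 0:
        return X_gene, X_gene.shape[1]
    return np.hstack([X_gene, np.asarray(X_mirna, dtype=float)]), X_gene.shape[1]


def em_fit(
    X_gene,
    X_mirna,
    K: int,
    seed: int | None = None,
    restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    var_floor: float = 1e-4,
    patient_ids=None,
) -> tuple[SharedVarianceGMM, ClusteringResult]:
    """Fit the mixture on gene and miRNA blocks and assign every patient."""
    X, G = _stack(X_gene, X_mirna)
    model = SharedVarianceGMM(
        n_components=K,
        n_gene_features=G,
        n_restarts=restarts,
        tol=tol,
        max_iter=max_iter,
        var_floor=var_floor,
        random_state=seed,
    ).fit(X)
    if patient_ids is None:
        patient_ids = pd.RangeIndex(X.shape[0])
    resp = pd.DataFrame(model.predict_proba(X), index=patient_ids)
    result = ClusteringResult(
        assignments=pd.Series(model.predict(X), index=patient_ids),
        responsibilities=resp,
        loglik=model.log_likelihood_,
        bic=model.bic(X),
        n_params=model.n_parameters_,
    )
    return model, result


def select_k(
    X_gene,
    X_mirna,
    k_min: int = 1,
    k_max: int = 6,
    seed: int | None = None,
    **em_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Fit K in [k_min, k_max], return the BIC-maximizing K and the table."""
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if k_min > k_max:
        raise ValueError("k_min must not exceed k_max")
    rows = []
    for K in range(k_min, k_max + 1):
        _, result = em_fit(X_gene, X_mirna, K, seed=seed, **em_kwargs)
        rows.append({"K": K, "loglik": result.loglik, "n_params": result.n_params,
                     "bic": result.bic})
    table = pd.DataFrame(rows).set_index("K")
    return int(table["bic"].idxmax()), table
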