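"""Admixture-model ancestry estimation with cross-validated choice of K.

Model: accession i's genotype at marker l is Binomial(2, p_il) with
p_il = sum_k q_ik f_kl, where q_i are the accession's ancestry proportions
over K ancestral groups and f_k the group allele frequencies. Parameters
are estimated by plain EM over the allele-origin latent variables (same
stationary points as accelerated implementations of this likelihood, just
slower); the log-likelihood is checked to be non-decreasing each iteration.

K is chosen by masking a fold of non-missing genotype entries, fitting on
the rest, predicting each masked genotype as 2 p_il, and scoring the mean
of (g - 2 p)^2 / 2 over masked entries, averaged over folds; the K with
the smallest cross-validation error wins (ties to the smaller K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import rng_for
from .genotypes import GenotypeMatrix

__all__ = ["AdmixtureFit", "CvCurve", "admixture_em", "choose_k"]

_EPS = 1e-6


@dataclass
class AdmixtureFit:
    q: np.ndarray  # accessions x K, rows sum to 1
    f: np.ndarray  # K x markers, in [eps, 1-eps]
    loglik: float
    n_iter: int
    seed: int
    loglik_path: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("ancestry rows must sum to 1")
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood not finite")


@dataclass
class CvCurve:
    k_values: list[int]
    cv_error: list[float]
    best_k: int

    def __post_init__(self) -> None:
        if len(self.k_values) != len(self.cv_error):
            raise ValueError("k_values and cv_error lengths differ")
        if self.best_k not in self.k_values:
            raise ValueError("best_k not among k_values")


def _loglik(g: np.ndarray, obs: np.ndarray, p: np.ndarray) -> float:
    ll = np.where(obs, g * np.log(p) + (2.0 - g) * np.log1p(-p), 0.0)
    return float(ll.sum())


def admixture_em(
    gm: GenotypeMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_init: int = 1,
) -> AdmixtureFit:
    """Fit the K-group admixture model by EM.

    Accepts a GenotypeMatrix or a raw dosage array (NaN = missing). Missing
    entries are skipped in both likelihood and updates. Initialization: q
    rows from a symmetric Dirichlet(1); f from the observed allele
    frequencies jittered by seeded U(-0.05, 0.05), clipped to [eps, 1-eps].
    With ``n_init`` > 1, that many independently seeded runs are fit and
    the one with the best final log-likelihood is returned.
    """
    if n_init > 1:
        fits = [
            admixture_em(gm, k, seed=seed + 7919 * r, tol=tol, max_iter=max_iter)
            for r in range(n_init)
        ]
        return max(fits, key=lambda f: f.loglik)
    d = gm.dosages if isinstance(gm, GenotypeMatrix) else np.asarray(gm, dtype=float)
    n, m = d.shape
    if not 1 <= k <= n:
        raise ValueError("k must be between 1 and the number of accessions")
    obs = ~np.isnan(d)
    n_obs_col = obs.sum(axis=0)
    if not ((np.nansum(d, axis=0) > 0) & (np.nansum(d, axis=0) < 2 * n_obs_col)).any():
        raise ValueError("no polymorphic marker")
    g = np.where(obs, d, 0.0)
    g2 = np.where(obs, 2.0 - d, 0.0)  # reference-allele count, 0 at missing

    rng = rng_for(seed, "admixture-em")
    with np.errstate(invalid="ignore"):
        freq = np.nansum(d, axis=0) / (2.0 * np.maximum(n_obs_col, 1))
    q = rng.dirichlet(np.ones(k), size=n)
    f = np.clip(freq[None, :] + rng.uniform(-0.05, 0.05, size=(k, m)), _EPS, 1 - _EPS)

    n_obs_row = 2.0 * obs.sum(axis=1)  # allele copies observed per accession
    path = []
    prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        p = np.clip(q @ f, _EPS, 1 - _EPS)
        ll = _loglik(g, obs, p)
        path.append(ll)
        if ll < prev - 1e-9 * max(1.0, abs(prev)):
            raise RuntimeError("EM log-likelihood decreased")
        # E-step responsibilities folded into M-step sufficient statistics
        alt = g / p  # n x m
        ref = g2 / (1.0 - p)
        # expected alt/ref allele copies from group k: q_ik f_kl alt_il etc.
        a_qf = alt @ f.T  # n x k, sum_l alt_il f_kl
        r_qf = ref @ (1.0 - f).T
        q_new = q * (a_qf + r_qf) / n_obs_row[:, None]
        q_new /= q_new.sum(axis=1, keepdims=True)
        a_f = (q * 1.0).T @ alt * f  # k x m: sum_i q_ik alt_il, times f_kl
        r_f = q.T @ ref * (1.0 - f)
        f_new = np.clip(a_f / np.maximum(a_f + r_f, 1e-300), _EPS, 1 - _EPS)
        q, f = q_new, f_new
        if prev > -np.inf and abs(ll - prev) <= tol * (abs(prev) + 1e-12):
            prev = ll
            break
        prev = ll
    p = np.clip(q @ f, _EPS, 1 - _EPS)
    final = _loglik(g, obs, p)
    path.append(final)
    return AdmixtureFit(q=q, f=f, loglik=final, n_iter=it, seed=seed,
                        loglik_path=np.asarray(path))


def predict_dosage(fit: AdmixtureFit) -> np.ndarray:
    """Expected dosage 2 p_il under the fitted model."""
    return 2.0 * np.clip(fit.q @ fit.f, _EPS, 1 - _EPS)


def choose_k(
    gm: GenotypeMatrix | np.ndarray,
    k_range: range | list[int] = range(1, 11),
    folds: int = 5,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 500,
    n_init: int = 3,
) -> CvCurve:
    """Choose K by fold-masked genotype cross-validation.

    Non-missing entries are assigned to folds by a seeded shuffle; for each
    fold the masked entries are held out, the model is refit, and held-out
    genotypes are scored as (g - 2 p)^2 / 2. Deterministic given the seed.
    """
    d = gm.dosages if isinstance(gm, GenotypeMatrix) else np.asarray(gm, dtype=float)
    obs_idx = np.argwhere(~np.isnan(d))
    if len(obs_idx) < folds:
        raise ValueError("not enough non-missing entries for the folds")
    rng = rng_for(seed, "cv-folds")
    assignment = np.arange(len(obs_idx)) % folds
    rng.shuffle(assignment)
    k_values = list(k_range)
    errors: list[float] = []
    for k in k_values:
        fold_err = []
        for fold in range(folds):
            mask = assignment == fold
            if not mask.any():
                raise ValueError(f"fold {fold} has no masked entries")
            rows, cols = obs_idx[mask, 0], obs_idx[mask, 1]
            train = d.copy()
            train[rows, cols] = np.nan
            fit = admixture_em(train, k, seed=seed * 1000 + fold, tol=tol,
                               max_iter=max_iter, n_init=n_init)
            pred = 2.0 * np.clip(fit.q @ fit.f, _EPS, 1 - _EPS)
            err = (d[rows, cols] - pred[rows, cols]) ** 2 / 2.0
            fold_err.append(float(err.mean()))
        errors.append(float(np.mean(fold_err)))
    best = k_values[int(np.argmin(errors))]
    return CvCurve(k_values=k_values, cv_error=errors, best_k=best)
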