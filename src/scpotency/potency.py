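"""Discrete potency states from logit-transformed normalized entropy rates.

Normalized entropy rates SR lie in (0, 1); on the logit scale
``y = log2(SR / (1 - SR))`` the population typically decomposes into a
small number of roughly Gaussian potency states.  A one-dimensional
Gaussian mixture is fitted by EM for K = 1..k_max components and the
Bayesian Information Criterion selects K; states are relabeled PS1..PSK
by ascending mean, so PSK (largest mean) is the high-potency state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.cluster import KMeans

__all__ = ["PotencyModel", "logit_sr", "infer_potency_states", "assign_state"]


def logit_sr(srn):
    """Base-2 logit of a normalized entropy rate, y = log2(SR/(1-SR)).

    Accepts a scalar or array; every value must lie strictly in (0, 1).
    """
    arr = np.asarray(srn, dtype=float)
    if np.any((arr <= 0) | (arr >= 1)):
        raise ValueError("logit requires values strictly inside (0, 1)")
    out = np.log2(arr / (1.0 - arr))
    return float(out) if np.isscalar(srn) or arr.ndim == 0 else out


@dataclass
class PotencyModel:
    """Fitted 1-D Gaussian mixture over logit-SR values.

    Components are ordered by ascending mean; state labels are the
    1-based integers 1..K (PS1 lowest potency ... PSK highest).
    """

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    bic_table: pd.Series      # index K, value BIC
    posteriors: np.ndarray    # n_cells x K
    labels: np.ndarray        # 1-based hard assignments
    equal_variance: bool = False
    seed: int = 0

    @property
    def high_state(self) -> int:
        """The high-potency state label (component of largest mean)."""
        return self.k

    def state_name(self, label: int) -> str:
        return f"PS{label}"

    def to_frame(self, y: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.posteriors, columns=[f"PS{k + 1}" for k in range(self.k)]
        )
        df.insert(0, "state", self.labels)
        if y is not None:
            df.insert(0, "logitSR", np.asarray(y, float))
        return df


_N_RESTARTS = 10
_EM_TOL = 1e-8
_EM_MAX_ITER = 500


def _em_1d(
    y: np.ndarray,
    k: int,
    seed: int,
    equal_variance: bool,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Best-of-restarts EM fit of a k-component 1-D Gaussian mixture.

    k-means initialization with 10 seeded restarts; convergence when
    the mean log-likelihood improves by less than 1e-8, capped at 500
    iterations.  A variance floor (1e-8 of the data variance) prevents
    components collapsing onto single points.  Returns
    ``(loglik, weights, means, sds)``.
    """
    n = y.size
    var_floor = max(1e-8 * y.var(), 1e-300)
    best = (-np.inf, None, None, None)
    for restart in range(_N_RESTARTS):
        if k == 1:
            means = np.array([y.mean()])
        else:
            km = KMeans(n_clusters=k, n_init=1, random_state=seed + restart)
            means = km.fit(y.reshape(-1, 1)).cluster_centers_.ravel()
        variances = np.full(k, max(y.var() / k, var_floor))
        weights = np.full(k, 1.0 / k)
        prev_ll = -np.inf
        for _ in range(_EM_MAX_ITER):
            # E step in log space
            log_comp = (
                np.log(weights)[None, :]
                - 0.5 * np.log(2 * np.pi * variances)[None, :]
                - 0.5 * (y[:, None] - means[None, :]) ** 2 / variances[None, :]
            )
            mx = log_comp.max(axis=1, keepdims=True)
            log_norm = mx.ravel() + np.log(np.exp(log_comp - mx).sum(axis=1))
            ll = float(log_norm.mean())
            resp = np.exp(log_comp - log_norm[:, None])
            # M step
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-12)
            weights = nk / n
            means = (resp * y[:, None]).sum(axis=0) / nk
            dev2 = (y[:, None] - means[None, :]) ** 2
            if equal_variance:
                v = float((resp * dev2).sum() / n)
                variances = np.full(k, max(v, var_floor))
            else:
                variances = np.maximum((resp * dev2).sum(axis=0) / nk, var_floor)
            if ll - prev_ll < _EM_TOL:
                break
            prev_ll = ll
        if ll > best[0]:
            best = (ll * n, weights, means, np.sqrt(variances))
        if k == 1:
            break  # restarts are identical for one component
    return best


def _bic(loglik: float, k: int, n: int, equal_variance: bool) -> float:
    p = (k - 1) + k + (1 if equal_variance else k)
    return -2.0 * loglik + p * np.log(n)


def infer_potency_states(
    y,
    k_max: int = 6,
    seed: int = 0,
    equal_variance: bool = False,
) -> PotencyModel:
    """Fit 1-D Gaussian mixtures for K = 1..k_max and select K by BIC.

    BIC = -2 log L + p ln(n) is minimized (equivalent to the maximizing
    convention of sign-flipped definitions).  EM uses k-means
    initialization with 10 restarts, tolerance 1e-8 and at most 500
    iterations, all seeded, so the fit is deterministic.  The default
    variance model allows a separate variance per component;
    ``equal_variance=True`` ties them.

    Requires at least ``10 * k_max`` finite observations and a
    non-degenerate spread of values.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("logit-SR values must be finite")
    if y.size < 10 * k_max:
        raise ValueError(
            f"need at least {10 * k_max} observations for k_max={k_max}, got {y.size}"
        )
    if np.ptp(y) == 0:
        raise ValueError("all values identical; mixture variance is degenerate")

    bics = {}
    fits = {}
    for k in range(1, k_max + 1):
        ll, weights_k, means_k, sds_k = _em_1d(y, k, seed, equal_variance)
        bics[k] = _bic(ll, k, y.size, equal_variance)
        fits[k] = (weights_k, means_k, sds_k)
    bic_table = pd.Series(bics, name="BIC")
    best_k = int(bic_table.idxmin())
    weights, means, sds = fits[best_k]

    order = np.argsort(means, kind="stable")
    model = PotencyModel(
        k=best_k,
        means=means[order],
        sds=sds[order],
        weights=weights[order],
        bic_table=bic_table,
        posteriors=np.empty((0, best_k)),
        labels=np.empty(0, dtype=int),
        equal_variance=equal_variance,
        seed=seed,
    )
    model.labels, model.posteriors = assign_state(model, y)
    return model


def assign_state(model: PotencyModel, y) -> tuple[np.ndarray, np.ndarray]:
    """Posterior state membership and hard labels for new logit-SR values.

    Posterior ~ weight_k * Normal(y; mean_k, sd_k), normalized per cell;
    the hard label is the argmax posterior with ties resolved to the
    lower state index.  Returns ``(labels, posteriors)`` with 1-based
    labels.
    """
    y = np.asarray(y, dtype=float).ravel()
    log_dens = (
        np.log(model.weights)[None, :]
        + norm.logpdf(y[:, None], loc=model.means[None, :], scale=model.sds[None, :])
    )
    log_dens -= log_dens.max(axis=1, keepdims=True)
    post = np.exp(log_dens)
    post /= post.sum(axis=1, keepdims=True)
    labels = np.argmax(post, axis=1) + 1  # argmax takes the first max: lower index wins ties
    return labels, post
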