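"""1-D Gaussian mixture fitting by EM with BIC model selection.

The bouton-volume samples are modeled as univariate Gaussian mixtures; the
component count and variance structure (equal or free per-component
variance) are selected by the highest BIC, using the convention

    BIC = 2 * loglik - p * ln(n)

where p counts free parameters: (k - 1) weights + k means + (k or 1)
variances.  Higher is better under this sign convention.

Fitting uses expectation-maximization with a variance floor (1e-6 um^6)
against singular components, quantile-spread initialization, and the best of
several seeded restarts.  The per-iteration log-likelihood trace is retained
on the returned fit so the EM monotonicity guarantee is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ModelingError

VARIANCE_MODELS = ("equal", "free")
VARIANCE_FLOOR = 1e-6  # um^6
DEFAULT_K_MAX = 9
DEFAULT_RESTARTS = 10
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000


@dataclass
class MixtureFit:
    """A fitted 1-D Gaussian mixture, components sorted by mean."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    variance_model: str
    n: int
    converged: bool
    n_iter: int = 0
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        return {
            "k": int(self.k),
            "weights": [float(w) for w in self.weights],
            "means": [float(m) for m in self.means],
            "sds": [float(s) for s in self.sds],
            "loglik": float(self.loglik),
            "bic": float(self.bic),
            "variance_model": self.variance_model,
            "n": int(self.n),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureFit":
        return cls(
            k=d["k"],
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            loglik=d["loglik"],
            bic=d["bic"],
            variance_model=d["variance_model"],
            n=d["n"],
            converged=d["converged"],
        )


def n_parameters(k: int, variance_model: str) -> int:
    """Free-parameter count: (k-1) weights + k means + k or 1 variances."""
    return (k - 1) + k + (k if variance_model == "free" else 1)


def bic_score(loglik: float, k: int, variance_model: str, n: int) -> float:
    return 2.0 * loglik - n_parameters(k, variance_model) * np.log(n)


_LOG_2PI = float(np.log(2 * np.pi))


def _em_once(x, k, variance_model, means0, max_iter, tol, state=None):
    """One EM run; returns (w, mu, var, ll, trace, converged, it).

    ``state`` optionally resumes from (w, mu, var) instead of the
    quantile-spread initialization (used to polish the best restart).
    """
    n = x.size
    if state is None:
        w = np.full(k, 1.0 / k)
        mu = means0.astype(float).copy()
        var = np.full(k, max(np.var(x) / k, VARIANCE_FLOOR))
    else:
        w, mu, var = (a.copy() for a in state)
    xc = x[:, None]
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: log responsibilities via a hand-rolled logsumexp
        logp = (
            np.log(w)
            - 0.5 * (_LOG_2PI + np.log(var))
            - 0.5 * (xc - mu) ** 2 / var
        )
        mx = logp.max(axis=1)
        np.exp(logp - mx[:, None], out=logp)
        norm = logp.sum(axis=1)
        ll = float((mx + np.log(norm)).sum())
        trace.append(ll)
        resp = logp / norm[:, None]
        # M-step
        nk = np.maximum(resp.sum(axis=0), 1e-300)
        w = nk / n
        mu = resp.T @ x / nk
        sq = (xc - mu) ** 2
        if variance_model == "free":
            var = np.einsum("ij,ij->j", resp, sq) / nk
        else:
            var = np.full(k, float(np.einsum("ij,ij->", resp, sq)) / n)
        var = np.maximum(var, VARIANCE_FLOOR)
        if prev > -np.inf and abs(ll - prev) <= tol * abs(prev):
            converged = True
            break
        prev = ll
    # final log-likelihood under the last parameter update
    logp = (
        np.log(w)
        - 0.5 * (_LOG_2PI + np.log(var))
        - 0.5 * (xc - mu) ** 2 / var
    )
    mx = logp.max(axis=1)
    ll = float((mx + np.log(np.exp(logp - mx[:, None]).sum(axis=1))).sum())
    trace.append(ll)
    return w, mu, var, ll, np.array(trace), converged, it


def _kmeans_1d(x, k, rng, n_iter=15):
    """Lloyd's k-means on 1-D data with k-means++ seeding; returns centers."""
    centers = np.empty(k)
    centers[0] = x[rng.integers(x.size)]
    d2 = (x - centers[0]) ** 2
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j:] = centers[0]
            break
        centers[j] = x[rng.choice(x.size, p=d2 / total)]
        d2 = np.minimum(d2, (x - centers[j]) ** 2)
    for _ in range(n_iter):
        assign = np.abs(x[:, None] - centers).argmin(axis=1)
        for j in range(k):
            sel = assign == j
            if sel.any():
                centers[j] = x[sel].mean()
    return np.sort(centers)


def fit_em(
    volumes,
    k: int,
    variance_model: str = "free",
    seed: int | None = None,
    n_restarts: int = DEFAULT_RESTARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> MixtureFit:
    """Fit a k-component 1-D Gaussian mixture by EM.

    The best of ``n_restarts`` quantile-spread initializations (by final
    log-likelihood) is returned, components sorted by mean.  Requires
    n >= 2k finite positive observations.
    """
    if variance_model not in VARIANCE_MODELS:
        raise ModelingError(f"unknown variance model {variance_model!r}")
    x = np.asarray(volumes, dtype=float).ravel()
    if x.size < 2 * k:
        raise InsufficientDataError(
            f"need at least {2 * k} observations for k={k} (got {x.size})"
        )
    if not np.all(np.isfinite(x)) or (x <= 0).any():
        raise ModelingError("volumes must be finite and positive")
    if k > 1 and np.ptp(x) == 0:
        raise ModelingError("all values identical: degenerate fit for k > 1")

    rng = np.random.default_rng(seed)
    # Screen restarts with short EM runs, then polish the best to full
    # tolerance (em-EM strategy); k=1 has a closed form after one pass.
    # Restart 0 uses evenly spread quantiles, restart 1 a k-means solution
    # (reliably isolates small, well-separated components), the rest random
    # quantile spreads.
    screen_iter = min(max_iter, 1 if k == 1 else 100)
    best = None
    for r in range(1 if k == 1 else max(1, n_restarts)):
        if r == 0:
            means0 = np.quantile(x, (np.arange(k) + 0.5) / k)
        elif r == 1:
            means0 = _kmeans_1d(x, k, rng)
        else:
            means0 = np.quantile(x, np.sort(rng.uniform(0.0, 1.0, size=k)))
        w, mu, var, ll, trace, conv, it = _em_once(
            x, k, variance_model, np.sort(means0), screen_iter, tol
        )
        if best is None or ll > best[3]:
            best = (w, mu, var, ll, trace, conv, it)
    w, mu, var, ll, trace, conv, it = best
    if not conv and it >= screen_iter:
        w, mu, var, ll, trace2, conv, it2 = _em_once(
            x, k, variance_model, mu, max_iter - screen_iter, tol,
            state=(w, mu, var),
        )
        trace = np.concatenate([trace[:-1], trace2])
        it += it2
    order = np.argsort(mu)
    return MixtureFit(
        k=k,
        weights=w[order],
        means=mu[order],
        sds=np.sqrt(var[order]),
        loglik=ll,
        bic=bic_score(ll, k, variance_model, x.size),
        variance_model=variance_model,
        n=x.size,
        converged=conv,
        n_iter=it,
        loglik_trace=trace,
    )


def select_by_bic(
    volumes,
    k_max: int = DEFAULT_K_MAX,
    seed: int | None = None,
    k_min: int = 1,
    n_restarts: int = DEFAULT_RESTARTS,
) -> tuple[MixtureFit, pd.DataFrame]:
    """Scan k = k_min..k_max over both variance models; pick the highest BIC.

    Returns ``(best_fit, table)`` where the table lists (k, variance_model,
    bic, loglik, converged) for every attempted fit, NaN BIC for fits that
    failed (e.g. too few observations for large k).
    """
    if k_max < 1 or k_min < 1 or k_min > k_max:
        raise ModelingError("require 1 <= k_min <= k_max")
    x = np.asarray(volumes, dtype=float).ravel()
    ss = np.random.SeedSequence(seed)
    rows = []
    best = None
    for k in range(k_min, k_max + 1):
        for vm in VARIANCE_MODELS:
            child = np.random.default_rng(ss.spawn(1)[0])
            sub_seed = int(child.integers(0, 2**31 - 1))
            try:
                fit = fit_em(x, k, vm, seed=sub_seed, n_restarts=n_restarts)
            except ModelingError:
                rows.append((k, vm, np.nan, np.nan, False))
                continue
            rows.append((k, vm, fit.bic, fit.loglik, fit.converged))
            if best is None or fit.bic > best.bic:
                best = fit
    table = pd.DataFrame(
        rows, columns=["k", "variance_model", "bic", "loglik", "converged"]
    )
    if best is None:
        raise ModelingError("all mixture fits failed over the requested k range")
    return best, table
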