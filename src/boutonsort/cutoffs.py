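"""Volume cutoffs between adjacent mixture components.

Two routes are provided:

* :func:`analytic_crossing` — the point where the weighted component
  densities are equal, obtained in closed form (linear for equal SDs,
  quadratic otherwise).  This is the theoretical boundary that minimizes
  expected misclassification between two weighted normal subpopulations.
* :func:`mc_cutoffs` — the Monte Carlo resampling procedure: per iteration,
  each component is simulated with ``multiplier x round(weight * n)``
  positive draws (relative subpopulation sizes kept constant), and the
  cutoff between adjacent components is the threshold minimizing the total
  misclassification of the two simulated samples, scanning over midpoints of
  the sorted pooled sample with ties broken toward the smallest threshold.
  The reported boundary is the mean over ``R`` iterations (default 10,000),
  with the across-iteration SD alongside.

The empirical minimum-misclassification threshold has the weighted-density
crossing as its expectation, so the two routes agree for adequately sized
components; the analytic route doubles as an oracle for the Monte Carlo one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ModelingError, NoCrossingError

DEFAULT_ITERATIONS = 10_000
DEFAULT_MULTIPLIER = 5


@dataclass(frozen=True)
class CutoffSet:
    """Ordered volume boundaries between adjacent subpopulations."""

    family: str
    boundaries: tuple
    method: str  # "analytic" | "monte_carlo"
    iterations: int = 0
    multiplier: int = 0
    boundary_sd: tuple = ()

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b.size and not np.all(np.diff(b) > 0):
            raise ConfigurationError("cutoff boundaries must be strictly increasing")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "boundaries": [float(b) for b in self.boundaries],
            "method": self.method,
            "iterations": int(self.iterations),
            "multiplier": int(self.multiplier),
            "boundary_sd": [float(s) for s in self.boundary_sd],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutoffSet":
        return cls(
            family=d["family"],
            boundaries=tuple(d["boundaries"]),
            method=d["method"],
            iterations=d.get("iterations", 0),
            multiplier=d.get("multiplier", 0),
            boundary_sd=tuple(d.get("boundary_sd", ())),
        )


def analytic_crossing(w1, m1, s1, w2, m2, s2) -> float:
    """Solve w1*N(x; m1, s1) = w2*N(x; m2, s2) between the two means.

    For equal SDs the crossing is unique and returned wherever it lies.
    For unequal SDs the log-density equality is quadratic with two roots;
    the root inside (m1, m2) is returned, and if neither root falls in the
    inter-mean interval a :class:`NoCrossingError` reports both roots.
    """
    if not (m1 < m2):
        raise ConfigurationError("require m1 < m2")
    if s1 <= 0 or s2 <= 0 or w1 <= 0 or w2 <= 0:
        raise ConfigurationError("weights and sds must be positive")
    if abs(s1 - s2) < 1e-12:
        # linear: (x-m1)^2 - (x-m2)^2 = 2 s^2 ln(w1/w2)
        return float((m1 + m2) / 2.0 + s1**2 * np.log(w1 / w2) / (m2 - m1))
    # quadratic a x^2 + b x + c = 0 from the log-density equality
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (
        m2**2 / (2 * s2**2)
        - m1**2 / (2 * s1**2)
        + np.log((w1 * s2) / (w2 * s1))
    )
    disc = b**2 - 4 * a * c
    if disc < 0:
        raise NoCrossingError(
            "weighted densities do not cross (negative discriminant)"
        )
    roots = sorted(((-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)))
    inside = [r for r in roots if m1 < r < m2]
    if not inside:
        raise NoCrossingError(
            f"no crossing in ({m1}, {m2}); roots at {roots[0]:.6g} and "
            f"{roots[1]:.6g} (extreme weight imbalance)",
            roots=roots,
        )
    return float(inside[0])


def analytic_cutoffs(fit, family: str | None = None) -> CutoffSet:
    """Weighted-density crossings for every adjacent component pair of a fit.

    ``fit`` is any object exposing ``weights``, ``means``, ``sds`` arrays
    (a MixtureFit or a MixtureSpec).
    """
    w, m, s = np.asarray(fit.weights), np.asarray(fit.means), np.asarray(fit.sds)
    bounds = [
        analytic_crossing(w[i], m[i], s[i], w[i + 1], m[i + 1], s[i + 1])
        for i in range(len(m) - 1)
    ]
    fam = family or getattr(fit, "family", "LM")
    return CutoffSet(family=fam, boundaries=tuple(bounds), method="analytic")


def _min_misclass_thresholds(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Per-row minimum-misclassification threshold between two samples.

    ``v1`` (rows x n1) is the lower component, ``v2`` (rows x n2) the upper.
    The threshold scans midpoints of the sorted pooled sample; misclassified
    points are component-1 values above the threshold plus component-2
    values at or below it; ties go to the smallest threshold.
    """
    n1 = v1.shape[1]
    pooled = np.concatenate([v1, v2], axis=1)
    is2 = np.zeros(pooled.shape[1], dtype=np.int64)
    is2[n1:] = 1
    order = np.argsort(pooled, axis=1, kind="stable")
    v_sorted = np.take_along_axis(pooled, order, axis=1)
    z = is2[order]
    cum2 = np.cumsum(z, axis=1)
    # threshold after position j (1..n-1): err = (n1 - #c1 in first j) + #c2 in first j
    j = np.arange(1, pooled.shape[1])
    err = (n1 - (j[None, :] - cum2[:, :-1])) + cum2[:, :-1]
    jstar = np.argmin(err, axis=1) + 1  # argmin takes the first (smallest) tie
    rows = np.arange(pooled.shape[0])
    return 0.5 * (v_sorted[rows, jstar - 1] + v_sorted[rows, jstar])


def _truncated_draws(rng, mean, sd, size):
    a = -mean / sd  # truncate at zero in standard units
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def mc_cutoffs(
    fit,
    R: int = DEFAULT_ITERATIONS,
    multiplier: int = DEFAULT_MULTIPLIER,
    seed: int | None = None,
    n: int | None = None,
    family: str | None = None,
) -> CutoffSet:
    """Monte Carlo cutoff estimation between every adjacent component pair.

    ``fit`` exposes ``weights``, ``means``, ``sds`` (MixtureFit or
    MixtureSpec); ``n`` defaults to ``fit.n`` and sets the observed cluster
    sizes ``round(weight * n)``, each simulated at ``multiplier`` times that
    size with draws truncated at zero.
    """
    w, m, s = np.asarray(fit.weights), np.asarray(fit.means), np.asarray(fit.sds)
    k = len(m)
    if k < 2:
        raise ModelingError("need at least 2 components for cutoffs")
    if R < 1 or multiplier < 1:
        raise ConfigurationError("R and multiplier must be >= 1")
    n = n if n is not None else getattr(fit, "n", None)
    if n is None:
        raise ConfigurationError("sample size n is required (fit has none)")
    sizes = np.maximum(np.round(w * n).astype(int), 0) * multiplier
    if (sizes < 2).any():
        raise ModelingError(
            f"component sizes after rounding are too small: {sizes.tolist()}"
        )
    rng = np.random.default_rng(seed)
    means_out, sds_out = [], []
    for i in range(k - 1):
        n1, n2 = int(sizes[i]), int(sizes[i + 1])
        chunk = max(1, int(2_000_000 // (n1 + n2)))
        vals = np.empty(R)
        done = 0
        while done < R:
            c = min(chunk, R - done)
            v1 = _truncated_draws(rng, m[i], s[i], (c, n1))
            v2 = _truncated_draws(rng, m[i + 1], s[i + 1], (c, n2))
            vals[done : done + c] = _min_misclass_thresholds(v1, v2)
            done += c
        means_out.append(float(vals.mean()))
        sds_out.append(float(vals.std(ddof=1)) if R > 1 else 0.0)
    fam = family or getattr(fit, "family", "LM")
    return CutoffSet(
        family=fam,
        boundaries=tuple(means_out),
        method="monte_carlo",
        iterations=R,
        multiplier=multiplier,
        boundary_sd=tuple(sds_out),
    )


def apply_cutoffs(boutons, cutoffs_lm: CutoffSet, cutoffs_dnm: CutoffSet):
    """Classify a bouton table by family and volume bin (pipeline wiring).

    Delegates to :func:`boutonsort.classify.classify_boutons`.
    """
    from .classify import classify_boutons

    return classify_boutons(boutons, cutoffs_lm, cutoffs_dnm)
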