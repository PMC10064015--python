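"""Mixture specifications for the bouton-volume families.

Synaptic boutons in the thalamic relay fall into two families by mitochondria
appearance: LM (light mitochondria, retinal origin) and DNM (dark or no
mitochondria, all non-retinal origins).  Within each family the bouton-volume
distribution is modeled as a finite mixture of positive-support normals; the
frozen default specifications below encode the published subpopulation
structure: four LM components (LM1-4, all retinal) and five DNM components
(DM1 corticothalamic, DM2 brainstem, DM3/DM4 inhibitory, DM5 RLD).

The default component weights follow the printed subpopulation shares,
renormalized within each family.  Means and SDs were derived once by numeric
search so that the weighted-density crossing of every adjacent component pair
equals the published volume cutoff (LM: 1.31, 3.34, 7.22 um^3; DNM: 0.22,
0.39, 0.75, 1.95 um^3), and are frozen as constants so that downstream tests
and simulations are stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

FAMILIES = ("LM", "DNM")
MITO_CLASSES = ("LM", "DM", "NM")

#: Published between-subpopulation volume cutoffs (um^3), used to calibrate
#: the default mixture parameters and as reference boundaries in tests.
PRINTED_CUTOFFS = {
    "LM": (1.31, 3.34, 7.22),
    "DNM": (0.22, 0.39, 0.75, 1.95),
}

#: Documented sample sizes of the two unbiased-sampling families
#: (1,048 boutons total, ~18% with light mitochondria).
DEFAULT_LM_N = 190
DEFAULT_DNM_N = 858

#: LM family share of all boutons (configurable where it matters).
DEFAULT_LM_FRACTION = 0.18


@dataclass(frozen=True)
class MixtureComponent:
    """One subpopulation of a bouton-volume mixture."""

    label: str
    origin: str
    mito_class: str
    weight: float
    mean: float  # um^3
    sd: float  # um^3


@dataclass(frozen=True)
class MixtureSpec:
    """An ordered finite mixture of positive-support normals for one family.

    Invariants: weights positive and sum to 1 (+-1e-9); means strictly
    increasing; SDs positive.  Violations raise :class:`ConfigurationError`
    naming the offending invariant.
    """

    components: tuple[MixtureComponent, ...]
    family: str

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        if not self.components:
            raise ConfigurationError("mixture must have at least one component")
        w = np.array([c.weight for c in self.components], dtype=float)
        if (w <= 0).any():
            raise ConfigurationError("component weights must be strictly positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"component weights must sum to 1 (got {w.sum():.12f})"
            )
        m = np.array([c.mean for c in self.components], dtype=float)
        if not np.all(np.diff(m) > 0):
            raise ConfigurationError("component means must be strictly increasing")
        s = np.array([c.sd for c in self.components], dtype=float)
        if (s <= 0).any():
            raise ConfigurationError("component sds must be strictly positive")
        for c in self.components:
            if c.mito_class not in MITO_CLASSES:
                raise ConfigurationError(
                    f"unknown mitochondria class {c.mito_class!r}"
                )

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c.sd for c in self.components])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.components)


# Frozen calibration (see module docstring).  Weights: LM shares 6.8/8.6/1.5 %
# of all boutons renormalized within the family, with the unprinted LM3/LM4
# split fixed at 0.060/0.029; DNM shares 37/21/12/9/2 % renormalized to the
# family (37/81 etc.).
_LM_TABLE = (
    ("LM1", "retinal", "LM", 0.402, 0.7500, 0.2800),
    ("LM2", "retinal", "LM", 0.509, 2.1479, 0.4450),
    ("LM3", "retinal", "LM", 0.060, 4.4073, 0.8300),
    ("LM4", "retinal", "LM", 0.029, 10.7143, 1.1400),
)
_DNM_TABLE = (
    ("DM1", "corticothalamic", "NM", 37 / 81, 0.1300, 0.0450),
    ("DM2", "brainstem", "DM", 21 / 81, 0.2905, 0.0400),
    ("DM3", "inhibitory", "DM", 12 / 81, 0.5436, 0.0800),
    ("DM4", "inhibitory", "DM", 9 / 81, 1.2374, 0.2500),
    ("DM5", "RLD", "DM", 2 / 81, 3.0826, 0.6250),
)


def default_lm_spec() -> MixtureSpec:
    """Frozen default 4-component LM (retinal) family specification."""
    return MixtureSpec(
        components=tuple(MixtureComponent(*row) for row in _LM_TABLE),
        family="LM",
    )


def default_dnm_spec() -> MixtureSpec:
    """Frozen default 5-component DNM (non-retinal) family specification."""
    return MixtureSpec(
        components=tuple(MixtureComponent(*row) for row in _DNM_TABLE),
        family="DNM",
    )


def calibrate_default_mixtures() -> tuple[MixtureSpec, MixtureSpec]:
    """Return the frozen default (LM, DNM) mixture specifications.

    The adjacent weighted-density crossings of these constants reproduce the
    published volume cutoffs to within +-0.05 um^3 (asserted in the test
    suite via :func:`boutonsort.cutoffs.analytic_crossing`).
    """
    return default_lm_spec(), default_dnm_spec()
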