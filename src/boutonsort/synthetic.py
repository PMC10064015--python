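"""Synthetic-data generators for every pipeline stage.

Three generators cover the three input kinds the analysis needs:

* :func:`generate_bouton_population` — bouton volumes drawn from a family
  :class:`~boutonsort.specs.MixtureSpec` with ground-truth component labels.
  Draws are resampled until positive (truncation at zero), because a bouton
  volume cannot be negative; for the default specifications the untruncated
  negative mass is below 1% per component, so the induced mean bias is small.
* :func:`generate_segment_dataset` — dendrite segments of three cell classes
  (X-like relay, Y-like relay, interneuron) with morphological flags and
  linked terminal boutons, with a configurable retinal/cortical segregation
  strength for X-like segments.
* :func:`generate_stack` — a sparse 3-D label volume of synapse blobs at
  SBEM-like 5 x 5 x 75 nm voxel anisotropy, with a synapse table linking
  blob ids to bouton records.

All randomness flows from one explicit seed per call; no global RNG state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError
from .specs import MixtureSpec, default_dnm_spec, default_lm_spec

CELL_CLASSES = ("X_like", "Y_like", "interneuron")
ITEM_ALPHABET = ("LM", "DM1", "DM2", "DM3", "DM4", "DM5")

BOUTON_COLUMNS = [
    "bouton_id",
    "volume_um3",
    "mito_class",
    "is_f2",
    "true_component",
    "segment_id",
]


def _truncated_normal(rng, mean, sd, size):
    """Positive draws from N(mean, sd) by resampling negatives."""
    x = rng.normal(mean, sd, size)
    bad = x <= 0
    while bad.any():
        x[bad] = rng.normal(
            mean[bad] if np.ndim(mean) else mean,
            sd[bad] if np.ndim(sd) else sd,
            int(bad.sum()),
        )
        bad = x <= 0
    return x


def generate_bouton_population(
    spec: MixtureSpec,
    n: int,
    seed: int | None = None,
    f2_probability: float = 0.05,
    id_offset: int = 0,
) -> pd.DataFrame:
    """Draw ``n`` boutons from a family mixture with ground-truth labels.

    Each bouton's volume is drawn from its component's normal, resampled
    until positive.  ``is_f2`` flags a small Bernoulli fraction of boutons
    from inhibitory-origin components (F2 appendages are interneuron
    processes); the flag plays no role in volume classification.

    Returns a DataFrame with columns ``bouton_id, volume_um3, mito_class,
    is_f2, true_component, segment_id`` (segment_id is NA here; the segment
    generator fills it).
    """
    if not isinstance(spec, MixtureSpec):
        raise ConfigurationError("spec must be a MixtureSpec")
    if n < 1:
        raise ConfigurationError(f"n must be >= 1 (got {n})")
    rng = np.random.default_rng(seed)
    comp_idx = rng.choice(spec.k, size=n, p=spec.weights)
    means = spec.means[comp_idx]
    sds = spec.sds[comp_idx]
    volumes = _truncated_normal(rng, means, sds, n)
    labels = np.array(spec.labels)[comp_idx]
    mito = np.array([c.mito_class for c in spec.components])[comp_idx]
    origins = np.array([c.origin for c in spec.components])[comp_idx]
    is_f2 = (origins == "inhibitory") & (rng.random(n) < f2_probability)
    return pd.DataFrame(
        {
            "bouton_id": np.arange(id_offset, id_offset + n),
            "volume_um3": volumes,
            "mito_class": mito,
            "is_f2": is_f2,
            "true_component": labels,
            "segment_id": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )


# ---------------------------------------------------------------------------
# Segment / terminal co-occurrence generator
# ---------------------------------------------------------------------------

#: Per-class default item-composition probabilities over the terminal
#: alphabet, echoing the published per-cell-type composition structure
#: (X-like: ~27% retinal; Y-like: ~7% retinal, inhibitory-dominated;
#: interneuron: retinal-dominated with sparse cortical/brainstem input).
DEFAULT_COMPOSITIONS = {
    "X_like": {"LM": 0.27, "DM1": 0.18, "DM2": 0.15, "DM3": 0.20, "DM4": 0.16, "DM5": 0.04},
    "Y_like": {"LM": 0.07, "DM1": 0.10, "DM2": 0.12, "DM3": 0.38, "DM4": 0.30, "DM5": 0.03},
    "interneuron": {"LM": 0.68, "DM1": 0.04, "DM2": 0.05, "DM3": 0.12, "DM4": 0.09, "DM5": 0.02},
}

#: Branch-order caliber parameters (um): mean and SD per order, matching the
#: published branch-order caliber summary statistics.
_ORDER_CALIBER = {
    "primary": (1.09, 0.25),
    "secondary": (0.75, 0.18),
    "tertiary": (0.66, 0.04),
    "quaternary": (0.60, 0.05),
}

DEFAULT_BRANCH_ORDER_PROBS = {
    "primary": 0.25,
    "secondary": 0.45,
    "tertiary": 0.25,
    "quaternary": 0.05,
}

SEGMENT_COLUMNS = [
    "segment_id",
    "dendrite_id",
    "cell_class_true",
    "branch_order",
    "length_um",
    "volume_um3",
    "has_presynaptic_zone",
    "has_triad_or_f2_input",
    "has_dendrodendritic_pa",
    "n_filopodia",
    "n_spines",
    "n_grapes",
    "synapse_count",
]


@dataclass(frozen=True)
class SegmentGenConfig:
    """Configuration of the segment/terminal co-occurrence generator.

    ``epsilon`` is the retinal/cortical segregation strength applied to
    X-like segments: with probability epsilon a segment hosts either retinal
    (LM) or corticothalamic (DM1) input but never both (which of the two is
    kept is chosen with probability proportional to their composition
    shares); with probability 1 - epsilon terminals are drawn independently
    from the class composition.  Y-like and interneuron segments always draw
    independently.  Default segment counts mirror the published dataset
    (43 X-like, 37 Y-like, 7 interneuron); default epsilon 0.9 reflects the
    near-complete segregation observed on X-like arbors.
    """

    n_segments: dict = field(
        default_factory=lambda: {"X_like": 43, "Y_like": 37, "interneuron": 7}
    )
    compositions: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_COMPOSITIONS.items()
    })
    epsilon: float = 0.9
    terminals_per_segment_mean: float = 8.0
    branch_order_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_ORDER_PROBS)
    )
    force_co_occurrence: bool = False
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ConfigurationError("epsilon must lie in [0, 1]")
        if self.terminals_per_segment_mean <= 0:
            raise ConfigurationError("terminals_per_segment_mean must be positive")
        for cls, comp in self.compositions.items():
            if cls not in CELL_CLASSES:
                raise ConfigurationError(f"unknown cell class {cls!r}")
            p = np.array(list(comp.values()), dtype=float)
            if (p < 0).any() or (p > 1).any():
                raise ConfigurationError(f"{cls}: probabilities must lie in [0, 1]")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"{cls}: composition must sum to 1")
            for item in comp:
                if item not in ITEM_ALPHABET:
                    raise ConfigurationError(f"{cls}: unknown item {item!r}")
        for cls in self.n_segments:
            if cls not in CELL_CLASSES:
                raise ConfigurationError(f"unknown cell class {cls!r}")
            if self.n_segments[cls] < 0:
                raise ConfigurationError("segment counts must be >= 0")
        bp = np.array(list(self.branch_order_probs.values()), dtype=float)
        if (bp < 0).any() or abs(bp.sum() - 1.0) > 1e-9:
            raise ConfigurationError("branch-order probabilities must sum to 1")
        if self.force_co_occurrence and self.epsilon == 1.0:
            raise ConfigurationError(
                "epsilon=1 excludes LM/DM1 co-occurrence on X-like segments; "
                "it cannot be combined with force_co_occurrence"
            )


def _component_for_item(item, lm_spec, dnm_spec, rng):
    """Pick a mixture component for one terminal item label."""
    if item == "LM":
        idx = rng.choice(lm_spec.k, p=lm_spec.weights)
        return lm_spec.components[idx]
    return dnm_spec.components[int(item[2:]) - 1]


def generate_segment_dataset(
    cfg: SegmentGenConfig,
    lm_spec: MixtureSpec | None = None,
    dnm_spec: MixtureSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate dendrite segments and their linked terminal boutons.

    Returns ``(segments, boutons)`` DataFrames.  Segment morphological flags
    are consistent with the cell classes: interneuron segments carry a
    presynaptic zone; X-like segments carry triad/F2 input and never a
    dendrodendritic puncta-adherentia flag; Y-like the converse.
    """
    lm_spec = lm_spec or default_lm_spec()
    dnm_spec = dnm_spec or default_dnm_spec()
    rng = np.random.default_rng(cfg.seed)
    orders = list(cfg.branch_order_probs)
    order_p = np.array(list(cfg.branch_order_probs.values()), dtype=float)

    seg_rows, bouton_rows = [], []
    seg_id = 0
    bouton_id = 0
    for cls in CELL_CLASSES:
        comp = cfg.compositions.get(cls)
        n_cls = cfg.n_segments.get(cls, 0)
        if n_cls and comp is None:
            raise ConfigurationError(f"no composition given for class {cls!r}")
        for _ in range(n_cls):
            order = orders[rng.choice(len(orders), p=order_p)]
            if cls == "interneuron":
                cal_mean, cal_sd = 0.90, 0.30
            else:
                cal_mean, cal_sd = _ORDER_CALIBER[order]
            caliber = max(0.1, rng.normal(cal_mean, cal_sd))
            length = float(np.exp(rng.normal(np.log(12.0), 0.4)))
            volume = np.pi * (caliber / 2.0) ** 2 * length

            n_term = max(1, int(rng.poisson(cfg.terminals_per_segment_mean)))
            probs = np.array([comp.get(i, 0.0) for i in ITEM_ALPHABET])
            if cls == "X_like" and rng.random() < cfg.epsilon:
                # segregated segment: keep LM or DM1, drop the other
                p_lm, p_dm1 = probs[0], probs[1]
                if p_lm + p_dm1 > 0:
                    drop = 1 if rng.random() < p_lm / (p_lm + p_dm1) else 0
                    probs = probs.copy()
                    probs[drop] = 0.0
                    probs = probs / probs.sum()
            items = rng.choice(len(ITEM_ALPHABET), size=n_term, p=probs)
            if cfg.force_co_occurrence and cls == "X_like":
                items[0], items[1 % n_term] = 0, 1  # plant LM and DM1

            for it in items:
                c = _component_for_item(ITEM_ALPHABET[it], lm_spec, dnm_spec, rng)
                vol = float(_truncated_normal(rng, c.mean, c.sd, 1)[0])
                bouton_rows.append(
                    (bouton_id, vol, c.mito_class,
                     bool(c.origin == "inhibitory" and rng.random() < 0.05),
                     c.label, seg_id)
                )
                bouton_id += 1

            seg_rows.append(
                (
                    seg_id,
                    seg_id // 4,  # group segments into dendrites of ~4 segments
                    cls,
                    order if cls != "interneuron" else "unknown",
                    length,
                    volume,
                    cls == "interneuron",
                    cls == "X_like",
                    cls == "Y_like",
                    int(rng.poisson(2.0)),
                    int(rng.poisson(1.0)) if cls == "X_like" else 0,
                    int(rng.poisson(0.5)) if cls == "X_like" else 0,
                    n_term,
                )
            )
            seg_id += 1

    segments = pd.DataFrame(seg_rows, columns=SEGMENT_COLUMNS)
    boutons = pd.DataFrame(bouton_rows, columns=BOUTON_COLUMNS)
    boutons["segment_id"] = boutons["segment_id"].astype("Int64")
    return segments, boutons


# ---------------------------------------------------------------------------
# Label-stack generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StackSpec:
    """Geometry and density of a synthetic annotated label stack.

    ``shape`` is (nx, ny, nz) in voxels; ``voxel_size_nm`` is the (x, y, z)
    voxel pitch, defaulting to the SBEM acquisition geometry of 5 x 5 nm
    pixels on sections 75 nm apart.
    """

    shape: tuple[int, int, int]
    voxel_size_nm: tuple[float, float, float] = (5.0, 5.0, 75.0)
    synapse_density_per_um3: float = 0.0
    blob_radius_voxels: int = 2
    seed: int | None = None

    def __post_init__(self):
        if any(d < 2 * self.blob_radius_voxels + 1 for d in self.shape[:2]):
            raise ConfigurationError(
                "stack x/y dimensions must fit at least one blob"
            )
        if any(d < 1 for d in self.shape):
            raise ConfigurationError("stack dimensions must be positive")
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ConfigurationError("voxel sizes must be positive")
        if self.synapse_density_per_um3 < 0:
            raise ConfigurationError("synapse density must be >= 0")
        if self.blob_radius_voxels < 1:
            raise ConfigurationError("blob radius must be >= 1 voxel")

    @property
    def volume_um3(self) -> float:
        nx, ny, nz = self.shape
        vx, vy, vz = self.voxel_size_nm
        return nx * ny * nz * vx * vy * vz * 1e-9


SYNAPSE_COLUMNS = ["synapse_id", "bouton_id", "cx", "cy", "cz"]


def _blob_offsets(radius: int) -> np.ndarray:
    """Voxel offsets of a discrete sphere (connected, 6-neighborhood)."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def generate_stack(
    spec: StackSpec, population: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Place synapse blobs of the population's boutons into a label volume.

    The synapse count is Poisson with mean ``density x stack volume``; each
    synapse is a connected spherical blob of voxels carrying a unique
    positive 16-bit id on a zero background, linked to a bouton drawn with
    replacement from ``population``.  Returns ``(labels, synapse_table)``
    with ``labels`` indexed as ``[z, y, x]`` and centroids in 0-based voxel
    coordinates.  Placements never overlap; if the requested density cannot
    be placed without overlap an error suggests lowering it.
    """
    if spec.synapse_density_per_um3 > 0 and population.empty:
        raise ConfigurationError("population must be nonempty")
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    labels = np.zeros((nz, ny, nx), dtype=np.uint16)
    n_syn = int(rng.poisson(spec.synapse_density_per_um3 * spec.volume_um3))
    if n_syn == 0:
        return labels, pd.DataFrame(columns=SYNAPSE_COLUMNS)
    if n_syn > 65535:
        raise ConfigurationError(
            f"{n_syn} synapses exceed 16-bit label capacity; lower the density"
        )
    offs = _blob_offsets(spec.blob_radius_voxels)
    r = spec.blob_radius_voxels
    rows = []
    placed = 0
    attempts = 0
    max_attempts = 200 * n_syn
    while placed < n_syn:
        if attempts >= max_attempts:
            raise ConfigurationError(
                f"could not place {n_syn} non-overlapping synapse blobs "
                f"after {max_attempts} attempts; lower the synapse density"
            )
        attempts += 1
        cx = int(rng.integers(r, nx - r))
        cy = int(rng.integers(r, ny - r))
        cz = int(rng.integers(0, nz))
        vox = offs + np.array([cx, cy, cz])
        vox = vox[(vox[:, 2] >= 0) & (vox[:, 2] < nz)]
        zz, yy, xx = vox[:, 2], vox[:, 1], vox[:, 0]
        if labels[zz, yy, xx].any():
            continue
        placed += 1
        labels[zz, yy, xx] = placed
        bouton = population.iloc[int(rng.integers(0, len(population)))]
        rows.append((placed, int(bouton["bouton_id"]), cx, cy, cz))
    return labels, pd.DataFrame(rows, columns=SYNAPSE_COLUMNS)


def write_stack(path, labels: np.ndarray, spec: StackSpec) -> None:
    """Write a label stack as multi-page 16-bit TIFF plus a JSON sidecar."""
    tifffile.imwrite(path, labels.astype(np.uint16))
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "voxel_size_nm": list(spec.voxel_size_nm),
                "shape_xyz": list(spec.shape),
                "axes": "ZYX",
            },
            fh,
            indent=2,
        )


def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a label stack written by :func:`write_stack`."""
    labels = tifffile.imread(path)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    return labels, meta
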