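"""Dendrite-segment morphometry.

Dendrite segments are treated as roughly cylindrical, so the caliber
(diameter) follows from reconstructed volume and length as

    d = 2 * sqrt(volume / (length * pi))

Cell-type classification from morphological flags follows the observed
exclusivity of triads and dendrodendritic puncta adherentia (PA): a segment
with any presynaptic zone is an interneuron dendrite (this takes precedence,
since relay subtyping only applies to dendrites lacking presynaptic zones);
among relay dendrites, triad/F2 input without PA marks the X-like type, PA
without triads the Y-like type, and neither leaves the segment unclassified.
A relay segment flagged with both is inconsistent with the observed
exclusivity and raises an error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError


def caliber(volume: float, length: float) -> float:
    """Cylinder-equivalent diameter (um) from volume (um^3) and length (um)."""
    volume = np.asarray(volume, dtype=float)
    length = np.asarray(length, dtype=float)
    if (volume <= 0).any() or (length <= 0).any():
        raise ConfigurationError("volume and length must be positive")
    d = 2.0 * np.sqrt(volume / (length * np.pi))
    return float(d) if d.ndim == 0 else d


def classify_cell_type(
    has_presynaptic_zone: bool,
    has_triad_or_f2_input: bool,
    has_dendrodendritic_pa: bool,
) -> str:
    """Morphological flags -> cell class.

    Raises :class:`DataIntegrityError` for a relay dendrite flagged with
    both triad and PA, which never co-occur on the same segment or arbor.
    """
    if has_presynaptic_zone:
        return "interneuron"
    if has_triad_or_f2_input and has_dendrodendritic_pa:
        raise DataIntegrityError(
            "triad/F2 input and dendrodendritic PA flagged on the same relay "
            "segment; these features are mutually exclusive"
        )
    if has_triad_or_f2_input:
        return "X_like"
    if has_dendrodendritic_pa:
        return "Y_like"
    return "unclassified"


def synapse_density(synapse_count: int, length: float) -> float:
    """Synapses per um of dendrite segment length."""
    if length <= 0:
        raise ConfigurationError("length must be positive")
    if synapse_count < 0:
        raise ConfigurationError("synapse count must be >= 0")
    return synapse_count / length


def annotate_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns: caliber_um, cell_class, synapses_per_um.

    Expects the segment-table columns produced by the synthetic generator or
    an equivalently structured CSV (length_um, volume_um3 and the three
    morphological flags; synapse_count optional).
    """
    required = [
        "length_um",
        "volume_um3",
        "has_presynaptic_zone",
        "has_triad_or_f2_input",
        "has_dendrodendritic_pa",
    ]
    for col in required:
        if col not in segments.columns:
            raise DataIntegrityError(f"segment table lacks column {col!r}")
    out = segments.copy()
    out["caliber_um"] = caliber(
        out["volume_um3"].to_numpy(), out["length_um"].to_numpy()
    )
    out["cell_class"] = [
        classify_cell_type(p, t, a)
        for p, t, a in zip(
            out["has_presynaptic_zone"],
            out["has_triad_or_f2_input"],
            out["has_dendrodendritic_pa"],
        )
    ]
    if "synapse_count" in out.columns:
        out["synapses_per_um"] = out["synapse_count"] / out["length_um"]
    return out
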