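"""Family and subpopulation classification of boutons, and composition tables.

Boutons are first split by mitochondria class (light mitochondria -> LM
family, dark or no mitochondria -> DNM family), then assigned a
subpopulation label (LM1-4 or DM1-5) by half-open volume bins between the
family's cutoff boundaries, and finally mapped to a putative origin
(retinal, corticothalamic, brainstem, inhibitory, RLD).  The origin mapping
is a configurable table defaulting to the published attributions, since
these identifications are putative.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cutoffs import CutoffSet
from .errors import ConfigurationError, DataIntegrityError

FAMILY_BY_MITO = {"LM": "LM", "DM": "DNM", "NM": "DNM"}

#: Default putative-origin attribution of each subpopulation.
DEFAULT_ORIGIN_MAP = {
    "LM1": "retinal",
    "LM2": "retinal",
    "LM3": "retinal",
    "LM4": "retinal",
    "DM1": "corticothalamic",
    "DM2": "brainstem",
    "DM3": "inhibitory",
    "DM4": "inhibitory",
    "DM5": "RLD",
}


def assign_family(mito_class: str) -> str:
    """LM -> LM; DM and NM -> DNM (NM boutons ride on dark-mitochondria axons)."""
    try:
        return FAMILY_BY_MITO[mito_class]
    except KeyError:
        raise ConfigurationError(
            f"unknown mitochondria class {mito_class!r}; expected LM/DM/NM"
        ) from None


def assign_subpopulation(volume: float, family: str, cutoffs) -> str:
    """Volume bin index within the family, half-open bins [low, high).

    ``cutoffs`` may be a CutoffSet or a sequence of strictly increasing
    boundaries.  volume < b1 -> index 1; b_i <= volume < b_{i+1} ->
    index i+1; volume >= b_{k-1} -> index k.
    """
    bounds = np.asarray(
        cutoffs.boundaries if isinstance(cutoffs, CutoffSet) else cutoffs,
        dtype=float,
    )
    if bounds.size and not np.all(np.diff(bounds) > 0):
        raise ConfigurationError("cutoffs must be strictly increasing")
    if np.ndim(volume) == 0 and volume <= 0:
        raise ConfigurationError("volume must be positive")
    idx = np.searchsorted(bounds, volume, side="right")
    prefix = "LM" if family == "LM" else "DM"
    if np.ndim(volume) == 0:
        return f"{prefix}{int(idx) + 1}"
    return np.array([f"{prefix}{i + 1}" for i in idx])


def map_origin(subpop: str, origin_map: dict | None = None) -> str:
    """Subpopulation label -> putative origin."""
    table = origin_map or DEFAULT_ORIGIN_MAP
    try:
        return table[subpop]
    except KeyError:
        raise ConfigurationError(f"unknown subpopulation {subpop!r}") from None


def classify_boutons(
    boutons: pd.DataFrame,
    cutoffs_lm: CutoffSet,
    cutoffs_dnm: CutoffSet,
    origin_map: dict | None = None,
) -> pd.DataFrame:
    """Append family, subpop and putative_origin columns to a bouton table.

    Requires ``volume_um3`` and ``mito_class`` columns; every bouton gets
    exactly one subpopulation (counts are conserved).
    """
    for col in ("volume_um3", "mito_class"):
        if col not in boutons.columns:
            raise DataIntegrityError(f"bouton table lacks column {col!r}")
    if (boutons["volume_um3"] <= 0).any():
        raise DataIntegrityError("bouton volumes must be positive")
    out = boutons.copy()
    out["family"] = out["mito_class"].map(assign_family)
    subpop = pd.Series(index=out.index, dtype=object)
    for fam, cuts in (("LM", cutoffs_lm), ("DNM", cutoffs_dnm)):
        mask = out["family"] == fam
        if mask.any():
            subpop[mask] = assign_subpopulation(
                out.loc[mask, "volume_um3"].to_numpy(), fam, cuts
            )
    out["subpop"] = subpop
    out["putative_origin"] = out["subpop"].map(
        lambda s: map_origin(s, origin_map)
    )
    return out


def composition_summary(
    boutons: pd.DataFrame,
    group_by: str | None = None,
    level: str = "subpop",
) -> pd.DataFrame:
    """Percent contribution of each subpopulation (or origin) per group.

    ``group_by`` may be None (one overall group), a column name such as
    ``cell_class`` or ``segment_id``.  Returns a tidy frame with columns
    ``group, label, count, percent``; percentages sum to 100 per group.
    Empty groups are omitted with a warning.
    """
    if level not in ("subpop", "putative_origin"):
        raise ConfigurationError("level must be 'subpop' or 'putative_origin'")
    if level not in boutons.columns:
        raise DataIntegrityError(f"bouton table lacks column {level!r}; classify first")
    df = boutons.copy()
    if group_by is None:
        df["_group"] = "all"
        group_by = "_group"
    elif group_by not in df.columns:
        raise DataIntegrityError(f"bouton table lacks column {group_by!r}")
    rows = []
    for grp, sub in df.groupby(group_by, dropna=False, observed=True):
        sub = sub.dropna(subset=[level])
        if sub.empty:
            warnings.warn(f"group {grp!r} has no classified boutons; omitted")
            continue
        counts = sub[level].value_counts().sort_index()
        total = counts.sum()
        for label, count in counts.items():
            rows.append((grp, label, int(count), 100.0 * count / total))
    return pd.DataFrame(rows, columns=["group", "label", "count", "percent"])
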