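"""The LDL window: a four-group partition of the (particle number, TG) plane.

The rule flags likely high sdLDL-C from two conventional measurements:
a particle-number marker (apoB, or non-HDL-C as its surrogate) and
fasting triglycerides as an inverse proxy of LDL size.  With the default
cutoffs the groups are

* ``normal``      marker < cutoff and TG < 150 mg/dL
* ``hyper_tg``    marker < cutoff and TG ≥ 150 mg/dL
* ``hyper_b``     marker ≥ cutoff and TG < 150 mg/dL
* ``hyper_tg_b``  marker ≥ cutoff and TG ≥ 150 mg/dL

``hyper_b`` reads "hyper-apoB" in apoB mode (cutoff 110 mg/dL) and
"hyper-non-HDL" in non-HDL mode (cutoff 170 mg/dL).  Boundaries are
inclusive on the hyper side (≥) on both axes.  The alternative window is
the same classifier consulting non-HDL-C — one rule, two markers.

The rule is defined on fasting TG; fasting state is not modelled here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .panels import PanelValidationError


class WindowGroup(str, enum.Enum):
    NORMAL = "normal"
    HYPER_TG = "hyper_tg"
    HYPER_B = "hyper_b"          # hyper-apoB or hyper-non-HDL per mode
    HYPER_TG_B = "hyper_tg_b"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


GROUP_ORDER = [WindowGroup.NORMAL, WindowGroup.HYPER_TG,
               WindowGroup.HYPER_B, WindowGroup.HYPER_TG_B]


@dataclass(frozen=True)
class WindowConfig:
    """Cutoff set and marker mode for the LDL-window classifier."""

    apob_cutoff: float = 110.0
    tg_cutoff: float = 150.0
    non_hdl_cutoff: float = 170.0
    pattern_threshold: float = 25.5
    mode: str = "apob"  # "apob" | "non_hdl"

    def __post_init__(self):
        for name in ("apob_cutoff", "tg_cutoff", "non_hdl_cutoff", "pattern_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.mode not in ("apob", "non_hdl"):
            raise ValueError(f"mode must be 'apob' or 'non_hdl', got {self.mode!r}")

    @property
    def marker_column(self) -> str:
        return "apob" if self.mode == "apob" else "non_hdl_c"

    @property
    def marker_cutoff(self) -> float:
        return self.apob_cutoff if self.mode == "apob" else self.non_hdl_cutoff

    def with_mode(self, mode: str) -> "WindowConfig":
        return replace(self, mode=mode)


def classify(particle_marker: float, tg: float,
             config: WindowConfig = WindowConfig()) -> WindowGroup:
    """Assign one subject to its LDL-window group.

    ``particle_marker`` is apoB or non-HDL-C per ``config.mode``; both
    axes are inclusive (≥) on the hyper side.
    """
    if particle_marker <= 0:
        raise PanelValidationError(config.marker_column, "must be strictly positive")
    if tg <= 0:
        raise PanelValidationError("tg", "must be strictly positive")
    high_b = particle_marker >= config.marker_cutoff
    high_tg = tg >= config.tg_cutoff
    if high_b and high_tg:
        return WindowGroup.HYPER_TG_B
    if high_b:
        return WindowGroup.HYPER_B
    if high_tg:
        return WindowGroup.HYPER_TG
    return WindowGroup.NORMAL


def classify_cohort(panels: pd.DataFrame,
                    config: WindowConfig = WindowConfig()) -> pd.DataFrame:
    """Classify every subject of a cohort; returns the frame with a
    ``window_group`` column added.

    Requires the mode's marker column (``apob`` or ``non_hdl_c``) for
    every subject; missing values raise with the offending subject ids.
    """
    if len(panels) == 0:
        raise ValueError("cohort is empty")
    col = config.marker_column
    if col not in panels.columns:
        raise PanelValidationError(col, "required marker column missing")
    marker = panels[col].to_numpy(dtype=float)
    tg = panels["tg"].to_numpy(dtype=float)
    missing = np.isnan(marker) | np.isnan(tg)
    if missing.any():
        raise PanelValidationError(
            col, "marker missing for some subjects",
            subject_ids=panels.loc[missing, "subject_id"].tolist())
    if (marker <= 0).any():
        raise PanelValidationError(col, "must be strictly positive")
    if (tg <= 0).any():
        raise PanelValidationError("tg", "must be strictly positive")
    high_b = marker >= config.marker_cutoff
    high_tg = tg >= config.tg_cutoff
    group = np.where(
        high_b & high_tg, WindowGroup.HYPER_TG_B.value,
        np.where(high_b, WindowGroup.HYPER_B.value,
                 np.where(high_tg, WindowGroup.HYPER_TG.value,
                          WindowGroup.NORMAL.value)))
    out = panels.copy()
    out["window_group"] = pd.Categorical(group, categories=[g.value for g in GROUP_ORDER])
    return out


def group_counts(assignments: pd.DataFrame) -> pd.DataFrame:
    """Group sizes and percentage shares from a classified cohort."""
    counts = assignments["window_group"].value_counts().reindex(
        [g.value for g in GROUP_ORDER], fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame({"n": counts, "share_pct": 100.0 * counts / total})
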