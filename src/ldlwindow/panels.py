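"""Lipid panels: validated raw measurements and the derived quantities.

A *panel* is one subject's fasting lipid measurements: total cholesterol,
HDL-C, TG, directly measured LDL-C, small-dense LDL cholesterol
(sdLDL-C), apoB, and optionally gradient-gel LDL particle size and
HbA1c (JDS standardization).  All concentrations are mg/dL, size in nm.

Derived quantities follow the standard clinical definitions:

* non-HDL-C  = total-C − HDL-C   (all apoB-particle cholesterol)
* lbLDL-C    = LDL-C − sdLDL-C   (large buoyant LDL cholesterol)
* sdLDL-C/LDL-C fraction, in percent
* LDL-C/apoB ratio (a particle cholesterol-content proxy for size)
* pattern B  = LDL size < 25.5 nm (strict), the small-LDL phenotype
* HbA1c NGSP = 1.02 × HbA1c(JDS) + 0.25

Validation is total: a panel either satisfies every plausibility
invariant or raises :class:`PanelValidationError` naming the offending
field and rule.  Inconsistent assay values (e.g. sdLDL-C > LDL-C) are
rejected, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

PATTERN_B_THRESHOLD_NM = 25.5
LDL_SIZE_BAND_NM = (23.0, 29.0)

#: Canonical column order for delimited panel files.
PANEL_COLUMNS = [
    "subject_id", "cohort", "age", "sex", "diabetes",
    "total_c", "hdl_c", "tg", "ldl_c", "sdldl_c", "apob",
    "ldl_size", "hba1c_jds",
]

DERIVED_COLUMNS = [
    "non_hdl_c", "lbldl_c", "sdldl_fraction", "ldl_apob_ratio",
    "pattern_b", "hba1c_ngsp",
]


class PanelValidationError(ValueError):
    """A panel (or a cohort of panels) violates a plausibility invariant.

    Attributes
    ----------
    field : name of the offending measurement
    rule : human-readable statement of the violated rule
    subject_ids : offending subjects, when validating a cohort
    """

    def __init__(self, field: str, rule: str, subject_ids: list | None = None):
        self.field = field
        self.rule = rule
        self.subject_ids = list(subject_ids) if subject_ids is not None else None
        msg = f"{field}: {rule}"
        if self.subject_ids:
            shown = ", ".join(map(str, self.subject_ids[:10]))
            more = "" if len(self.subject_ids) <= 10 else f" (+{len(self.subject_ids) - 10} more)"
            msg += f" [subjects: {shown}{more}]"
        super().__init__(msg)


# ---------------------------------------------------------------------------
# scalar/vector derivation operations
# ---------------------------------------------------------------------------

def _check_positive(value, field: str):
    if np.any(np.asarray(value) <= 0):
        raise PanelValidationError(field, "must be strictly positive")


def derive_non_hdl(total_c, hdl_c):
    """Non-HDL cholesterol: total-C minus HDL-C (mg/dL).

    Requires ``total_c > hdl_c > 0``; accepts scalars or arrays.
    """
    _check_positive(hdl_c, "hdl_c")
    _check_positive(total_c, "total_c")
    if np.any(np.asarray(total_c) <= np.asarray(hdl_c)):
        raise PanelValidationError("hdl_c", "must be below total_c")
    return np.subtract(total_c, hdl_c)


def derive_lbldl(ldl_c, sdldl_c):
    """Large-buoyant LDL cholesterol: LDL-C minus sdLDL-C (mg/dL).

    ``sdldl_c > ldl_c`` indicates inconsistent assay values and raises.
    """
    _check_positive(sdldl_c, "sdldl_c")
    if np.any(np.asarray(sdldl_c) > np.asarray(ldl_c)):
        raise PanelValidationError("sdldl_c", "cannot exceed ldl_c (inconsistent assays)")
    return np.subtract(ldl_c, sdldl_c)


def sdldl_fraction(sdldl_c, ldl_c):
    """sdLDL-C as a percentage of LDL-C."""
    _check_positive(ldl_c, "ldl_c")
    _check_positive(sdldl_c, "sdldl_c")
    if np.any(np.asarray(sdldl_c) > np.asarray(ldl_c)):
        raise PanelValidationError("sdldl_c", "cannot exceed ldl_c (inconsistent assays)")
    return 100.0 * np.divide(sdldl_c, ldl_c)


def ldl_apob_ratio(ldl_c, apob):
    """LDL-C/apoB ratio (dimensionless); rises with LDL particle size."""
    _check_positive(apob, "apob")
    if np.any(np.asarray(ldl_c) < 0):
        raise PanelValidationError("ldl_c", "must be non-negative")
    return np.divide(ldl_c, apob)


def hba1c_ngsp(jds):
    """Convert HbA1c from JDS to NGSP standardization: 1.02·JDS + 0.25."""
    arr = np.asarray(jds, dtype=float)
    if np.any((arr < 0) | (arr >= 20)):
        raise PanelValidationError("hba1c_jds", "must lie in [0, 20) percent")
    return 1.02 * np.asarray(jds) + 0.25


def call_pattern_b(ldl_size, threshold: float = PATTERN_B_THRESHOLD_NM):
    """Small-LDL phenotype call: pattern B iff size < threshold (strict).

    Sizes at exactly the threshold are pattern A.
    """
    arr = np.asarray(ldl_size, dtype=float)
    lo, hi = LDL_SIZE_BAND_NM
    valid = np.isnan(arr) | ((arr >= lo) & (arr <= hi))
    if not np.all(valid):
        raise PanelValidationError("ldl_size", f"outside plausibility band [{lo}, {hi}] nm")
    return np.less(ldl_size, threshold)


# ---------------------------------------------------------------------------
# panel container and cohort-level operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LipidPanel:
    """One subject's raw lipid panel.  ``validate()`` enforces invariants."""

    subject_id: str
    cohort: str
    age: float
    sex: str
    diabetes: bool
    total_c: float
    hdl_c: float
    tg: float
    ldl_c: float
    sdldl_c: float
    apob: float
    ldl_size: float | None = None
    hba1c_jds: float | None = None

    def validate(self) -> "LipidPanel":
        frame = pd.DataFrame([self.__dict__])
        validate_panels(frame)
        return self


_RULES = [
    # (field, rule text, row-wise violation predicate)
    ("total_c", "must be strictly positive", lambda d: d["total_c"] <= 0),
    ("hdl_c", "must be strictly positive", lambda d: d["hdl_c"] <= 0),
    ("tg", "must be strictly positive", lambda d: d["tg"] <= 0),
    ("ldl_c", "must be strictly positive", lambda d: d["ldl_c"] <= 0),
    ("sdldl_c", "must be strictly positive", lambda d: d["sdldl_c"] <= 0),
    ("apob", "must be strictly positive", lambda d: d["apob"] <= 0),
    ("hdl_c", "must be below total_c", lambda d: d["hdl_c"] >= d["total_c"]),
    ("sdldl_c", "cannot exceed ldl_c", lambda d: d["sdldl_c"] > d["ldl_c"]),
    ("ldl_c", "cannot exceed non-HDL-C (total_c - hdl_c)",
     lambda d: d["ldl_c"] > d["total_c"] - d["hdl_c"]),
    ("ldl_size", f"outside plausibility band {LDL_SIZE_BAND_NM} nm",
     lambda d: d["ldl_size"].notna()
     & ((d["ldl_size"] < LDL_SIZE_BAND_NM[0]) | (d["ldl_size"] > LDL_SIZE_BAND_NM[1]))
     if "ldl_size" in d else pd.Series(False, index=d.index)),
]


def validate_panels(panels: pd.DataFrame) -> pd.DataFrame:
    """Check every panel invariant on a cohort frame; raise on the first
    violated rule with the offending subject ids.  Returns the frame."""
    required = [c for c in PANEL_COLUMNS if c not in ("ldl_size", "hba1c_jds")]
    missing = [c for c in required if c not in panels.columns]
    if missing:
        raise PanelValidationError(missing[0], "required column missing")
    for field, rule, predicate in _RULES:
        bad = predicate(panels)
        if bad.any():
            ids = panels.loc[bad, "subject_id"].tolist()
            raise PanelValidationError(field, rule, subject_ids=ids)
    return panels


def derive_panels(panels: pd.DataFrame, pattern_threshold: float = PATTERN_B_THRESHOLD_NM,
                  validate: bool = True) -> pd.DataFrame:
    """Attach all derived quantities to a validated cohort frame.

    Optional inputs propagate as missing derived values: subjects without
    ``ldl_size`` get no ``pattern_b`` call and subjects without
    ``hba1c_jds`` get no ``hba1c_ngsp``.
    """
    if validate:
        validate_panels(panels)
    out = panels.copy()
    out["non_hdl_c"] = derive_non_hdl(out["total_c"].to_numpy(), out["hdl_c"].to_numpy())
    out["lbldl_c"] = derive_lbldl(out["ldl_c"].to_numpy(), out["sdldl_c"].to_numpy())
    out["sdldl_fraction"] = sdldl_fraction(out["sdldl_c"].to_numpy(), out["ldl_c"].to_numpy())
    out["ldl_apob_ratio"] = ldl_apob_ratio(out["ldl_c"].to_numpy(), out["apob"].to_numpy())
    if "ldl_size" in out.columns:
        size = out["ldl_size"].to_numpy(dtype=float)
        pat = pd.array(call_pattern_b(size, pattern_threshold), dtype="boolean")
        pat[np.isnan(size)] = pd.NA
        out["pattern_b"] = pat
    else:
        out["pattern_b"] = pd.array([pd.NA] * len(out), dtype="boolean")
    if "hba1c_jds" in out.columns:
        jds = out["hba1c_jds"].to_numpy(dtype=float)
        ngsp = np.full(len(out), np.nan)
        has = ~np.isnan(jds)
        if has.any():
            ngsp[has] = hba1c_ngsp(jds[has])
        out["hba1c_ngsp"] = ngsp
    else:
        out["hba1c_ngsp"] = np.nan
    return out


# ---------------------------------------------------------------------------
# delimited text I/O
# ---------------------------------------------------------------------------

def read_panels(path, sep: str = ",", validate: bool = True) -> pd.DataFrame:
    """Read a delimited panel file with the canonical header."""
    frame = pd.read_csv(path, sep=sep)
    if validate:
        validate_panels(frame)
    return frame


def write_panels(panels: pd.DataFrame | Iterable[LipidPanel], path, sep: str = ",") -> None:
    """Write panels as delimited text (canonical column order first)."""
    if not isinstance(panels, pd.DataFrame):
        panels = pd.DataFrame([p.__dict__ for p in panels])
    cols = [c for c in PANEL_COLUMNS if c in panels.columns]
    cols += [c for c in panels.columns if c not in cols]
    panels[cols].to_csv(path, sep=sep, index=False)
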