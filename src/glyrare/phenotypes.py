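"""Derived glycaemic phenotypes and medication adjustments.

Pure functions over oral-glucose-tolerance-test (OGTT) measurements and a
phenotype table: the insulinogenic index (early insulin secretion), trapezoid
areas under glucose/insulin excursion curves, the incretin effect (oral vs
intravenous insulin response), additive blood-pressure medication adjustment,
and trait transforms.  Missing values propagate as missing, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OGTTRecord",
    "UndefinedValueError",
    "TooFewPointsError",
    "insulinogenic_index",
    "auc_trapezoid",
    "incretin_effect",
    "adjust_bp_for_meds",
    "adjust_bp_table",
    "preprocess_trait",
]


class UndefinedValueError(ValueError):
    """A derived phenotype is undefined for these inputs (e.g. zero denominator)."""


class TooFewPointsError(ValueError):
    """Fewer time points than the AUC rule requires (>= 3)."""


@dataclass(frozen=True)
class OGTTRecord:
    """Glucose/insulin excursion sampled at minutes from the glucose load."""

    times: tuple[float, ...]
    glucose: tuple[float, ...]
    insulin: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        for name in ("glucose", "insulin"):
            v = np.asarray(getattr(self, name), dtype=float)
            if len(v) != len(t):
                raise ValueError(f"{name} must align with times")
            if np.any(v[~np.isnan(v)] < 0):
                raise ValueError(f"{name} values must be non-negative")


def insulinogenic_index(ins0, ins30, glu0, glu30):
    """(insulin at 30 min − fasting insulin) / (glucose at 30 min − fasting glucose).

    Insulin in pmol/l, glucose in mmol/l (units are carried by convention, not
    converted).  Missing inputs (NaN) propagate; a zero glucose increment makes
    the index undefined.
    """
    vals = [ins0, ins30, glu0, glu30]
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        return float("nan")
    if glu30 == glu0:
        raise UndefinedValueError("glucose increment is zero; insulinogenic index undefined")
    return (ins30 - ins0) / (glu30 - glu0)


def auc_trapezoid(record: OGTTRecord, series: str = "glucose") -> float:
    """Area under the excursion curve by the trapezoid rule, in value·minutes.

    Requires at least 3 sampled time points.
    """
    if series not in ("glucose", "insulin"):
        raise ValueError("series must be 'glucose' or 'insulin'")
    t = np.asarray(record.times, dtype=float)
    if len(t) < 3:
        raise TooFewPointsError(f"AUC needs >= 3 OGTT time points, got {len(t)}")
    v = np.asarray(getattr(record, series), dtype=float)
    if np.any(np.isnan(v)):
        return float("nan")
    return float(np.trapezoid(v, t))


def incretin_effect(auc_ins_ogtt: float, auc_ins_ivgtt: float) -> float:
    """Fractional augmentation of insulin response after oral vs IV glucose.

    (AUC_oral − AUC_iv) / AUC_oral; undefined when the oral AUC is zero.
    """
    if np.isnan(auc_ins_ogtt) or np.isnan(auc_ins_ivgtt):
        return float("nan")
    if auc_ins_ogtt == 0:
        raise UndefinedValueError("oral insulin AUC is zero; incretin effect undefined")
    return (auc_ins_ogtt - auc_ins_ivgtt) / auc_ins_ogtt


def adjust_bp_for_meds(sbp, dbp, on_bp_meds):
    """Add 15 mmHg systolic / 10 mmHg diastolic for treated individuals.

    Vectorized over numpy arrays; untreated values pass through unchanged.
    The pipeline guards against double application via a provenance flag.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    treated = np.asarray(on_bp_meds, dtype=bool)
    sbp_adj = np.where(treated, sbp + 15.0, sbp)
    dbp_adj = np.where(treated, dbp + 10.0, dbp)
    if sbp_adj.ndim == 0:
        return float(sbp_adj), float(dbp_adj)
    return sbp_adj, dbp_adj


def adjust_bp_table(pheno, sbp_col: str = "sbp", dbp_col: str = "dbp",
                    meds_col: str = "on_bp_meds"):
    """Apply the medication adjustment to a phenotype table exactly once.

    A provenance flag in ``DataFrame.attrs`` guards against double
    application; a second call raises.
    """
    if pheno.attrs.get("bp_meds_adjusted"):
        raise ValueError("blood-pressure medication adjustment already applied")
    out = pheno.copy()
    sbp, dbp = adjust_bp_for_meds(
        out[sbp_col].to_numpy(), out[dbp_col].to_numpy(),
        out[meds_col].to_numpy().astype(bool),
    )
    out[sbp_col] = sbp
    out[dbp_col] = dbp
    out.attrs["bp_meds_adjusted"] = True
    return out


def preprocess_trait(values, transform: str = "none"):
    """Apply the configured trait transform element-wise.

    ``transform`` is ``none`` or ``log`` (natural log; e.g. fasting insulin is
    log transformed before association testing).  Returns
    ``(transformed, provenance)`` where provenance records the transform
    applied.  NaN propagates; non-positive values under log raise.
    """
    v = np.asarray(values, dtype=float)
    if transform == "none":
        return v.copy(), {"transform": "none"}
    if transform == "log":
        finite = v[~np.isnan(v)]
        if np.any(finite <= 0):
            raise ValueError("natural-log transform requires strictly positive values")
        return np.log(v), {"transform": "log"}
    raise ValueError(f"unknown transform {transform!r}")
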