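"""Combination sensitivity scoring: normalized AUCs, CSS1/CSS2/CSS and the
between-arm consistency QC filter."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ._exceptions import FitError
from .curves import combination_auc, fit_combination_curve
from .io_data import CrossDesignRecord

logger = logging.getLogger(__name__)

DEFAULT_INH_MIN = 0.10
DEFAULT_QC_THRESHOLD = 10.0


@dataclass(frozen=True)
class CssResult:
    block_id: str
    css1: float
    css2: float
    css: float
    abs_diff: float
    qc_pass: bool
    inh_min_used: float
    valid: bool = True
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "block_id": self.block_id,
            "css1": self.css1, "css2": self.css2, "css": self.css,
            "abs_diff": self.abs_diff, "qc_pass": self.qc_pass,
            "inh_min_used": self.inh_min_used, "valid": self.valid,
            "notes": self.notes,
        }


def normalize_auc(auc: float, conc_range, inh_min: float = DEFAULT_INH_MIN) -> float:
    """Normalize an AUC to the fraction of its maximal possible inhibition.

    ``(auc - inh_min * (c2 - c1)) / ((1 - inh_min) * (c2 - c1))``, where the
    ``inh_min`` floor (default 10%) is treated as experimental noise. The
    result is clipped to [0, 1]; clipping is logged.
    """
    c1, c2 = conc_range
    if not c2 > c1:
        raise ValueError("conc_range must satisfy c2 > c1")
    if not 0.0 <= inh_min < 1.0:
        raise ValueError("inh_min must be in [0, 1)")
    width = c2 - c1
    raw = (auc - inh_min * width) / ((1.0 - inh_min) * width)
    if raw < 0.0 or raw > 1.0:
        logger.debug("normalized AUC %.4f clipped to [0, 1]", raw)
    return float(np.clip(raw, 0.0, 1.0))


def combine_css(block_id: str, css1: float, css2: float,
                qc_threshold: float = DEFAULT_QC_THRESHOLD,
                inh_min: float = DEFAULT_INH_MIN, notes: str = "") -> CssResult:
    """Average the two background-drug-specific CSS values and apply QC.

    ``abs_diff`` exactly at the threshold still passes; only a strictly
    bigger between-arm difference fails.
    """
    abs_diff = abs(css1 - css2)
    return CssResult(
        block_id=block_id, css1=css1, css2=css2,
        css=(css1 + css2) / 2.0, abs_diff=abs_diff,
        qc_pass=abs_diff <= qc_threshold,
        inh_min_used=inh_min, notes=notes,
    )


def css_of_curve(curve, inh_min: float = DEFAULT_INH_MIN) -> float:
    """Percent-scale CSS of a single fitted combination curve."""
    return 100.0 * normalize_auc(combination_auc(curve), curve.conc_range, inh_min)


def css_from_cross(rec: CrossDesignRecord,
                   inh_min: float = DEFAULT_INH_MIN,
                   qc_threshold: float = DEFAULT_QC_THRESHOLD) -> CssResult:
    """CSS1/CSS2/CSS of a cross-design record.

    Each arm is fitted with the four-parameter log-logistic and its AUC
    normalized over that arm's tested log10 range. A hard fit failure on
    either arm yields an invalid result (NaN scores, ``qc_pass=False``)
    rather than an exception, so batch scoring can continue.
    """
    try:
        curve1 = fit_combination_curve(rec.curve1_points)
        curve2 = fit_combination_curve(rec.curve2_points)
    except FitError as exc:
        return CssResult(
            block_id=rec.block_id, css1=math.nan, css2=math.nan, css=math.nan,
            abs_diff=math.nan, qc_pass=False, inh_min_used=inh_min,
            valid=False, notes=f"fit failed: {exc}",
        )
    css1 = css_of_curve(curve1, inh_min)
    css2 = css_of_curve(curve2, inh_min)
    notes = ""
    if not (curve1.fit_diag.converged and curve2.fit_diag.converged):
        notes = "trapezoid fallback used"
    return combine_css(rec.block_id, css1, css2, qc_threshold, inh_min, notes)


def qc_filter(results, threshold: float = DEFAULT_QC_THRESHOLD):
    """Partition CSS results into (pass, fail) at the given threshold.

    Invalid results (unfittable blocks) always land in the fail set.
    """
    results = list(results)
    if not results:
        raise ValueError("no CSS results to filter")
    passed = [r for r in results
              if r.valid and not math.isnan(r.abs_diff) and r.abs_diff <= threshold]
    failed = [r for r in results if r not in passed]
    logger.info("QC filter at %.3g: %d pass, %d fail",
                threshold, len(passed), len(failed))
    return passed, failed
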