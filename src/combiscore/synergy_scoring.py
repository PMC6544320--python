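"""S synergy scores from the cross design and the four full-matrix
reference synergy models (HSA, Bliss, Loewe, ZIP) that define the
consensus synergistic/antagonistic ground truth.

All per-cell scores work on inhibition fractions; matrix-level averages
and the S scores are reported on the percent-inhibition scale so they are
commensurate with CSS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from ._exceptions import DesignError, FitError
from .css_scoring import DEFAULT_INH_MIN, DEFAULT_QC_THRESHOLD, css_from_cross, normalize_auc
from .curves import (
    MonotherapyCurve,
    fit_combination_curve,
    fit_monotherapy_curve,
    monotherapy_auc,
)
from .io_data import DoseResponseMatrix, extract_cross

SYNERGISTIC = "synergistic"
ANTAGONISTIC = "antagonistic"
NON_INTERACTIVE = "non-interactive"

DEFAULT_CONSENSUS_THRESHOLD = 5.0
S_VARIANTS = ("sum", "max", "mean")


# ---------------------------------------------------------------------------
# S scores
# ---------------------------------------------------------------------------


def normalized_monotherapy_auc(curve: MonotherapyCurve,
                               inh_min: float = DEFAULT_INH_MIN) -> float:
    """Monotherapy AUC normalized like CSS, on the percent scale."""
    return 100.0 * normalize_auc(monotherapy_auc(curve), curve.conc_range, inh_min)


def s_scores(css: float, mono1: MonotherapyCurve, mono2: MonotherapyCurve,
             inh_min: float = DEFAULT_INH_MIN) -> tuple[float, float, float]:
    """(s_sum, s_max, s_mean): CSS minus the sum / max / mean of the two
    normalized monotherapy AUCs, all on the percent-inhibition scale."""
    auc1 = normalized_monotherapy_auc(mono1, inh_min)
    auc2 = normalized_monotherapy_auc(mono2, inh_min)
    return (css - (auc1 + auc2), css - max(auc1, auc2),
            css - (auc1 + auc2) / 2.0)


# ---------------------------------------------------------------------------
# Reference-model cell scores (fractions)
# ---------------------------------------------------------------------------


def hsa_cell(y_c: float, y1: float, y2: float) -> float:
    """Observed effect minus the highest single-agent effect."""
    return y_c - max(y1, y2)


def bliss_cell(y_c: float, y1: float, y2: float) -> float:
    """Observed effect minus the independence expectation ``y1 + y2 - y1*y2``."""
    return y_c - (y1 + y2 - y1 * y2)


def loewe_cell(y_c: float, x1: float, x2: float,
               mono1: MonotherapyCurve, mono2: MonotherapyCurve) -> float:
    """Observed effect minus the dose-additivity expectation.

    The expectation is the effect of the summed dose ``x1 + x2`` evaluated on
    the fitted monotherapy curves; with two distinct curves the mean of the
    two evaluations is used (they coincide for a drug combined with itself).
    """
    if x1 + x2 <= 0:
        raise ValueError("x1 + x2 must be > 0")
    total = x1 + x2
    y_e = 0.5 * (float(mono1.predict_conc(total)) + float(mono2.predict_conc(total)))
    return y_c - y_e


def _fit_line(concs, fracs):
    """Fit one matrix row/column (percent scale expected by the fitter)."""
    pts = [(c, 100.0 * y) for c, y in zip(concs, fracs) if not math.isnan(y)]
    if len({c for c, _ in pts}) < 2:
        raise FitError("fewer than 2 defined cells in line")
    return fit_combination_curve(pts)


def zip_cell(matrix: DoseResponseMatrix, mono1: MonotherapyCurve,
             mono2: MonotherapyCurve, at: tuple[float, float]) -> float:
    """Zero-interaction-potency score for one combination cell.

    ``y'_1`` and ``y'_2`` are the fitted monotherapy values; ``y'_c`` is the
    mean of log-logistic fits along the cell's matrix row (drug 2 titrated)
    and column (drug 1 titrated), each evaluated at ``at = (x1, x2)``. If
    neither direction is fittable the observed cell value is used instead.
    """
    x1, x2 = at
    i = int(np.where(matrix.row_concs == x1)[0][0])
    j = int(np.where(matrix.col_concs == x2)[0][0])
    row_mask = matrix.col_concs > 0
    col_mask = matrix.row_concs > 0

    fitted = []
    try:
        row_curve = _fit_line(matrix.col_concs[row_mask],
                              matrix.inhibition[i, row_mask] / 100.0)
        fitted.append(float(row_curve.predict_conc(x2)))
    except FitError:
        pass
    try:
        col_curve = _fit_line(matrix.row_concs[col_mask],
                              matrix.inhibition[col_mask, j] / 100.0)
        fitted.append(float(col_curve.predict_conc(x1)))
    except FitError:
        pass
    if fitted:
        y_c = float(np.mean(fitted))
    else:
        warnings.warn(f"ZIP: unfittable row and column at {at}; using observed cell")
        y_c = float(matrix.inhibition[i, j]) / 100.0
    y1 = float(mono1.predict_conc(x1))
    y2 = float(mono2.predict_conc(x2))
    return y_c - (y1 + y2 - y1 * y2)


# ---------------------------------------------------------------------------
# Matrix-level averages
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceScores:
    """Matrix-averaged reference synergy scores on the percent scale."""

    hsa: float
    bliss: float
    loewe: float
    zip_score: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.hsa, self.bliss, self.loewe, self.zip_score)


def fit_matrix_monotherapies(matrix: DoseResponseMatrix):
    """Fit both monotherapy curves from the zero-dose margins."""
    if not matrix.has_margins:
        raise DesignError(
            f"block {matrix.block_id}: zero-dose margins are required")
    m1 = matrix.monotherapy_points(1)
    m2 = matrix.monotherapy_points(2)
    if len(m1) < 2 or len(m2) < 2:
        raise DesignError(
            f"block {matrix.block_id}: monotherapy margins too sparse to fit")
    return fit_monotherapy_curve(m1), fit_monotherapy_curve(m2)


def matrix_synergy(matrix: DoseResponseMatrix,
                   mono1: MonotherapyCurve | None = None,
                   mono2: MonotherapyCurve | None = None) -> ReferenceScores:
    """Average the four per-cell reference scores over all combination cells
    (both doses strictly positive); zero-dose margins are excluded.

    HSA and Bliss use the observed margin responses; Loewe and ZIP use the
    fitted monotherapy curves (fitted here from the margins unless supplied).
    """
    if mono1 is None or mono2 is None:
        mono1, mono2 = fit_matrix_monotherapies(matrix)
    i0 = int(np.where(matrix.row_concs == 0.0)[0][0])
    j0 = int(np.where(matrix.col_concs == 0.0)[0][0])

    rows = np.where(matrix.row_concs > 0)[0]
    cols = np.where(matrix.col_concs > 0)[0]
    rc = matrix.row_concs[rows]
    cc = matrix.col_concs[cols]
    combo = matrix.inhibition[np.ix_(rows, cols)] / 100.0
    defined = ~np.isnan(combo)
    if not defined.any():
        raise DesignError(f"block {matrix.block_id}: no combination cells")

    y1_obs = matrix.inhibition[rows, j0] / 100.0  # margin of drug 1 per row
    y2_obs = matrix.inhibition[i0, cols] / 100.0  # margin of drug 2 per col
    Y1 = y1_obs[:, None] + np.zeros_like(combo)
    Y2 = y2_obs[None, :] + np.zeros_like(combo)

    hsa_grid = combo - np.maximum(Y1, Y2)
    bliss_grid = combo - (Y1 + Y2 - Y1 * Y2)

    total = rc[:, None] + cc[None, :]
    loewe_expect = 0.5 * (mono1.predict_conc(total) + mono2.predict_conc(total))
    loewe_grid = combo - loewe_expect

    # ZIP: cache one fit per row and per column, then evaluate at every cell.
    row_pred = np.full_like(combo, np.nan)
    for a, i in enumerate(rows):
        try:
            curve = _fit_line(cc, matrix.inhibition[i, cols] / 100.0)
            row_pred[a, :] = curve.predict_conc(cc)
        except FitError:
            pass
    col_pred = np.full_like(combo, np.nan)
    for b, j in enumerate(cols):
        try:
            curve = _fit_line(rc, matrix.inhibition[rows, j] / 100.0)
            col_pred[:, b] = curve.predict_conc(rc)
        except FitError:
            pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yc_fit = np.nanmean(np.stack([row_pred, col_pred]), axis=0)
    yc_fit = np.where(np.isnan(yc_fit), combo, yc_fit)  # no-fit fallback
    y1_fit = np.asarray(mono1.predict_conc(rc))[:, None] + np.zeros_like(combo)
    y2_fit = np.asarray(mono2.predict_conc(cc))[None, :] + np.zeros_like(combo)
    zip_grid = yc_fit - (y1_fit + y2_fit - y1_fit * y2_fit)

    def avg(grid):
        return 100.0 * float(np.mean(grid[defined]))

    return ReferenceScores(hsa=avg(hsa_grid), bliss=avg(bliss_grid),
                           loewe=avg(loewe_grid), zip_score=avg(zip_grid))


def consensus_label(scores, threshold: float = DEFAULT_CONSENSUS_THRESHOLD) -> str:
    """Consensus class across (hsa, bliss, loewe, zip), all strictly beyond
    +threshold / -threshold; anything else is non-interactive."""
    vals = scores.as_tuple() if isinstance(scores, ReferenceScores) else tuple(scores)
    if len(vals) != 4 or not all(math.isfinite(v) for v in vals):
        raise ValueError("need four finite reference scores")
    if min(vals) > threshold:
        return SYNERGISTIC
    if max(vals) < -threshold:
        return ANTAGONISTIC
    return NON_INTERACTIVE


# ---------------------------------------------------------------------------
# Block-level scoring record and the cross-design pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynergyResult:
    """Per-block synergy summary: cross-design S scores plus the four
    full-matrix reference scores and their consensus label."""

    block_id: str
    s_sum: float
    s_max: float
    s_mean: float
    auc1_pct: float
    auc2_pct: float
    hsa: float
    bliss: float
    loewe: float
    zip_score: float
    consensus: str
    css: float = math.nan
    css1: float = math.nan
    css2: float = math.nan
    qc_pass: bool = True
    drug_row: str = ""
    drug_col: str = ""
    cell_line: str = ""

    def s_variant(self, variant: str) -> float:
        if variant not in S_VARIANTS:
            raise ValueError(f"unknown S variant {variant!r}")
        return getattr(self, f"s_{variant}")

    def to_dict(self) -> dict:
        return {
            "block_id": self.block_id, "drug_row": self.drug_row,
            "drug_col": self.drug_col, "cell_line": self.cell_line,
            "css1": self.css1, "css2": self.css2, "css": self.css,
            "qc_pass": self.qc_pass,
            "s_sum": self.s_sum, "s_max": self.s_max, "s_mean": self.s_mean,
            "auc1_pct": self.auc1_pct, "auc2_pct": self.auc2_pct,
            "hsa": self.hsa, "bliss": self.bliss, "loewe": self.loewe,
            "zip": self.zip_score, "consensus": self.consensus,
        }


def score_block(matrix: DoseResponseMatrix,
                inh_min: float = DEFAULT_INH_MIN,
                qc_threshold: float = DEFAULT_QC_THRESHOLD,
                consensus_threshold: float = DEFAULT_CONSENSUS_THRESHOLD,
                ic50_1: float | None = None,
                ic50_2: float | None = None) -> SynergyResult:
    """Full scoring of one dose-response matrix block.

    Monotherapy curves are fitted from the margins; unless supplied, the
    IC50 anchors for the cross extraction are the fitted midpoints.
    """
    mono1, mono2 = fit_matrix_monotherapies(matrix)
    cross = extract_cross(matrix,
                          ic50_1 if ic50_1 is not None else mono1.ic50,
                          ic50_2 if ic50_2 is not None else mono2.ic50)
    css_res = css_from_cross(cross, inh_min=inh_min, qc_threshold=qc_threshold)
    refs = matrix_synergy(matrix, mono1, mono2)
    ssum, smax, smean = s_scores(css_res.css, mono1, mono2, inh_min)
    auc1 = normalized_monotherapy_auc(mono1, inh_min)
    auc2 = normalized_monotherapy_auc(mono2, inh_min)
    return SynergyResult(
        block_id=matrix.block_id,
        s_sum=ssum, s_max=smax, s_mean=smean,
        auc1_pct=auc1, auc2_pct=auc2,
        hsa=refs.hsa, bliss=refs.bliss, loewe=refs.loewe,
        zip_score=refs.zip_score,
        consensus=consensus_label(refs, consensus_threshold),
        css=css_res.css, css1=css_res.css1, css2=css_res.css2,
        qc_pass=css_res.qc_pass,
        drug_row=matrix.drug_row, drug_col=matrix.drug_col,
        cell_line=matrix.cell_line,
    )


# ---------------------------------------------------------------------------
# Evaluation and prioritization
# ---------------------------------------------------------------------------


def evaluate_s_scores(results, variants=S_VARIANTS) -> dict[str, tuple[float, float]]:
    """AUROC / AUPRC of each S variant for ranking consensus-synergistic
    (positive) above consensus-antagonistic blocks; non-interactive blocks
    are excluded. Raises ``ValueError`` when only one class is present."""
    results = [r for r in results if r.consensus != NON_INTERACTIVE]
    labels = np.array([1 if r.consensus == SYNERGISTIC else 0 for r in results])
    if labels.size == 0 or labels.min() == labels.max():
        raise ValueError("need both synergistic and antagonistic blocks")
    out = {}
    for variant in variants:
        scores = np.array([r.s_variant(variant) for r in results], dtype=float)
        out[variant] = (float(roc_auc_score(labels, scores)),
                        float(average_precision_score(labels, scores)))
    return out


def ss_prioritize(scores, quantile: float = 0.75,
                  variant: str = "sum") -> pd.DataFrame:
    """Sensitivity-synergy prioritization: flag blocks at or above the given
    quantile (linear interpolation) of both CSS and the chosen S variant.

    ``scores`` may be a DataFrame with ``css`` and ``s_<variant>`` columns or
    an iterable of :class:`SynergyResult`.
    """
    if not isinstance(scores, pd.DataFrame):
        scores = pd.DataFrame([r.to_dict() for r in scores])
    col = f"s_{variant}"
    if col not in scores.columns or "css" not in scores.columns:
        raise ValueError(f"scores must provide 'css' and {col!r} columns")
    df = scores.copy()
    css_thr = float(np.quantile(df["css"].to_numpy(float), quantile))
    s_thr = float(np.quantile(df[col].to_numpy(float), quantile))
    df["css_threshold"] = css_thr
    df["s_threshold"] = s_thr
    df["hit"] = (df["css"] >= css_thr) & (df[col] >= s_thr)
    return df
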