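"""Model evaluation and plausibility analyses.

Covers ROC/AUC (rank / Mann-Whitney formulation, ties count 1/2), cutoff
classification at 0.5, the DeLong test for comparing correlated AUCs via
structural components, an IPI clinical baseline (score >= 4 = high risk),
Platt-style logistic calibration of the raw probabilities, Pearson
association of predictions with MTV and Dmax_bulk, and the tumour-ablation
analysis that re-predicts on MIPs whose tumours were replaced by mean
background-free intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .mip_engine import ablate_tumours
from .volume_io import PatientRecord, TTP1

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.5
IPI_HIGH_RISK = 4


@dataclass
class EvalReport:
    auc: float
    sensitivity: float          # NaN when undefined (no positives)
    specificity: float          # NaN when undefined (no negatives)
    cutoff: float
    n_pos: int
    n_neg: int
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame)
    auc_other: Optional[float] = None
    delong_p: Optional[float] = None

    def to_dict(self) -> dict:
        d = {"auc": self.auc, "sensitivity": self.sensitivity,
             "specificity": self.specificity, "cutoff": self.cutoff,
             "n_pos": self.n_pos, "n_neg": self.n_neg}
        if self.auc_other is not None:
            d["auc_other"] = self.auc_other
            d["delong_p"] = self.delong_p
        return d


@dataclass
class CalibrationFit:
    """Univariate logistic map from raw P(TTP1) to calibrated probability."""

    intercept: float
    slope: float
    penalized: bool = False


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney U) formulation.

    Equals the probability that a random positive outranks a random
    negative, with ties contributing 1/2.
    """
    labels = _check_binary(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = stats.rankdata(scores)  # midranks handle ties
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def classify_at_cutoff(p_ttp1: Sequence[float], labels: Sequence[int],
                       cutoff: float = DEFAULT_CUTOFF,
                       patient_ids: Optional[Sequence[str]] = None) -> EvalReport:
    """Sensitivity/specificity at a probability cutoff (>= cutoff => TTP1).

    Sensitivity is reported as NaN (not 0) when there are no positives, and
    likewise specificity without negatives; AUC requires both classes and is
    NaN otherwise.
    """
    p = np.asarray(p_ttp1, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = (p >= cutoff).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    auc = roc_auc(p, y) if (n_pos and n_neg) else float("nan")
    ids = list(patient_ids) if patient_ids is not None else [f"{i}" for i in range(len(p))]
    preds = pd.DataFrame({"patient_id": ids, "p_ttp1": p, "label": y, "predicted": pred})
    return EvalReport(auc=auc, sensitivity=sens, specificity=spec, cutoff=cutoff,
                      n_pos=n_pos, n_neg=n_neg, predictions=preds)


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------

def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """Per-observation placement values (V10 for positives, V01 for negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # V10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i), and symmetrically V01
    v10 = np.array([np.mean((neg < x) + 0.5 * (neg == x)) for x in pos])
    v01 = np.array([np.mean((pos > x) + 0.5 * (pos == x)) for x in neg])
    return v10, v01


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    p_value: float
    z: float
    degenerate: bool = False


def delong_test(scores_a: Sequence[float], scores_b: Sequence[float],
                labels: Sequence[int]) -> DeLongResult:
    """Two-sided DeLong test comparing two correlated (paired) AUCs.

    Both score vectors must be evaluated on the same patients.  The variance
    of the AUC difference is estimated from the covariance of the paired
    structural components; when it vanishes (e.g. identical scores) the
    result is flagged degenerate with p = 1.
    """
    labels = _check_binary(np.asarray(labels))
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape[0] != labels.shape[0]:
        raise ValueError("scores_a, scores_b and labels must be the same length")
    v10a, v01a = _structural_components(a, labels)
    v10b, v01b = _structural_components(b, labels)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 1e-16:
        return DeLongResult(auc_a=auc_a, auc_b=auc_b, p_value=1.0, z=0.0, degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, p_value=float(p), z=float(z))


def auc_confidence_interval(scores: Sequence[float], labels: Sequence[int],
                            level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a Wald confidence interval from the DeLong variance.

    Returns (auc, lower, upper), the interval clipped to [0, 1].
    """
    labels = _check_binary(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    v10, v01 = _structural_components(scores, labels)
    auc = float(v10.mean())
    var = (v10.var(ddof=1) / len(v10) if len(v10) > 1 else 0.0) + \
          (v01.var(ddof=1) / len(v01) if len(v01) > 1 else 0.0)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return auc, max(0.0, auc - half), min(1.0, auc + half)


# ---------------------------------------------------------------------------
# clinical baseline, calibration, plausibility
# ---------------------------------------------------------------------------

def ipi_baseline(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """IPI comparator: raw 0-5 score for ROC, high risk (TTP1) iff IPI >= 4."""
    missing = [r.patient_id for r in records if r.ipi_score is None]
    if missing:
        raise ValueError(f"IPI score missing for patients: {missing}")
    return pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "ipi_score": [int(r.ipi_score) for r in records],
        "high_risk": [int(r.ipi_score) >= IPI_HIGH_RISK for r in records],
        "label": [r.label for r in records],
    })


def fit_calibration(p_ttp1: Sequence[float], labels: Sequence[int]) -> CalibrationFit:
    """Platt-style logistic recalibration: labels ~ logistic(a + b * p_raw).

    Fit by maximum likelihood (IRLS, tolerance 1e-8, up to 100 iterations);
    under perfect separation the ML fit diverges and an L2-penalized fit is
    used instead, with a logged notice.
    """
    y = _check_binary(np.asarray(labels))
    p = np.asarray(p_ttp1, dtype=float)
    X = sm.add_constant(p)
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
        if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > 1e3:
            raise sm.tools.sm_exceptions.PerfectSeparationError("diverging fit")
        return CalibrationFit(intercept=float(res.params[0]), slope=float(res.params[1]))
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError):
        logger.warning("calibration: ML fit separated/diverged, using penalized fit")
        res = sm.Logit(y, X).fit_regularized(alpha=1.0, disp=0, L1_wt=0.0)
        return CalibrationFit(intercept=float(res.params[0]), slope=float(res.params[1]),
                              penalized=True)


def apply_calibration(fit: CalibrationFit, p_ttp1) -> np.ndarray:
    """Logistic of (intercept + slope * p); output strictly inside (0, 1)."""
    p = np.asarray(p_ttp1, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(fit.intercept + fit.slope * p)))
    return np.clip(out, 1e-12, 1 - 1e-12)


def feature_association(p_ttp1: Sequence[float],
                        features: dict[str, Sequence[float]]) -> tuple[dict, pd.DataFrame]:
    """Pearson correlation of P(TTP1) with each PET feature (MTV, Dmax_bulk).

    Returns per-feature r (NaN for zero-variance features) plus the scatter
    table for plotting.
    """
    p = np.asarray(p_ttp1, dtype=float)
    if len(p) < 3:
        raise ValueError("need at least 3 patients")
    out = {}
    scatter = {"p_ttp1": p}
    for name, vals in features.items():
        v = np.asarray(vals, dtype=float)
        if np.std(v) == 0 or np.std(p) == 0:
            out[name] = float("nan")
        else:
            out[name] = float(stats.pearsonr(p, v).statistic)
        scatter[name] = v
    return out, pd.DataFrame(scatter)


def ablation_analysis(trained, mips: dict, lesion_masks: dict,
                      calibration: CalibrationFit,
                      labels: Optional[dict] = None,
                      hist_bins: int = 20) -> tuple[pd.DataFrame, dict]:
    """Tumour-ablation plausibility check.

    For every patient, predicts calibrated P(TTP1) on the original MIP pair
    and on the pair with tumours replaced by mean non-background intensity.
    Returns the paired table plus summary counts (patients crossing from
    > 0.6 before ablation to < 0.4 after) and histogram bins for both
    probability sets.
    """
    from .outcome_cnn import predict  # local import to avoid a cycle

    rows = []
    for pid in sorted(mips):
        cor, sag = mips[pid]["coronal"], mips[pid]["sagittal"]
        mcor, msag = lesion_masks[pid]["coronal"], lesion_masks[pid]["sagittal"]
        p_before = predict(trained, cor, sag).p_ttp1
        p_after = predict(trained, ablate_tumours(cor, mcor),
                          ablate_tumours(sag, msag)).p_ttp1
        cb = float(apply_calibration(calibration, p_before))
        ca = float(apply_calibration(calibration, p_after))
        row = {"patient_id": pid, "p_before": cb, "p_after": ca,
               "raw_before": p_before, "raw_after": p_after}
        if labels is not None:
            row["label"] = labels[pid]
        rows.append(row)
    table = pd.DataFrame(rows)
    edges = np.linspace(0, 1, hist_bins + 1)
    summary = {
        "n": len(table),
        "mean_before": float(table["p_before"].mean()),
        "mean_after": float(table["p_after"].mean()),
        "n_high_before": int((table["p_before"] > 0.6).sum()),
        "n_crossed_low": int(((table["p_before"] > 0.6) & (table["p_after"] < 0.4)).sum()),
        "hist_edges": edges.tolist(),
        "hist_before": np.histogram(table["p_before"], bins=edges)[0].tolist(),
        "hist_after": np.histogram(table["p_after"], bins=edges)[0].tolist(),
    }
    return table, summary
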