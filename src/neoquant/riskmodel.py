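"""Combined-predictor relapse risk model.

Logistic regression of 3-year relapse-free status on log-transformed
neoantigen features with clinical adjustment (sex, stage, smoking), the
predicted relapse-free probabilities, ROC/AUC with Youden-optimal cutoffs,
and a paired AUC comparison.

Eligibility follows the landmark construction: a patient contributes iff
the outcome at the horizon is determined — recurrence before 3 years
(outcome 0) or event-free follow-up of at least 3 years (outcome 1);
patients censored earlier without recurrence are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

DEFAULT_HORIZON_MONTHS = 36.0
DEFAULT_ADJUST = ("sex", "stage", "smoking")


def eligible_at_horizon(
    clinical: pd.DataFrame, horizon: float = DEFAULT_HORIZON_MONTHS
) -> pd.Series:
    """Boolean eligibility mask: relapse-free status determined at horizon."""
    event_before = clinical["ttr_event"].astype(bool) & (
        clinical["ttr_time"] <= horizon
    )
    followed = clinical["ttr_time"] >= horizon
    return event_before | followed


def relapse_free_outcome(
    clinical: pd.DataFrame, horizon: float = DEFAULT_HORIZON_MONTHS
) -> pd.Series:
    """1 = relapse-free at horizon, 0 = recurrence by horizon; NaN ineligible."""
    elig = eligible_at_horizon(clinical, horizon)
    event_before = clinical["ttr_event"].astype(bool) & (
        clinical["ttr_time"] <= horizon
    )
    out = pd.Series(np.nan, index=clinical.index)
    out[elig] = (~event_before[elig]).astype(float)
    return out


@dataclass
class RelapseRiskResults:
    """Fitted logistic model for 3-year relapse-free probability."""

    params: pd.Series  # includes "const"
    bse: pd.Series
    feature_cols: List[str]  # transformed feature column names
    design_cols: List[str]
    log_features: List[str]  # original names that were log1p-transformed
    n: int
    converged: bool
    separation_flag: bool
    penalized: bool

    @property
    def conf_int(self) -> pd.DataFrame:
        z = stats.norm.ppf(0.975)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse,
             "upper": self.params + z * self.bse}
        )

    @property
    def p_values(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "OR": np.exp(self.params),
                "lower95": ci["lower"],
                "upper95": ci["upper"],
                "p": self.p_values,
            }
        )

    def predict_probability(self, x: pd.DataFrame) -> np.ndarray:
        """Relapse-free probability ``1/(1+exp(-(b0 + sum b_i x_i)))`` for a
        design frame in the model's (already transformed) columns."""
        missing = [c for c in self.design_cols if c not in x.columns]
        if missing:
            raise ValueError(f"missing covariates: {missing}")
        eta = self.params["const"] + x[self.design_cols].to_numpy(float) @ \
            self.params[self.design_cols].to_numpy(float)
        return 1.0 / (1.0 + np.exp(-eta))


class RelapseRiskModel:
    """Logistic model of relapse-free status at a fixed horizon.

    Continuous features enter as ``log(x + 1)`` so zero-valued loads are
    admissible; clinical adjustment covariates (sex, stage, smoking) are
    indicator-coded.  ``fit()`` returns :class:`RelapseRiskResults`.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        clinical: pd.DataFrame,
        feature_names: Sequence[str],
        adjust: Sequence[str] = DEFAULT_ADJUST,
        horizon: float = DEFAULT_HORIZON_MONTHS,
        log_transform: bool = True,
    ) -> None:
        if horizon <= 0:
            raise ValueError("horizon must be positive")
        df = features.join(clinical, how="inner", lsuffix="", rsuffix="_clin")
        outcome = relapse_free_outcome(df, horizon)
        df = df[outcome.notna()].copy()
        if df.empty:
            raise ValueError("no patients with determinable 3-year status")
        self.outcome = outcome.dropna().astype(int)
        self.horizon = horizon
        self.feature_names = list(feature_names)
        self.log_transform = log_transform
        design = pd.DataFrame(index=df.index)
        self.log_features: List[str] = []
        for f in self.feature_names:
            x = df[f].astype(float)
            if log_transform:
                design[f"log_{f}"] = np.log1p(x)
                self.log_features.append(f)
            else:
                design[f] = x
        self.feature_cols = list(design.columns)
        for a in adjust:
            if a == "sex":
                design["sex_F"] = (df["sex"] == "F").astype(float)
            elif a == "stage":
                design["stage_II"] = (df["stage"] == "II").astype(float)
                design["stage_III"] = (df["stage"] == "III").astype(float)
            elif a == "smoking":
                design["smoking"] = df["smoking"].astype(float)
            else:
                design[a] = df[a].astype(float)
        # drop constant adjustment columns (e.g. no stage-III patients)
        keep = [c for c in design.columns
                if c in self.feature_cols or design[c].nunique() > 1]
        self.design = design[keep]
        self.n = len(df)

    def fit(self, penalized_fallback: bool = True) -> RelapseRiskResults:
        X = sm.add_constant(self.design, has_constant="add")
        y = self.outcome.to_numpy()
        separation = False
        penalized = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", False))
            except Exception:
                converged = False
                res = None
        if res is None or not converged or not np.all(np.isfinite(res.bse)) \
                or np.max(np.abs(res.params)) > 50:
            separation = True
            if not penalized_fallback:
                raise RuntimeError(
                    "logistic fit did not converge (possible separation)"
                )
            penalized = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                    alpha=1e-3, L1_wt=0.0
                )
            params = pd.Series(res.params, index=X.columns)
            bse = pd.Series(np.nan, index=X.columns)
            return RelapseRiskResults(
                params=params, bse=bse, feature_cols=self.feature_cols,
                design_cols=list(self.design.columns),
                log_features=self.log_features, n=self.n,
                converged=True, separation_flag=True, penalized=True,
            )
        return RelapseRiskResults(
            params=pd.Series(res.params, index=X.columns),
            bse=pd.Series(res.bse, index=X.columns),
            feature_cols=self.feature_cols,
            design_cols=list(self.design.columns),
            log_features=self.log_features,
            n=self.n,
            converged=converged,
            separation_flag=separation,
            penalized=penalized,
        )

    def transformed_design(self) -> pd.DataFrame:
        return self.design.copy()


def predict_probability(params: Dict[str, float], x: Dict[str, float]) -> float:
    """Logistic probability from raw coefficients: ``expit(b0 + sum b_i x_i)``.

    ``params`` must contain ``"const"``; every other key needs a matching
    covariate value in ``x``.
    """
    eta = params["const"]
    for name, beta in params.items():
        if name == "const":
            continue
        if name not in x:
            raise ValueError(f"missing covariate {name!r}")
        eta += beta * x[name]
    return float(1.0 / (1.0 + np.exp(-eta)))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_j: float
    youden_cutoff: float
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)

    def dichotomise(self, scores: Optional[Sequence[float]] = None) -> np.ndarray:
        """'high'/'low' group labels at the Youden-optimal cutoff."""
        s = self.scores if scores is None else np.asarray(scores, dtype=float)
        return np.where(s >= self.youden_cutoff, "high", "low")


def roc_analysis(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Empirical ROC over all score thresholds, trapezoidal AUC and the
    Youden-optimal cutoff (ties broken toward the lowest threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    fpr, tpr, thresh = roc_curve(labels, scores, drop_intermediate=False)
    auc_val = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    jmax = j.max()
    # roc_curve thresholds are decreasing; pick the lowest threshold at max J
    best = np.where(np.isclose(j, jmax))[0][-1]
    cutoff = float(thresh[best])
    if np.isinf(cutoff):
        cutoff = float(scores.max())
    return ROCResult(
        thresholds=thresh,
        sensitivity=tpr,
        specificity=1 - fpr,
        auc=auc_val,
        youden_j=float(jmax),
        youden_cutoff=cutoff,
        scores=scores,
        labels=labels,
    )


def auc_pair_counting(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC by exhaustive positive-negative pair counting (ties count 1/2).

    Independent oracle for the trapezoidal ROC AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required")
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return float(wins / (pos.size * neg.size))


def _placements(pos: np.ndarray, neg: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    v_pos = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / neg.size
                      for p in pos])
    v_neg = np.array([(np.sum(pos > n) + 0.5 * np.sum(pos == n)) / pos.size
                      for n in neg])
    return v_pos, v_neg


def compare_auc(
    roc_a: ROCResult, roc_b: ROCResult, paired: bool = True
) -> Tuple[float, float]:
    """Paired AUC comparison via the covariance of placement values
    (DeLong construction); returns (z, two-sided p).

    In paired mode both ROCs must come from the same subjects in the same
    order.
    """
    if not paired:
        raise NotImplementedError("only the paired comparison is implemented")
    if roc_a.labels.shape != roc_b.labels.shape or np.any(
        roc_a.labels != roc_b.labels
    ):
        raise ValueError("paired comparison requires identical subjects/labels")
    pos_mask = roc_a.labels == 1
    va_p, va_n = _placements(roc_a.scores[pos_mask], roc_a.scores[~pos_mask])
    vb_p, vb_n = _placements(roc_b.scores[pos_mask], roc_b.scores[~pos_mask])
    m, n = va_p.size, va_n.size
    s_p = np.cov(np.vstack([va_p, vb_p])) if m > 1 else np.zeros((2, 2))
    s_n = np.cov(np.vstack([va_n, vb_n])) if n > 1 else np.zeros((2, 2))
    var = (
        (s_p[0, 0] + s_p[1, 1] - 2 * s_p[0, 1]) / m
        + (s_n[0, 0] + s_n[1, 1] - 2 * s_n[0, 1]) / n
    )
    diff = roc_a.auc - roc_b.auc
    if diff == 0 or var <= 0:
        return 0.0, 1.0
    z = diff / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))
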