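"""Survival analysis: Kaplan-Meier, log-rank, Cox PH, optimal-cutoff
dichotomization and the nonparametric association tests.

The Cox model follows the Model -> fit() -> Results pattern:

>>> model = CoxPHModel(df, "ttr_time", "ttr_event",
...                    covariates=["neoantigen_load"],
...                    unit_scales={"neoantigen_load": 1000})
>>> res = model.fit()
>>> res.summary()          # hazard ratios per stated unit, 95% CI, Wald p

Hazard ratios are reported per the stated unit increase (e.g. per 1000
neoantigens), matching how such effect sizes are tabulated clinically.

The optimal-cutoff scan reproduces the minimum-log-rank-p dichotomization
popularised by Cutoff Finder.  The returned p-value is the uncorrected
minimum over all admissible cutpoints and is therefore optimistic; the full
profile is returned so users can apply corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "KMCurve", "km_estimate", "logrank_test", "CoxPHModel", "CoxPHResults",
    "CutoffResult", "optimal_cutoff", "spearman", "mann_whitney",
    "kruskal_wallis",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times < 0):
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(timeline).to_numpy(dtype=float)
    return KMCurve(
        timeline=timeline,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(times[~events]),
    )


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def logrank_test(
    times: Sequence[float],
    events: Sequence[bool],
    group: Sequence[int],
) -> Tuple[float, float]:
    """Two-group log-rank test; returns (chi-square on 1 df, p).

    Standard (O - E)^2 / V with the hypergeometric variance at each distinct
    event time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {labels.size}")
    g1 = group == labels[1]
    o_minus_e, var = _logrank_terms(times, events, g1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _logrank_terms(
    times: np.ndarray, events: np.ndarray, g1: np.ndarray
) -> Tuple[float, float]:
    event_times = np.unique(times[events])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & g1).sum()
        if n <= 1:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o_minus_e), float(var)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxPHResults:
    """Estimates from a fitted Cox PH model, on the per-unit scale declared
    by the model's ``unit_scales``."""

    covariates: List[str]
    coefs: np.ndarray
    se: np.ndarray
    unit_scales: Dict[str, float]
    ties: str
    n: int
    n_events: int
    alpha: float = 0.05
    converged: bool = True

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefs)

    @property
    def conf_int(self) -> np.ndarray:
        z = stats.norm.ppf(1 - self.alpha / 2)
        return np.column_stack(
            [np.exp(self.coefs - z * self.se), np.exp(self.coefs + z * self.se)]
        )

    @property
    def p_values(self) -> np.ndarray:
        z = self.coefs / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int
        return pd.DataFrame(
            {
                "unit": [self.unit_scales.get(c, 1.0) for c in self.covariates],
                "coef": self.coefs,
                "HR": self.hazard_ratios,
                "HR_lower95": ci[:, 0],
                "HR_upper95": ci[:, 1],
                "p": self.p_values,
            },
            index=pd.Index(self.covariates, name="variable"),
        )


class CoxPHModel:
    """Cox proportional-hazards model on a patient-level DataFrame.

    Parameters
    ----------
    data : DataFrame with duration, event and covariate columns.
    duration_col, event_col : endpoint column names (e.g. TTR or RFS).
    covariates : columns entering the linear predictor.  Categorical
        columns are not auto-encoded; pass indicator columns.
    unit_scales : covariate -> unit size; hazard ratios are reported per
        that many units (e.g. ``{"neoantigen_load": 1000}`` reports the HR
        per 1000-neoantigen increase).
    ties : ``"efron"`` (default) or ``"breslow"``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        duration_col: str,
        event_col: str,
        covariates: Sequence[str],
        unit_scales: Optional[Dict[str, float]] = None,
        ties: str = "efron",
    ) -> None:
        if ties not in {"efron", "breslow"}:
            raise ValueError("ties must be 'efron' or 'breslow'")
        self.data = data
        self.duration_col = duration_col
        self.event_col = event_col
        self.covariates = list(covariates)
        self.unit_scales = dict(unit_scales or {})
        self.ties = ties
        X = data[self.covariates].astype(float)
        if (X.nunique() <= 1).any():
            bad = list(X.columns[X.nunique() <= 1])
            raise ValueError(f"constant covariates: {bad}")
        if not data[event_col].astype(bool).any():
            raise ValueError("no events in the data")

    def fit(self, tol: float = 1e-9, maxiter: int = 100) -> CoxPHResults:
        X = self.data[self.covariates].astype(float).to_numpy()
        # optimize on sd-standardised covariates (well-conditioned), then
        # report per the declared unit scales
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        model = sm.PHReg(
            self.data[self.duration_col].astype(float).to_numpy(),
            X / sd,
            status=self.data[self.event_col].astype(int).to_numpy(),
            ties=self.ties,
        )
        with warnings.catch_warnings():
            # PHReg's line search probes extreme betas on small samples, and
            # BFGS can stall just above the very tight gradient tolerance;
            # the converged flag is recorded and estimates are checked for
            # finiteness below
            warnings.simplefilter("ignore")
            res = model.fit(method="bfgs", gtol=tol, maxiter=maxiter,
                            disp=False)
        retvals = getattr(res, "mle_retvals", None) or {}
        converged = bool(retvals.get("converged", True))
        units = np.array(
            [self.unit_scales.get(c, 1.0) for c in self.covariates]
        )
        coefs = np.asarray(res.params, dtype=float) / sd * units
        se = np.asarray(res.bse, dtype=float) / sd * units
        if not np.all(np.isfinite(coefs)) or not np.all(np.isfinite(se)):
            raise RuntimeError("Cox fit failed to converge to finite estimates")
        return CoxPHResults(
            covariates=self.covariates,
            coefs=coefs,
            se=se,
            unit_scales=self.unit_scales,
            ties=self.ties,
            n=len(self.data),
            n_events=int(self.data[self.event_col].astype(bool).sum()),
            converged=converged,
        )


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    unit_scales: Optional[Dict[str, float]] = None,
    ties: str = "efron",
) -> CoxPHResults:
    """Convenience wrapper: build a :class:`CoxPHModel` and fit it."""
    return CoxPHModel(
        data, duration_col, event_col, covariates, unit_scales, ties
    ).fit()


def cox_partial_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    ties: str = "efron",
) -> float:
    """Cox partial log-likelihood at a given coefficient vector.

    Used as an independent check of the fitter (e.g. grid maximisation);
    Efron and Breslow tie corrections supported.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(times[events.astype(bool)]):
        dead = (times == t) & events.astype(bool)
        risk = times >= t
        d = int(dead.sum())
        sum_dead = eta[dead].sum()
        risk_sum = w[risk].sum()
        dead_sum = w[dead].sum()
        if ties == "breslow":
            ll += sum_dead - d * np.log(risk_sum)
        else:
            ll += sum_dead - sum(
                np.log(risk_sum - (j / d) * dead_sum) for j in range(d)
            )
    return float(ll)


# ---------------------------------------------------------------------------
# optimal cutoff (Cutoff Finder style)
# ---------------------------------------------------------------------------

@dataclass
class CutoffResult:
    """Minimum-p dichotomization of a continuous marker.

    ``p_value`` is the uncorrected minimum over the scanned profile and is
    optimistic (selection over cutpoints); interpret accordingly.
    """

    cutoff: float
    chi2: float
    p_value: float
    n_low: int
    n_high: int
    profile: pd.DataFrame  # columns: cutoff, chi2, p, n_low, n_high

    def groups(self, values: Sequence[float]) -> np.ndarray:
        """'high'/'low' labels for new values under the optimal cutoff."""
        v = np.asarray(values, dtype=float)
        return np.where(v > self.cutoff, "high", "low")


def optimal_cutoff(
    values: Sequence[float],
    times: Sequence[float],
    events: Sequence[bool],
    min_group_frac: float = 0.1,
) -> CutoffResult:
    """Scan midpoints between consecutive distinct values; return the cutoff
    minimising the log-rank p, subject to both groups holding at least
    ``min_group_frac`` of the patients.  Ties in p resolve to the smallest
    cutoff."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValueError("marker is constant; no cutoff exists")
    n = values.size
    floor = min_group_frac * n
    rows = []
    for cut in (distinct[:-1] + distinct[1:]) / 2.0:
        hi = values > cut
        n_hi = int(hi.sum())
        if n_hi < floor or (n - n_hi) < floor:
            continue
        chi2, p = logrank_test(times, events, hi.astype(int))
        rows.append((cut, chi2, p, n - n_hi, n_hi))
    if not rows:
        raise ValueError(
            f"no admissible cutoff with min_group_frac={min_group_frac}"
        )
    profile = pd.DataFrame(rows, columns=["cutoff", "chi2", "p", "n_low", "n_high"])
    i = int(profile["p"].idxmin())
    best = profile.loc[i]
    return CutoffResult(
        cutoff=float(best["cutoff"]),
        chi2=float(best["chi2"]),
        p_value=float(best["p"]),
        n_low=int(best["n_low"]),
        n_high=int(best["n_high"]),
        profile=profile,
    )


# ---------------------------------------------------------------------------
# nonparametric association tests
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation (tie-corrected); requires n >= 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test for a two-group comparison."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)


def kruskal_wallis(*groups: Sequence[float]) -> Tuple[float, float]:
    """Kruskal-Wallis H test (tie-corrected) for >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
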