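"""Model evaluation: Harrell's C-index, median-risk stratification,
log-rank group separation and chi-square clinical association.

The C-index is the fraction of permissible patient pairs whose predicted
risks order the same way as their survival times (0.5 = random, 1 =
perfect).  A pair (i, j) is permissible when the patient with the shorter
time had an event — either T_i < T_j with E_i = 1, or T_i = T_j with
exactly one event (the event patient counted as failing first).  Tied
predicted risks contribute 0.5.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .cohort_io import SurvivalTable
from .deep_cox import RiskScores

logger = logging.getLogger("atrcn")


@dataclass
class RiskGroups:
    sample_ids: list[str]
    group: np.ndarray     # "high" / "low" per sample
    threshold: float      # the median risk used for the split

    @property
    def high_mask(self) -> np.ndarray:
        return self.group == "high"


@dataclass
class EvaluationReport:
    c_index: float
    logrank_p: float
    logrank_statistic: float
    risk_groups: RiskGroups
    per_fold_c: list[float] = field(default_factory=list)
    covariate_tests: list[tuple[str, float, float, int]] = field(default_factory=list)

    @property
    def cv_mean_c(self) -> float:
        return float(np.mean(self.per_fold_c)) if self.per_fold_c else self.c_index

    @property
    def cv_sd_c(self) -> float:
        return float(np.std(self.per_fold_c, ddof=1)) if len(self.per_fold_c) > 1 else 0.0

    def to_json(self, path: str) -> None:
        payload = {
            "c_index": self.c_index,
            "per_fold_c": self.per_fold_c,
            "cv_mean_c": self.cv_mean_c,
            "cv_sd_c": self.cv_sd_c,
            "logrank_statistic": self.logrank_statistic,
            "logrank_p": self.logrank_p,
            "risk_threshold": self.risk_groups.threshold,
            "risk_groups": {
                s: g for s, g in zip(self.risk_groups.sample_ids, self.risk_groups.group)
            },
            "covariate_tests": [
                {"covariate": c, "statistic": x2, "p": p, "df": df}
                for c, x2, p, df in self.covariate_tests
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def concordance_index(scores: RiskScores | np.ndarray, s: SurvivalTable) -> float:
    """Harrell's C over all permissible ordered pairs (vectorized)."""
    vec = scores.score if isinstance(scores, RiskScores) else np.asarray(scores, dtype=float)
    if vec.shape[0] != s.n_samples:
        raise ValueError("scores not aligned with survival table")
    t, e = s.time, s.event.astype(bool)
    # permissible[i, j]: i fails observably before j
    earlier = t[:, None] < t[None, :]
    tied_time = t[:, None] == t[None, :]
    perm = (earlier & e[:, None]) | (tied_time & e[:, None] & ~e[None, :])
    n_perm = perm.sum()
    if n_perm == 0:
        raise ValueError("no permissible pairs (cannot compute C-index)")
    higher = vec[:, None] > vec[None, :]
    tied_score = vec[:, None] == vec[None, :]
    weight = (perm & higher).sum() + 0.5 * (perm & tied_score).sum()
    return float(weight / n_perm)


# ---------------------------------------------------------------------------
# risk stratification and group tests
# ---------------------------------------------------------------------------

def median_split(scores: RiskScores) -> RiskGroups:
    """Split at the median predicted risk: score > median is high risk.

    Scores exactly at the median go to the low-risk group, guaranteeing a
    nonempty high-risk group whenever scores are not all identical.
    """
    if len(scores.sample_ids) < 2:
        raise ValueError("median split needs at least 2 samples")
    med = float(np.median(scores.score))
    if np.all(scores.score == scores.score[0]):
        raise ValueError("all risk scores identical: no median split possible")
    group = np.where(scores.score > med, "high", "low")
    return RiskGroups(list(scores.sample_ids), group, med)


def logrank_test(groups: RiskGroups, s: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    high = groups.high_mask
    if high.all() or not high.any():
        raise ValueError("both risk groups must be nonempty")
    if s.n_events == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(
        s.time[high], s.time[~high], s.event[high], s.event[~high]
    )
    return float(res.test_statistic), float(res.p_value)


def chisq_association(
    groups: RiskGroups,
    covariate: pd.Series | np.ndarray,
    quartile_bin: bool | None = None,
) -> tuple[float, float, int]:
    """Pearson chi-square between risk group and a clinical covariate.

    Continuous covariates are binned into quartile intervals
    (<25%, 25–50%, 50–75%, >75%) first; ``quartile_bin`` forces or
    suppresses the binning, otherwise numeric dtype decides.  Categories
    with a zero margin are dropped with a warning.  Returns
    (statistic, p, degrees of freedom).
    """
    cov = pd.Series(np.asarray(covariate), name="covariate")
    if len(cov) != len(groups.sample_ids):
        raise ValueError("covariate not aligned with risk groups")
    numeric = pd.api.types.is_numeric_dtype(cov)
    if quartile_bin is None:
        quartile_bin = numeric and cov.nunique() > 4
    if quartile_bin:
        if not numeric:
            raise ValueError("quartile binning requires a numeric covariate")
        cov = pd.qcut(cov, q=4, duplicates="drop")
    table = pd.crosstab(pd.Series(groups.group, name="risk"), cov)
    empty = table.columns[(table.sum(axis=0) == 0)]
    if len(empty):
        logger.warning("dropping zero-margin covariate categories: %s", list(empty))
        table = table.drop(columns=empty)
    if table.shape[1] < 2:
        raise ValueError("fewer than 2 nonempty covariate categories")
    stat, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(stat), float(p), int(df)


def evaluate_risk_scores(
    scores: RiskScores,
    s: SurvivalTable,
    per_fold_c: list[float] | None = None,
    covariates: pd.DataFrame | None = None,
) -> EvaluationReport:
    """Full report: C-index, median-split log-rank, covariate chi-squares."""
    c = concordance_index(scores, s)
    groups = median_split(scores)
    stat, p = logrank_test(groups, s)
    cov_tests = []
    if covariates is not None:
        for col in covariates.columns:
            try:
                x2, pc, df = chisq_association(groups, covariates[col])
            except ValueError as exc:
                logger.warning("skipping covariate %r: %s", col, exc)
                continue
            cov_tests.append((str(col), x2, pc, df))
    return EvaluationReport(c, p, stat, groups, per_fold_c or [], cov_tests)


def plot_km_by_group(groups: RiskGroups, s: SurvivalTable, path: str) -> None:
    """Kaplan–Meier curves of the high- and low-risk groups."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, mask in (("high risk", groups.high_mask), ("low risk", ~groups.high_mask)):
        kmf = KaplanMeierFitter()
        kmf.fit(s.time[mask], s.event[mask], label=label)
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
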