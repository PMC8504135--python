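"""Cohort descriptors: 12 phenotype + 10 genotype summary features.

Each cohort is characterized by a 22-number vector:

* phenotype — survival statistics of the cohort: Kaplan–Meier 3- and 5-year
  survival rates (Y3, Y5), mean and SD of observed time (SAVE, STD),
  time quartiles and maximum (T1..T4), and the fractions of patients whose
  observed time falls in the four equal subdivisions of [0, T4] (S1..S4);
* genotype — the expression matrix is compressed to two kernel-PCA
  components (Fe1, Fe2; rbf kernel) and each component is summarized by its
  mean, median, SD, excess kurtosis and skewness.

Stacking the vectors of several cohorts and z-scoring each feature column
yields the normalized descriptor matrix on which cohorts are clustered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sklearn.decomposition import KernelPCA

from .cohort_io import Cohort, ExpressionMatrix, SurvivalTable

logger = logging.getLogger("atrcn")

PHENOTYPE_FEATURES = (
    "Y3", "Y5", "SAVE", "STD", "T1", "T2", "T3", "T4", "S1", "S2", "S3", "S4",
)
GENOTYPE_FEATURES = (
    "AVE1", "MID1", "STD1", "KURT1", "SKEW1",
    "AVE2", "MID2", "STD2", "KURT2", "SKEW2",
)
FEATURE_NAMES = PHENOTYPE_FEATURES + GENOTYPE_FEATURES


@dataclass
class CompressedExpression:
    """Per-sample coordinates on the top-2 kernel principal components."""

    sample_ids: list[str]
    fe1: np.ndarray
    fe2: np.ndarray


@dataclass
class DescriptorVector:
    cohort_name: str
    phenotype: dict[str, float]
    genotype: dict[str, float]

    def as_array(self) -> np.ndarray:
        vals = [self.phenotype[f] for f in PHENOTYPE_FEATURES]
        vals += [self.genotype[f] for f in GENOTYPE_FEATURES]
        return np.array(vals, dtype=float)


@dataclass
class DescriptorMatrix:
    cohort_names: list[str]
    raw: np.ndarray          # cohorts x 22
    normalized: np.ndarray   # per-feature z-scores; constant columns -> 0
    center: np.ndarray
    scale: np.ndarray

    def to_frame(self, normalized: bool = True) -> pd.DataFrame:
        data = self.normalized if normalized else self.raw
        return pd.DataFrame(data, index=self.cohort_names, columns=list(FEATURE_NAMES))

    def write_tsv(self, path: str, normalized: bool = True) -> None:
        self.to_frame(normalized).to_csv(path, sep="\t", index_label="cohort")


# ---------------------------------------------------------------------------
# genotype side: KPCA compression + moment summaries
# ---------------------------------------------------------------------------

def kpca_compress(
    m: ExpressionMatrix,
    kernel: str = "rbf",
    n_components: int = 2,
    gamma: float | None = None,
) -> CompressedExpression:
    """Project samples onto the top kernel principal components.

    Samples are the observations (genes are the kernel features); ``gamma``
    defaults to 1/n_genes.  The sign of each component is fixed so that its
    largest-magnitude coordinate is positive, making descriptors
    reproducible across runs and platforms.
    """
    if m.n_samples < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} samples for {n_components} components"
        )
    if np.isnan(m.values).any():
        raise ValueError("expression matrix must be imputed before KPCA")
    x = m.values.T  # samples x genes
    if gamma is None and kernel == "rbf":
        gamma = 1.0 / m.n_genes
    kp = KernelPCA(n_components=n_components, kernel=kernel, gamma=gamma)
    coords = kp.fit_transform(x)
    # deterministic sign convention
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    return CompressedExpression(list(m.sample_ids), coords[:, 0], coords[:, 1])


def _moments(v: np.ndarray) -> tuple[float, float, float, float, float]:
    """mean, median, sd (n-1), excess kurtosis, skewness — plain moment estimators."""
    mean = float(np.mean(v))
    med = float(np.median(v))
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        logger.warning("constant KPCA component: kurtosis/skewness reported as 0")
        return mean, med, 0.0, 0.0, 0.0
    c = v - mean
    m2 = float(np.mean(c ** 2))
    skew = float(np.mean(c ** 3)) / m2 ** 1.5
    kurt = float(np.mean(c ** 4)) / m2 ** 2 - 3.0
    return mean, med, sd, kurt, skew


def genotype_features(c: CompressedExpression) -> dict[str, float]:
    """Moment summaries (mean/median/SD/excess kurtosis/skewness) of Fe1, Fe2."""
    if len(c.sample_ids) < 4:
        raise ValueError("genotype features require at least 4 samples")
    out: dict[str, float] = {}
    for i, comp in enumerate((c.fe1, c.fe2), start=1):
        ave, mid, sd, kurt, skew = _moments(np.asarray(comp, dtype=float))
        out[f"AVE{i}"] = ave
        out[f"MID{i}"] = mid
        out[f"STD{i}"] = sd
        out[f"KURT{i}"] = kurt
        out[f"SKEW{i}"] = skew
    return out


# ---------------------------------------------------------------------------
# phenotype side: survival summaries
# ---------------------------------------------------------------------------

def phenotype_features(
    s: SurvivalTable,
    unit_scale: float = 1.0,
    survival_rate_estimator: str = "km",
) -> dict[str, float]:
    """Twelve survival summaries of one cohort.

    ``unit_scale`` converts stored time units to years (365.25 for days, 12
    for months, 1 if times are already in years); only Y3/Y5 depend on it.
    Y3/Y5 default to the Kaplan–Meier estimate of S(t) at the 3- and 5-year
    horizons (clamped to the last observed time when follow-up is shorter);
    ``survival_rate_estimator="naive"`` instead uses the fraction of
    patients with observed time past the horizon.  SAVE/STD/T1..T4/S1..S4
    are computed over the observed times of all patients, censored included.
    The four S intervals are half-open (lo, hi]; survival times are strictly
    positive, so the intervals partition the patients — times 1, 2, 3, 4
    give S1 = S2 = S3 = S4 = 0.25.
    """
    if s.n_samples < 4:
        raise ValueError("phenotype features require at least 4 samples")
    if unit_scale <= 0:
        raise ValueError("unit_scale must be positive")
    t = s.time
    t_years = t / unit_scale

    if survival_rate_estimator == "km":
        if s.n_events == 0:
            logger.warning("all-censored cohort: KM survival rate is 1 before last time")
        kmf = KaplanMeierFitter()
        kmf.fit(t_years, s.event)
        last = t_years.max()
        y3 = float(kmf.predict(min(3.0, last)))
        y5 = float(kmf.predict(min(5.0, last)))
    elif survival_rate_estimator == "naive":
        y3 = float(np.mean(t_years > 3.0))
        y5 = float(np.mean(t_years > 5.0))
    else:
        raise ValueError(f"unknown survival_rate_estimator {survival_rate_estimator!r}")

    t4 = float(t.max())
    q1, q2, q3 = (float(np.quantile(t, q)) for q in (0.25, 0.5, 0.75))
    lower = np.array([0.0, 0.25, 0.5, 0.75]) * t4
    upper = np.array([0.25, 0.5, 0.75, 1.0]) * t4
    s_frac = [float(np.mean((t > lo) & (t <= hi))) for lo, hi in zip(lower, upper)]

    return {
        "Y3": y3, "Y5": y5,
        "SAVE": float(np.mean(t)), "STD": float(np.std(t, ddof=1)),
        "T1": q1, "T2": q2, "T3": q3, "T4": t4,
        "S1": s_frac[0], "S2": s_frac[1], "S3": s_frac[2], "S4": s_frac[3],
    }


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def describe_cohort(
    c: Cohort,
    unit_scale: float | None = None,
    kernel: str = "rbf",
    gamma: float | None = None,
    survival_rate_estimator: str = "km",
) -> DescriptorVector:
    """Compute the full 22-feature descriptor of one cohort."""
    if unit_scale is None:
        unit_scale = {"days": 365.25, "months": 12.0, "years": 1.0}.get(c.time_unit, 1.0)
    pheno = phenotype_features(c.survival, unit_scale, survival_rate_estimator)
    comp = kpca_compress(c.expression, kernel=kernel, gamma=gamma)
    geno = genotype_features(comp)
    return DescriptorVector(c.name, pheno, geno)


def build_descriptor_matrix(vectors: list[DescriptorVector]) -> DescriptorMatrix:
    """Stack descriptor vectors and z-score each feature across cohorts.

    Constant feature columns are mapped to all zeros rather than dividing
    by a zero scale.
    """
    if len(vectors) < 2:
        raise ValueError("descriptor matrix needs at least 2 cohorts")
    raw = np.vstack([v.as_array() for v in vectors])
    for r, v in zip(raw, vectors):
        if not np.isfinite(r).all():
            bad = FEATURE_NAMES[int(np.flatnonzero(~np.isfinite(r))[0])]
            raise ValueError(f"non-finite descriptor {bad!r} for cohort {v.cohort_name!r}")
    center = raw.mean(axis=0)
    scale = raw.std(axis=0)
    safe = np.where(scale == 0, 1.0, scale)
    normalized = (raw - center) / safe
    normalized[:, scale == 0] = 0.0
    return DescriptorMatrix(
        [v.cohort_name for v in vectors], raw, normalized, center, scale
    )
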