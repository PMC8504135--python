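"""Reading, validation, preprocessing and harmonization of survival cohorts.

A *cohort* pairs a gene-expression matrix (genes x samples) with a survival
table (one row per sample: observed time, event indicator, optional
categorical clinical covariates).  All downstream stages — descriptor
construction, cohort selection, network training — consume :class:`Cohort`
objects produced here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("atrcn")

#: cell tokens treated as missing when parsing expression files
MISSING_TOKENS = ("NA", "", "nan", "NaN", "NULL")

#: accepted spellings of the event indicator
EVENT_MAP = {
    "0": 0, "1": 1, "false": 0, "true": 1,
    "alive": 0, "dead": 1, "censored": 0, "event": 1,
}


class CohortValidationError(ValueError):
    """A cohort file or object violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix; entries may be NaN before preprocessing."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_genes, n_samples), float64, NaN = missing
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CohortValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise CohortValidationError(f"duplicate {label} id: {i!r}")
                seen.add(i)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SurvivalTable:
    """Observed time, event indicator and optional categorical covariates."""

    sample_ids: list[str]
    time: np.ndarray    # positive reals, consistent unit within a cohort
    event: np.ndarray   # 1 = event observed (uncensored), 0 = censored
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise CohortValidationError("time/event length mismatch with sample_ids")
        if len(set(self.sample_ids)) != n:
            raise CohortValidationError("duplicate sample ids in survival table")
        bad = np.flatnonzero(~(self.time > 0))
        if bad.size:
            raise CohortValidationError(
                f"nonpositive survival time for sample {self.sample_ids[bad[0]]!r}"
            )
        if not np.isin(self.event, (0, 1)).all():
            raise CohortValidationError("event indicator outside {0,1}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalTable":
        cov = self.covariates.iloc[idx].reset_index(drop=True) if self.covariates is not None else None
        return SurvivalTable(
            [self.sample_ids[i] for i in idx], self.time[idx], self.event[idx], cov
        )


@dataclass
class Cohort:
    """One named dataset: expression matrix + aligned survival table."""

    name: str
    expression: ExpressionMatrix
    survival: SurvivalTable
    family: int | None = None       # planted family label for synthetic studies
    time_unit: str = "days"

    def __post_init__(self) -> None:
        if self.expression.n_samples < 2:
            raise CohortValidationError(f"cohort {self.name!r}: fewer than 2 samples")
        if set(self.expression.sample_ids) != set(self.survival.sample_ids):
            raise CohortValidationError(
                f"cohort {self.name!r}: expression and survival sample ids differ"
            )
        # align survival row order to expression column order
        if self.expression.sample_ids != self.survival.sample_ids:
            pos = {s: i for i, s in enumerate(self.survival.sample_ids)}
            order = np.array([pos[s] for s in self.expression.sample_ids])
            self.survival = self.survival.subset(order)

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples

    @property
    def n_uncensored(self) -> int:
        return self.survival.n_events


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_expression(path: str, sep: str | None = None) -> ExpressionMatrix:
    """Parse a TSV/CSV expression file: first column gene ids, header sample ids.

    Missing-value tokens ("NA", "", "nan", ...) become NaN, never zero.
    """
    sep = sep or _sniff_sep(str(path))
    try:
        df = pd.read_csv(
            path, sep=sep, index_col=0, na_values=list(MISSING_TOKENS),
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise CohortValidationError(f"cannot parse expression file {path}: {exc}") from exc
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise CohortValidationError(f"duplicate gene id: {dup[0]!r}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
    )


def read_survival(path: str, sep: str | None = None) -> SurvivalTable:
    """Parse a survival CSV with mandatory columns sample_id, time, event.

    The event column accepts 0/1, TRUE/FALSE and dead/alive spellings; any
    extra column is retained as a categorical covariate.
    """
    sep = sep or _sniff_sep(str(path))
    df = pd.read_csv(path, sep=sep)
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise CohortValidationError(f"survival table missing column {col!r}")

    def coerce_event(v: object) -> int:
        key = str(v).strip().lower()
        if key in EVENT_MAP:
            return EVENT_MAP[key]
        raise CohortValidationError(f"unrecognized event value {v!r}")

    event = np.array([coerce_event(v) for v in df["event"]])
    extra = [c for c in df.columns if c not in ("sample_id", "time", "event")]
    covariates = df[extra].astype("object").reset_index(drop=True) if extra else None
    return SurvivalTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        time=df["time"].to_numpy(dtype=float),
        event=event,
        covariates=covariates,
    )


def load_cohort(name: str, expression_path: str, survival_path: str, **kw) -> Cohort:
    return Cohort(name, read_expression(expression_path), read_survival(survival_path), **kw)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_expression(
    m: ExpressionMatrix,
    missing_gene_frac: float = 0.20,
    log_transform: bool = True,
) -> ExpressionMatrix:
    """Drop sparse genes, median-impute the rest, optionally log2(v+1).

    Genes with a missing fraction *strictly greater* than
    ``missing_gene_frac`` are removed (exactly at the threshold they are
    kept); remaining missing entries are replaced by that gene's median over
    observed samples.  The log transform uses a pseudocount of 1 so zero
    stays zero, and is recorded on the output so repeated preprocessing is
    idempotent.
    """
    if not 0 <= missing_gene_frac <= 1:
        raise ValueError("missing_gene_frac must lie in [0, 1]")
    vals = m.values.copy()
    missing = np.isnan(vals)
    keep = missing.mean(axis=1) <= missing_gene_frac
    if not keep.any():
        raise CohortValidationError("all genes exceed the missing-value threshold")
    vals = vals[keep]
    gene_ids = [g for g, k in zip(m.gene_ids, keep) if k]
    miss = np.isnan(vals)
    if miss.any():
        med = np.nanmedian(vals, axis=1, keepdims=True)
        vals = np.where(miss, med, vals)
    do_log = log_transform and not m.log_transformed
    if do_log:
        if (vals < 0).any():
            raise CohortValidationError("negative expression value under log transform")
        vals = np.log2(vals + 1.0)
    return ExpressionMatrix(
        gene_ids, list(m.sample_ids), vals,
        log_transformed=m.log_transformed or do_log,
    )


def preprocess_cohort(c: Cohort, **kw) -> Cohort:
    return replace(c, expression=preprocess_expression(c.expression, **kw))


# ---------------------------------------------------------------------------
# cohort-level filters and harmonization
# ---------------------------------------------------------------------------

def filter_candidate_cohorts(
    cohorts: list[Cohort],
    min_uncensored: int = 50,
    min_samples: int = 100,
) -> list[Cohort]:
    """Keep cohorts with uncensored count > min_uncensored AND n > min_samples.

    Both inequalities are strict; input order is preserved.
    """
    kept = [
        c for c in cohorts
        if c.n_uncensored > min_uncensored and c.n_samples > min_samples
    ]
    if not kept:
        logger.warning(
            "no cohort passes the candidate filter (>%d uncensored, >%d samples)",
            min_uncensored, min_samples,
        )
    return kept


def harmonize_genes(cohorts: list[Cohort]) -> list[Cohort]:
    """Restrict every cohort to the shared genes, in identical order."""
    if not cohorts:
        raise ValueError("harmonize_genes requires at least one cohort")
    shared = set(cohorts[0].expression.gene_ids)
    for c in cohorts[1:]:
        shared &= set(c.expression.gene_ids)
    if not shared:
        raise CohortValidationError("cohorts share no genes")
    # deterministic order: first cohort's ordering restricted to the intersection
    order = [g for g in cohorts[0].expression.gene_ids if g in shared]
    out = []
    for c in cohorts:
        pos = {g: i for i, g in enumerate(c.expression.gene_ids)}
        idx = np.array([pos[g] for g in order])
        expr = ExpressionMatrix(
            order, list(c.expression.sample_ids), c.expression.values[idx],
            log_transformed=c.expression.log_transformed,
        )
        out.append(replace(c, expression=expr))
    return out
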