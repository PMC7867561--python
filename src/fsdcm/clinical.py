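"""PANSS-8 clinical table: validation, composites, and the PEB design matrices.

The study cohort is 19 first-episode psychosis subjects rated on the 8-item
Positive and Negative Syndrome Scale (P1 delusions, P2 conceptual
disorganization, P3 hallucinations, N1 blunted affect, N4 social withdrawal,
N6 lack of spontaneity, G5 mannerisms, G9 unusual thoughts), with a binary
antipsychotic-exposure flag and duration of untreated psychosis (DUP, months)
as nuisance covariates.  The group-level (PEB) model space regresses the four
effective-connectivity parameters on one symptom covariate at a time; this
module builds those design matrices.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PANSSRecord",
    "CompositeScores",
    "DesignMatrix",
    "PairedTestResult",
    "MODEL_LABELS",
    "ClinicalValidationError",
    "load_panss",
    "packaged_clinical_table",
    "packaged_explained_variance",
    "packaged_group_free_energies",
    "composite_scores",
    "paired_difference_test",
    "build_design_matrix",
    "model_space",
]

log = logging.getLogger(__name__)

ITEM_NAMES = ("p1", "p2", "p3", "n1", "n4", "n6", "g5", "g9")

#: The nine second-level models: one symptom covariate each, plus a null
#: (intercept-only) model representing no symptom/connectivity association.
MODEL_LABELS = (
    "delusions",
    "disorganization",
    "hallucinations",
    "total positive",
    "blunted affect",
    "social withdrawal",
    "lack of spontaneity",
    "total negative",
    "null",
)

_MODEL_COVARIATES = {
    "delusions": ("p1",),
    "disorganization": ("p2",),
    "hallucinations": ("p3",),
    "total positive": ("p1", "p2", "p3"),
    "blunted affect": ("n1",),
    "social withdrawal": ("n4",),
    "lack of spontaneity": ("n6",),
    "total negative": ("n1", "n4", "n6"),
}


class ClinicalValidationError(ValueError):
    """Raised when a clinical table violates the PANSS-8 contract."""


@dataclass(frozen=True)
class PANSSRecord:
    """One subject's PANSS-8 item scores and nuisance covariates."""

    subject_id: str
    p1: int
    p2: int
    p3: int
    n1: int
    n4: int
    n6: int
    g5: int
    g9: int
    medication: int
    dup_months: float | None

    def __post_init__(self) -> None:
        for name in ITEM_NAMES:
            score = getattr(self, name)
            if not (1 <= int(score) <= 7):
                raise ClinicalValidationError(
                    f"subject {self.subject_id}: item {name.upper()} score "
                    f"{score} outside the PANSS range [1, 7]"
                )
        if int(self.medication) not in (0, 1):
            raise ClinicalValidationError(
                f"subject {self.subject_id}: medication flag must be 0/1"
            )
        if self.dup_months is not None and self.dup_months < 0:
            raise ClinicalValidationError(
                f"subject {self.subject_id}: negative DUP {self.dup_months}"
            )

    @property
    def items(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in ITEM_NAMES], dtype=float)


@dataclass(frozen=True)
class CompositeScores:
    total_positive: int
    total_negative: int
    panss8_total: int


@dataclass(frozen=True)
class DesignMatrix:
    """Between-subject design: rows = subjects, named columns, ones first."""

    name: str
    values: np.ndarray
    columns: tuple[str, ...]
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.values, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.columns):
            raise ValueError("design shape does not match column names")
        if not np.allclose(X[:, 0], 1.0):
            raise ValueError("first design column must be all ones")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns),
                            index=list(self.subject_ids))


@dataclass(frozen=True)
class PairedTestResult:
    mean_diff: float
    sd_diff: float
    t_stat: float | None
    df: int
    ci_low: float | None
    ci_high: float | None
    p_value: float | None

    @property
    def degenerate(self) -> bool:
        """True when the differences had zero variance (t undefined)."""
        return self.t_stat is None


def _records_from_frame(df: pd.DataFrame, source: str) -> list[PANSSRecord]:
    required = {"subject_id", *ITEM_NAMES, "medication", "dup_months"}
    missing = required - set(df.columns)
    if missing:
        raise ClinicalValidationError(
            f"{source}: missing required columns {sorted(missing)}"
        )
    if df.empty:
        raise ClinicalValidationError(f"{source}: table contains no subjects")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)  # keep rows object-typed
    ids = df["subject_id"]
    dupes = ids[ids.duplicated()].tolist()
    if dupes:
        raise ClinicalValidationError(f"{source}: duplicate subject_id {dupes}")
    records = []
    for _, row in df.iterrows():
        dup = row["dup_months"]
        dup = None if pd.isna(dup) else float(dup)
        if dup is None:
            log.info("subject %s: DUP missing (flagged, not dropped)",
                     row["subject_id"])
        records.append(PANSSRecord(
            subject_id=str(row["subject_id"]),
            **{n: int(row[n]) for n in ITEM_NAMES},
            medication=int(row["medication"]),
            dup_months=dup,
        ))
    return records


def load_panss(table_path: str | Path) -> list[PANSSRecord]:
    """Load and validate a delimited PANSS-8 table (one row per subject)."""
    path = Path(table_path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise ClinicalValidationError(f"{path}: empty or unreadable file") from exc
    return _records_from_frame(df, str(path))


def _data_path(name: str) -> Path:
    return Path(str(resources.files("fsdcm.data").joinpath(name)))


def packaged_clinical_table(as_records: bool = True):
    """The study's printed clinical table (19 subjects).

    Returns validated records by default, or the raw DataFrame (which also
    carries the printed composite columns) with ``as_records=False``.
    """
    path = _data_path("clinical_panss8.csv")
    if as_records:
        return load_panss(path)
    return pd.read_csv(path)


def packaged_explained_variance() -> pd.DataFrame:
    """Per-subject explained variance (%) of the published first-level fits."""
    return pd.read_csv(_data_path("explained_variance.csv"))


def packaged_group_free_energies() -> pd.DataFrame:
    """Published group-level free energies of the nine symptom models."""
    # keep_default_na: the "null" model label must stay a string
    return pd.read_csv(_data_path("group_free_energy.csv"),
                       keep_default_na=False)


def composite_scores(record: PANSSRecord) -> CompositeScores:
    """Total positive (P1+P2+P3), total negative (N1+N4+N6), PANSS-8 total."""
    pos = record.p1 + record.p2 + record.p3
    neg = record.n1 + record.n4 + record.n6
    return CompositeScores(pos, neg, pos + neg + record.g5 + record.g9)


def paired_difference_test(a: Sequence[float], b: Sequence[float]) -> PairedTestResult:
    """Classical paired t-test with a two-sided 95% t-interval on the mean.

    Zero-variance differences yield a degenerate result (t and CI ``None``)
    rather than an infinite statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        return PairedTestResult(mean, 0.0, None, df, None, None, None)
    se = sd / np.sqrt(n)
    t_stat = mean / se
    q = stats.t.ppf(0.975, df)
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    return PairedTestResult(mean, sd, float(t_stat), df,
                            float(mean - q * se), float(mean + q * se), float(p))


def _covariate_vector(records: Sequence[PANSSRecord], model_name: str) -> np.ndarray:
    items = _MODEL_COVARIATES[model_name]
    return np.array([sum(getattr(r, it) for it in items) for r in records],
                    dtype=float)


def build_design_matrix(records: Sequence[PANSSRecord], model_name: str) -> DesignMatrix:
    """Design matrix for one of the nine group-level models.

    The null model is a single column of ones.  Every other model has four
    columns: [constant, symptom covariate, medication flag, DUP].  Covariates
    are mean-centred so the constant encodes the group-mean connectivity;
    missing DUP is imputed with the within-sample mean before centring (which
    zeroes its net contribution for those subjects).
    """
    if model_name not in MODEL_LABELS:
        raise ValueError(
            f"unknown model {model_name!r}; valid labels: {list(MODEL_LABELS)}"
        )
    ids = tuple(r.subject_id for r in records)
    n = len(records)
    if n < 2:
        raise ValueError("need at least two subjects for a group design")
    ones = np.ones(n)
    if model_name == "null":
        return DesignMatrix("null", ones[:, None], ("constant",), ids)

    cov = _covariate_vector(records, model_name)
    med = np.array([r.medication for r in records], dtype=float)
    dup = np.array([np.nan if r.dup_months is None else r.dup_months
                    for r in records], dtype=float)
    n_missing = int(np.isnan(dup).sum())
    if n_missing:
        fill = float(np.nanmean(dup))
        log.info("imputing %d missing DUP value(s) with sample mean %.2f",
                 n_missing, fill)
        dup = np.where(np.isnan(dup), fill, dup)
    X = np.column_stack([ones, cov - cov.mean(), med - med.mean(),
                         dup - dup.mean()])
    return DesignMatrix(model_name, X,
                        ("constant", model_name, "medication", "dup"), ids)


def model_space(records: Sequence[PANSSRecord]) -> dict[str, DesignMatrix]:
    """All nine design matrices, keyed by model label."""
    return {name: build_design_matrix(records, name) for name in MODEL_LABELS}
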