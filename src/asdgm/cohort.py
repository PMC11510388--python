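"""Clinical metadata handling and neuropsychological stratification.

Subjects in the cohort carry an ADOS-2 Calibrated Severity Score (CSS,
1-10), three CBCL t-scores (Internalizing, Externalizing, Total Problems)
and an IQ or developmental quotient (IQ/DQ).  Each variable induces its own
subgrouping of the cohort:

* CSS        -> {mild_moderate, severe}
* CBCL_*     -> {no_symptoms, at_risk, symptoms}  (t < 60 / 60-63 / >= 64)
* IQ/DQ      -> {cidd, no_cidd}  (cognitive impairment / developmental delay)

Missing scores propagate to a missing label; a subject is never assigned a
default class.  Percentages in summaries are computed over scored subjects
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "StratConfig",
    "ClinicalTable",
    "read_clinical",
    "stratify_cbcl",
    "stratify_css",
    "stratify_iq",
    "stratify",
    "cohort_summary",
    "VARIABLES",
    "LABEL_SETS",
]

#: stratification variables recognised by :func:`stratify`
VARIABLES = ("CSS", "CBCL_INT", "CBCL_EXT", "CBCL_TOT", "IQ_DQ")

#: legal label set per variable
LABEL_SETS: Mapping[str, tuple[str, ...]] = {
    "CSS": ("mild_moderate", "severe"),
    "CBCL_INT": ("no_symptoms", "at_risk", "symptoms"),
    "CBCL_EXT": ("no_symptoms", "at_risk", "symptoms"),
    "CBCL_TOT": ("no_symptoms", "at_risk", "symptoms"),
    "IQ_DQ": ("cidd", "no_cidd"),
}

_SCORE_COLUMN = {
    "CSS": "css",
    "CBCL_INT": "cbcl_int",
    "CBCL_EXT": "cbcl_ext",
    "CBCL_TOT": "cbcl_tot",
    "IQ_DQ": "iq_dq",
}


@dataclass(frozen=True)
class StratConfig:
    """Thresholds for the neuropsychological subgroupings.

    Parameters
    ----------
    cbcl_none_below : float
        CBCL t-scores strictly below this are non-clinical (default 60).
    cbcl_clinical_at : float
        CBCL t-scores at or above this are clinical (default 64); scores in
        between are "at risk".
    css_severe_at : float
        CSS at or above this is severe autism (default 8; the severity
        banding of the calibrated score, exposed because clinical practice
        varies).
    iq_cidd_below : float
        IQ/DQ strictly below this marks cognitive impairment /
        developmental delay (default 70, the conventional clinical cutoff).
    """

    cbcl_none_below: float = 60.0
    cbcl_clinical_at: float = 64.0
    css_severe_at: float = 8.0
    iq_cidd_below: float = 70.0

    def __post_init__(self) -> None:
        if not self.cbcl_none_below < self.cbcl_clinical_at:
            raise ValueError("cbcl_none_below must be < cbcl_clinical_at")
        for name in ("cbcl_none_below", "cbcl_clinical_at", "css_severe_at", "iq_cidd_below"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class ClinicalTable:
    """Per-subject phenotype scores and covariates.

    Wraps a DataFrame indexed by subject id with columns
    ``age, gender, css, cbcl_int, cbcl_ext, cbcl_tot, iq_dq``.  Age and
    gender are required covariates; the score columns may hold missing
    values (NaN).
    """

    REQUIRED = ("age", "gender")
    SCORES = ("css", "cbcl_int", "cbcl_ext", "cbcl_tot", "iq_dq")

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject ids: {dups}")
        for col in self.REQUIRED:
            if col not in data.columns:
                raise ValueError(f"required column '{col}' missing")
            if data[col].isna().any():
                bad = data.index[data[col].isna()].tolist()
                raise ValueError(f"missing {col} for subjects {bad}")
        for col in self.SCORES:
            if col not in data.columns:
                data[col] = np.nan
            data[col] = pd.to_numeric(data[col], errors="coerce")
        data["age"] = pd.to_numeric(data["age"])
        if (data["age"] <= 0).any():
            raise ValueError("ages must be positive")
        bad_gender = set(data["gender"]) - {"male", "female"}
        if bad_gender:
            raise ValueError(f"unrecognised gender values: {sorted(bad_gender)}")
        css = data["css"].dropna()
        if ((css < 1) | (css > 10)).any():
            raise ValueError("CSS values must lie in [1, 10]")
        self.data = data

    @property
    def subject_ids(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)

    def scores(self, variable: str) -> pd.Series:
        """Score series for one stratification variable (missing as NaN)."""
        if variable not in _SCORE_COLUMN:
            raise ValueError(f"unknown variable {variable!r}; expected one of {VARIABLES}")
        return self.data[_SCORE_COLUMN[variable]]


#: default column-name mapping accepted by :func:`read_clinical`
DEFAULT_DIALECT = {
    "subject_id": "subject_id",
    "age": "age",
    "gender": "gender",
    "css": "css",
    "cbcl_int": "cbcl_int",
    "cbcl_ext": "cbcl_ext",
    "cbcl_tot": "cbcl_tot",
    "iq_dq": "iq_dq",
}


def read_clinical(path: str | Path, dialect: Mapping[str, str] | None = None) -> ClinicalTable:
    """Read a delimited clinical table (TSV/CSV by extension).

    ``dialect`` maps canonical field names (keys of ``DEFAULT_DIALECT``) to
    the column names used in the file.  Unparseable numeric cells become
    missing; duplicated subject ids and absent age/gender columns are hard
    errors.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    id_col = mapping["subject_id"]
    if id_col not in raw.columns:
        raise ValueError(f"subject-id column '{id_col}' not found in {path.name}")
    frame = pd.DataFrame(index=pd.Index(raw[id_col], name="subject_id"))
    for canonical in ("age", "gender", "css", "cbcl_int", "cbcl_ext", "cbcl_tot", "iq_dq"):
        col = mapping[canonical]
        if col in raw.columns:
            frame[canonical] = raw[col].values
    if "gender" in frame.columns:
        frame["gender"] = frame["gender"].str.strip().str.lower()
    for col in ("age", "css", "cbcl_int", "cbcl_ext", "cbcl_tot", "iq_dq"):
        if col in frame.columns:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return ClinicalTable(frame)


def _as_series(scores) -> pd.Series:
    s = pd.Series(scores, dtype=float) if not isinstance(scores, pd.Series) else scores.astype(float)
    return s


def stratify_cbcl(t_scores, cfg: StratConfig = StratConfig()) -> pd.Series:
    """Three-band CBCL stratification: no_symptoms / at_risk / symptoms.

    t < cbcl_none_below -> no_symptoms; cbcl_none_below <= t < cbcl_clinical_at
    -> at_risk; t >= cbcl_clinical_at -> symptoms.  With defaults the bands
    are <60, 60-63, >=64; both 60 and 63 fall in at_risk.
    """
    s = _as_series(t_scores)
    if (s.dropna() < 0).any():
        raise ValueError("CBCL t-scores must be non-negative")
    out = pd.Series(pd.NA, index=s.index, dtype=object)
    out[s < cfg.cbcl_none_below] = "no_symptoms"
    out[(s >= cfg.cbcl_none_below) & (s < cfg.cbcl_clinical_at)] = "at_risk"
    out[s >= cfg.cbcl_clinical_at] = "symptoms"
    return out


def stratify_css(css, cfg: StratConfig = StratConfig()) -> pd.Series:
    """Two-level autism severity from the calibrated severity score."""
    s = _as_series(css)
    valid = s.dropna()
    if ((valid < 1) | (valid > 10)).any():
        raise ValueError("CSS values must lie in [1, 10]")
    out = pd.Series(pd.NA, index=s.index, dtype=object)
    out[s < cfg.css_severe_at] = "mild_moderate"
    out[s >= cfg.css_severe_at] = "severe"
    return out


def stratify_iq(iq, cfg: StratConfig = StratConfig()) -> pd.Series:
    """Cognitive impairment / developmental delay split on IQ/DQ."""
    s = _as_series(iq)
    out = pd.Series(pd.NA, index=s.index, dtype=object)
    out[s < cfg.iq_cidd_below] = "cidd"
    out[s >= cfg.iq_cidd_below] = "no_cidd"
    return out


def stratify(clinical: ClinicalTable, variable: str, cfg: StratConfig = StratConfig()) -> pd.Series:
    """Subgroup labels for one variable, indexed by subject id."""
    scores = clinical.scores(variable)
    if variable == "CSS":
        return stratify_css(scores, cfg)
    if variable.startswith("CBCL"):
        return stratify_cbcl(scores, cfg)
    return stratify_iq(scores, cfg)


def stratify_all(clinical: ClinicalTable, cfg: StratConfig = StratConfig()) -> pd.DataFrame:
    """Tidy long-format label table (subject_id, variable, label)."""
    rows = []
    for var in VARIABLES:
        labels = stratify(clinical, var, cfg)
        for sid, lab in labels.items():
            rows.append((sid, var, lab))
    return pd.DataFrame(rows, columns=["subject_id", "variable", "label"])


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def cohort_summary(labels: pd.Series) -> pd.DataFrame:
    """Counts and integer percents per label over the scored subjects.

    Percents use the number of non-missing labels as the denominator and
    round half away from zero, matching clinical reporting convention.
    """
    non_missing = labels.dropna()
    if len(non_missing) == 0:
        raise ValueError("all labels missing; nothing to summarise")
    counts = non_missing.value_counts()
    n = len(non_missing)
    out = pd.DataFrame(
        {
            "count": counts,
            "percent": [_round_half_away(100.0 * c / n) for c in counts],
        }
    )
    out.index.name = "label"
    out.attrs["n_scored"] = n
    out.attrs["n_missing"] = int(labels.isna().sum())
    return out
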