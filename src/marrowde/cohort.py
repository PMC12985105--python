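"""Clinical cohort table: loading, contrasts, cross-tabulation, confounder eligibility.

The cohort is a small table of transplant recipients with two partially
overlapping binary outcomes — chronic graft-versus-host disease (cGvHD) and
leukemia relapse — plus clinical covariates (donor source, HLA matching,
GvHD prophylaxis, acute GvHD history, disease risk) and a processing-batch
label. Each outcome is analyzed as a two-group contrast with the *other*
outcome and the batch always kept as covariates, because the outcomes
partially overlap within the same subjects.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DegenerateContrastError, SchemaError, ValidationError

OUTCOMES = ("cgvhd", "relapse")

REQUIRED_COLUMNS = (
    "subject_id",
    "cgvhd",
    "relapse",
    "batch",
)

#: clinical factors examined for confounder robustness
DEFAULT_CANDIDATE_FACTORS = ("donor_source", "hla_match", "ptcy", "all_risk", "agvhd")

_TRUE = {"1", "yes", "true", "y"}
_FALSE = {"0", "no", "false", "n"}


@dataclass(frozen=True)
class ContrastSpec:
    """One two-group comparison: an outcome of interest vs the rest of the cohort.

    The covariate list always contains the processing batch and the other
    outcome, mirroring the role-swap between the two analyses.
    """

    variable: str
    covariates: tuple[str, ...]
    positive_group: frozenset[str]
    negative_group: frozenset[str]

    @property
    def n_positive(self) -> int:
        return len(self.positive_group)

    @property
    def n_negative(self) -> int:
        return len(self.negative_group)


@dataclass
class CohortTable:
    """Validated per-subject clinical table.

    ``data`` is indexed by ``subject_id``; outcome columns are 0/1 integers,
    other clinical factors are normalized (case-folded) strings.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _validate(self.data)

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


def _coerce_binary(series: pd.Series, name: str) -> pd.Series:
    out = []
    for v in series:
        s = str(v).strip().casefold()
        if s in _TRUE:
            out.append(1)
        elif s in _FALSE:
            out.append(0)
        else:
            raise ValidationError(
                f"column {name!r}: value {v!r} is not binary (expected 0/1/yes/no)"
            )
    return pd.Series(out, index=series.index, dtype=int)


def _validate(df: pd.DataFrame) -> None:
    if df.index.name != "subject_id":
        raise SchemaError("cohort table must be indexed by subject_id")
    if not df.index.is_unique:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated subject_id values: {dupes}")
    for col in ("cgvhd", "relapse"):
        if not set(df[col].unique()) <= {0, 1}:
            raise ValidationError(f"outcome column {col!r} is not strictly 0/1")
    if df["batch"].isna().any() or (df["batch"].astype(str).str.strip() == "").any():
        raise ValidationError("every subject must have a batch label")


def load_cohort(path: str | Path | None = None) -> CohortTable:
    """Load and validate a cohort table from TSV/CSV.

    With no ``path``, loads the packaged study cohort (14 subjects in three
    processing batches; note the batch assignment in the packaged table is a
    deterministic placeholder, as cartridge assignments are not public).
    A ``ptcy`` column is derived from the prophylaxis string when absent.
    """
    if path is None:
        ref = importlib.resources.files("marrowde.data") / "cohort_tables12.tsv"
        with importlib.resources.as_file(ref) as p:
            return load_cohort(p)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df["subject_id"] = df["subject_id"].astype(str).str.strip()
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicated subject_id values: {dupes}")
    df = df.set_index("subject_id")
    for col in ("cgvhd", "relapse", "agvhd", "ptcy"):
        if col in df.columns:
            df[col] = _coerce_binary(df[col], col)
    if "ptcy" not in df.columns and "prophylaxis" in df.columns:
        df["ptcy"] = (
            df["prophylaxis"].str.casefold().str.contains("ptcy").astype(int)
        )
    # normalize categorical levels; missing non-outcome values become their own level
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].fillna("missing").astype(str).str.strip().str.casefold()
    for col in ("sampling_day", "age_at_hsct"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col]).astype(int)
    return CohortTable(df)


def build_contrast(cohort: CohortTable, variable: str) -> ContrastSpec:
    """Partition the cohort by one outcome; the other outcome and batch are covariates."""
    if variable not in OUTCOMES:
        raise ValueError(f"variable must be one of {OUTCOMES}, got {variable!r}")
    other = OUTCOMES[1 - OUTCOMES.index(variable)]
    flags = cohort.data[variable]
    pos = frozenset(flags.index[flags == 1])
    neg = frozenset(flags.index[flags == 0])
    if min(len(pos), len(neg)) < 2:
        raise DegenerateContrastError(
            f"contrast on {variable!r} degenerate: group sizes {len(pos)}/{len(neg)}"
        )
    return ContrastSpec(
        variable=variable,
        covariates=("batch", other),
        positive_group=pos,
        negative_group=neg,
    )


def crosstab_outcomes(cohort: CohortTable) -> pd.DataFrame:
    """2x2 subject counts, cGvHD status (rows) by relapse status (columns)."""
    df = cohort.data
    tab = pd.DataFrame(0, index=[1, 0], columns=[1, 0], dtype=int)
    for g in (1, 0):
        for r in (1, 0):
            tab.loc[g, r] = int(((df["cgvhd"] == g) & (df["relapse"] == r)).sum())
    tab.index.name = "cgvhd"
    tab.columns.name = "relapse"
    return tab


def binarize_factor(values: pd.Series) -> pd.Series:
    """Majority level vs rest, as 0/1 (1 = minority pool).

    With a cohort of 14 a multi-level clinical factor is not estimable, so
    every factor enters eligibility and robustness models as majority vs rest.
    Ties are broken by lexicographic level order for determinism.
    """
    counts = values.value_counts()
    majority = sorted(counts.index[counts == counts.max()])[0]
    return (values != majority).astype(int)


def eligible_confounders(
    cohort: CohortTable,
    candidate_fields: tuple[str, ...] | list[str] = DEFAULT_CANDIDATE_FACTORS,
    min_minority: int = 4,
) -> list[str]:
    """Clinical factors with adequate variation to be modeled as confounders.

    A factor qualifies when, after binarizing majority-vs-rest, its minority
    pool has at least ``min_minority`` subjects (default 4, i.e. more than 3
    subjects differing from the rest).
    """
    out = []
    for f in candidate_fields:
        if f not in cohort.data.columns:
            raise SchemaError(f"candidate factor {f!r} not in cohort table")
        b = binarize_factor(cohort.data[f])
        minority = int(min(b.sum(), (1 - b).sum()))
        if minority >= min_minority:
            out.append(f)
    return out
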