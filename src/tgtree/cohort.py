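"""Patient-level cohort container, validation and CSV input/output.

One record per patient: demographic and pathological predictors measured
before postoperative radioiodine therapy (age, sex, histology, T and N
stage, ATA recurrence-risk class), the pre-ablation laboratory panel
(TSH, thyroglobulin, 24-h radioiodine uptake), the post-treatment
whole-body scintigraphy (PT-WBS) reading, and an optional treating-center
label. The modeled endpoint is *positive* PT-WBS, i.e. pathological
uptake outside the thyroid bed; remnant-only uptake is a non-event.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

SEX_LEVELS = ("M", "F")
HISTOLOGY_LEVELS = ("PTC", "PTC-FV", "FTC", "HCTC")
ATA_LEVELS = ("low", "intermediate", "high")  # ordered
T_STAGE_LEVELS = (1, 2, 3, 4)
N_STAGE_LEVELS = (0, 1)
PTWBS_LEVELS = ("negative", "remnant", "positive")

#: Canonical CSV column order. ``center`` is optional on input.
COLUMNS = (
    "age", "sex", "histology", "t_stage", "n_stage", "ata_risk",
    "tsh", "tg", "raiu", "ptwbs", "center",
)
MANDATORY_COLUMNS = COLUMNS[:-1]

#: Case-insensitive header aliases accepted by :func:`read_cohort_csv`.
COLUMN_ALIASES = {
    "age": "age",
    "sex": "sex", "gender": "sex",
    "histology": "histology", "histotype": "histology",
    "t_stage": "t_stage", "t": "t_stage", "tstage": "t_stage",
    "n_stage": "n_stage", "n": "n_stage", "nstage": "n_stage",
    "ata_risk": "ata_risk", "ata": "ata_risk", "ata_class": "ata_risk",
    "tsh": "tsh",
    "tg": "tg", "thyroglobulin": "tg",
    "raiu": "raiu", "uptake": "raiu",
    "ptwbs": "ptwbs", "pt_wbs": "ptwbs", "pt-wbs": "ptwbs", "wbs": "ptwbs",
    "center": "center", "centre": "center", "site": "center",
}


class SchemaError(ValueError):
    """The CSV header does not map onto the cohort schema."""


class CohortValidationError(ValueError):
    """A record violates a field invariant."""


def binarize_endpoint(ptwbs_label: str) -> int:
    """Map a PT-WBS reading to the binary endpoint.

    ``positive`` (pathological uptake outside the thyroid bed) -> 1;
    ``negative`` and ``remnant`` (thyroid-bed uptake only) -> 0.
    """
    if ptwbs_label not in PTWBS_LEVELS:
        raise CohortValidationError(f"unknown endpoint label: {ptwbs_label!r}")
    return 1 if ptwbs_label == "positive" else 0


@dataclass(frozen=True)
class PatientRecord:
    """A single validated patient record."""

    age: int
    sex: str
    histology: str
    t_stage: int
    n_stage: int
    ata_risk: str
    tsh: float
    tg: float
    raiu: float
    ptwbs: str
    center: Optional[str] = None

    def __post_init__(self) -> None:
        if not float(self.age).is_integer() or self.age < 18:
            raise CohortValidationError(f"age must be an integer >= 18, got {self.age}")
        if self.sex not in SEX_LEVELS:
            raise CohortValidationError(f"unknown sex: {self.sex!r}")
        if self.histology not in HISTOLOGY_LEVELS:
            raise CohortValidationError(f"unknown histology: {self.histology!r}")
        if self.t_stage not in T_STAGE_LEVELS:
            raise CohortValidationError(f"t_stage must be in {T_STAGE_LEVELS}")
        if self.n_stage not in N_STAGE_LEVELS:
            raise CohortValidationError(f"n_stage must be in {N_STAGE_LEVELS}")
        if self.ata_risk not in ATA_LEVELS:
            raise CohortValidationError(f"unknown ata_risk: {self.ata_risk!r}")
        if not self.tsh > 0:
            raise CohortValidationError("tsh must be positive")
        if self.tg < 0:
            raise CohortValidationError("tg must be non-negative")
        if not 0 <= self.raiu <= 100:
            raise CohortValidationError("raiu must lie in [0, 100]")
        if self.ptwbs not in PTWBS_LEVELS:
            raise CohortValidationError(f"unknown endpoint label: {self.ptwbs!r}")

    @property
    def endpoint(self) -> int:
        return binarize_endpoint(self.ptwbs)


@dataclass
class ParseReport:
    """Row-level accounting for a CSV read."""

    n_read: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class Cohort:
    """An ordered, validated collection of patient records.

    Backed by a :class:`pandas.DataFrame` in canonical column order; the
    row order is stable because resampling reproducibility depends on it.
    """

    df: pd.DataFrame
    provenance: str = ""
    seed: Optional[int] = None
    report: Optional[ParseReport] = None

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"cohort frame missing columns: {missing}")
        self.df = self.df.loc[:, list(COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    @property
    def records(self) -> list[PatientRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            center = d.get("center")
            if center is not None and (center == "" or (isinstance(center, float) and np.isnan(center))):
                center = None
            d["center"] = center
            out.append(PatientRecord(**d))
        return out

    @classmethod
    def from_records(cls, records: Iterable[PatientRecord], provenance: str = "",
                     seed: Optional[int] = None) -> "Cohort":
        rows = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(rows, columns=list(COLUMNS))
        return cls(df, provenance=provenance, seed=seed)

    @property
    def endpoint(self) -> np.ndarray:
        """Binary endpoint vector: 1 iff ptwbs == 'positive'."""
        return (self.df["ptwbs"].to_numpy() == "positive").astype(np.int64)

    @property
    def event_rate(self) -> float:
        if len(self) == 0:
            raise CohortValidationError("empty cohort has no event rate")
        return float(self.endpoint.mean())

    def subset(self, index: Sequence[int] | np.ndarray, provenance: str | None = None) -> "Cohort":
        df = self.df.iloc[np.asarray(index)].reset_index(drop=True)
        return Cohort(df, provenance=provenance or self.provenance, seed=self.seed)


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Vectorized row validation; returns (clean frame, rejected rows)."""
    n = len(df)
    reason = np.array([""] * n, dtype=object)

    def flag(bad: np.ndarray, msg: str) -> None:
        fresh = bad & (reason == "")
        reason[fresh] = msg

    num = {}
    for col in ("age", "t_stage", "n_stage", "tsh", "tg", "raiu"):
        v = pd.to_numeric(df[col], errors="coerce")
        flag(v.isna().to_numpy(), f"missing or unparseable {col}")
        num[col] = v

    cat = {}
    for col, levels in (("sex", SEX_LEVELS), ("histology", HISTOLOGY_LEVELS),
                        ("ata_risk", ATA_LEVELS)):
        v = df[col].astype("string").str.strip()
        cat[col] = v
        flag((v.isna() | ~v.isin(levels)).to_numpy(), f"unknown {col} label")
    wbs = df["ptwbs"].astype("string").str.strip()
    flag((wbs.isna() | ~wbs.isin(PTWBS_LEVELS)).to_numpy(), "unknown endpoint label")

    with np.errstate(invalid="ignore"):
        flag((num["age"] < 18).to_numpy() | (num["age"] % 1 != 0).to_numpy(), "age out of range")
        flag(~num["t_stage"].isin(T_STAGE_LEVELS).to_numpy(), "t_stage out of range")
        flag(~num["n_stage"].isin(N_STAGE_LEVELS).to_numpy(), "n_stage out of range")
        flag((num["tsh"] <= 0).to_numpy(), "tsh out of range")
        flag((num["tg"] < 0).to_numpy(), "tg out of range")
        flag(((num["raiu"] < 0) | (num["raiu"] > 100)).to_numpy(), "raiu out of range")

    ok = reason == ""
    rejected = [(int(i), str(r)) for i, r in enumerate(reason) if r]
    center = df["center"].astype("string").str.strip() if "center" in df.columns else pd.Series([pd.NA] * n, dtype="string")
    clean = pd.DataFrame({
        "age": num["age"],
        "sex": cat["sex"], "histology": cat["histology"],
        "t_stage": num["t_stage"], "n_stage": num["n_stage"],
        "ata_risk": cat["ata_risk"], "tsh": num["tsh"], "tg": num["tg"],
        "raiu": num["raiu"], "ptwbs": wbs, "center": center,
    })[ok].reset_index(drop=True)
    clean = clean.astype({"age": "int64", "t_stage": "int64", "n_stage": "int64"})
    for c in ("sex", "histology", "ata_risk", "ptwbs", "center"):
        clean[c] = clean[c].astype(object)
    clean["center"] = clean["center"].where(pd.notna(clean["center"]), None)
    return clean, rejected


def read_cohort_csv(path: str | Path, *, strict: bool = False,
                    provenance: str | None = None) -> Cohort:
    """Read and validate a cohort CSV.

    Header is mandatory; column names are matched case-insensitively
    through :data:`COLUMN_ALIASES`. Rows violating any record invariant
    (including missing mandatory values) are rejected, mirroring the
    study's complete-case inclusion rule; the per-row reasons are kept in
    ``cohort.report``. With ``strict=True`` any rejected row raises.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    rename = {}
    for col in raw.columns:
        key = col.strip().lower()
        if key in COLUMN_ALIASES:
            rename[col] = COLUMN_ALIASES[key]
    raw = raw.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    if "center" not in raw.columns:
        raw["center"] = pd.NA

    clean, rejected = _validate_frame(raw)
    if strict and rejected:
        i, why = rejected[0]
        raise CohortValidationError(f"row {i}: {why}")
    report = ParseReport(n_read=len(raw), n_accepted=len(clean), rejected=rejected)
    return Cohort(clean, provenance=provenance or str(path), report=report)


def write_cohort_csv(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort in the canonical CSV dialect.

    Comma-separated, UTF-8, '.' decimal separator, deterministic column
    order, full-precision floats (round-trips through
    :func:`read_cohort_csv` without loss).
    """
    path = Path(path)
    df = cohort.df.copy()
    df["center"] = df["center"].fillna("")
    df.to_csv(path, index=False, encoding="utf-8")
    return path
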