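"""Imaging geometry and cohort ingestion.

Segmented MRI tumor volumes (gadolinium-enhanced T1, T2/FLAIR, central
necrosis) are reduced to spherically-equivalent radii, from which composite
measures (contrast-enhancing rim thickness) and survival-group labels
(extreme vs short-term survivors) are derived.  The loader validates the
geometric nesting invariants — necrosis inside the T1Gd abnormality inside
the T2/FLAIR abnormality — and rejects inconsistent rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gliosurv")

#: overall survival (days) at or above which a patient is an extreme survivor
EXS_THRESHOLD_DAYS = 1825.0
#: overall survival (days) at or below which a patient is a short-term survivor
STS_THRESHOLD_DAYS = 210.0

SEXES = ("male", "female")
LATERALITY_LEVELS = ("left", "right", "bilateral", "unknown")
EOR_LEVELS = ("GTR", "STR", "biopsy", "unknown")
IDH1_LEVELS = ("mut", "wt", "unknown")
MGMT_LEVELS = ("methylated", "unmethylated", "unknown")

#: the eight quantitative pre-treatment variables used throughout the analysis
QUANTITATIVE_VARIABLES = (
    "age_years",
    "t1gd_radius_mm",
    "necrosis_radius_mm",
    "ce_thickness_mm",
    "t2flair_radius_mm",
    "pihna_D",
    "pihna_rho",
    "pi_D_over_rho",
)

#: the subset of quantitative variables that require T2/FLAIR imaging
KINETIC_VARIABLES = ("t2flair_radius_mm", "pihna_D", "pihna_rho", "pi_D_over_rho")

MANDATORY_COLUMNS = ("id", "sex", "age_years", "os_days", "t1gd")


class SchemaError(ValueError):
    """Raised when a cohort table lacks mandatory columns."""


class InvalidInputError(ValueError):
    """Raised when a scalar operation receives out-of-domain input."""


def volume_to_radius(volume_mm3: float) -> float:
    """Spherically-equivalent radius (mm) of a segmented volume (mm^3).

    Inverts V = (4/3) pi r^3.  Monotone in the volume; zero maps to zero.
    """
    if volume_mm3 < 0:
        raise InvalidInputError(f"volume must be non-negative, got {volume_mm3}")
    return (3.0 * volume_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def radius_to_volume(radius_mm: float) -> float:
    """Volume (mm^3) of a sphere of the given radius (mm)."""
    if radius_mm < 0:
        raise InvalidInputError(f"radius must be non-negative, got {radius_mm}")
    return 4.0 / 3.0 * math.pi * radius_mm**3


def ce_thickness(t1gd_radius_mm: float, necrosis_radius_mm: float) -> float:
    """Contrast-enhancing rim thickness: T1Gd radius minus necrosis radius.

    A negative difference signals an inconsistent segmentation (necrotic core
    larger than the enclosing enhancing lesion) and raises.
    """
    if necrosis_radius_mm < 0:
        raise InvalidInputError("necrosis radius must be non-negative")
    diff = t1gd_radius_mm - necrosis_radius_mm
    if diff < 0:
        raise InvalidInputError(
            f"necrosis radius {necrosis_radius_mm} exceeds T1Gd radius {t1gd_radius_mm}"
        )
    return diff


def classify_survival_group(
    os_days: float,
    exs_threshold: float = EXS_THRESHOLD_DAYS,
    sts_threshold: float = STS_THRESHOLD_DAYS,
) -> str:
    """Label a survival time as ``EXS``, ``STS`` or ``neither``.

    Extreme survivors live at least `exs_threshold` days (default 5 years);
    short-term survivors at most `sts_threshold` days (default 210).  Both
    boundaries are inclusive and the two labels are mutually exclusive.
    """
    if os_days <= 0:
        raise InvalidInputError(f"overall survival must be positive, got {os_days}")
    if exs_threshold <= sts_threshold:
        raise InvalidInputError("EXS threshold must exceed STS threshold")
    if os_days >= exs_threshold:
        return "EXS"
    if os_days <= sts_threshold:
        return "STS"
    return "neither"


@dataclass
class PatientRecord:
    """One subject: demographics, survival, imaging radii, kinetics, covariates.

    Radii are in mm, kinetic rates in mm^2/year (D) and 1/year (rho), overall
    survival in days, age in years.  Optional numeric fields use NaN for
    missing; categorical fields use ``"unknown"``.
    """

    id: str
    sex: str
    age_years: float
    os_days: float
    event: int = 1
    t1gd_radius_mm: float = float("nan")
    t2flair_radius_mm: float = float("nan")
    necrosis_radius_mm: float = float("nan")
    ce_thickness_mm: float = float("nan")
    pihna_D: float = float("nan")
    pihna_rho: float = float("nan")
    pi_D_over_rho: float = float("nan")
    laterality: str = "unknown"
    eor: str = "unknown"
    idh1: str = "unknown"
    mgmt: str = "unknown"
    survival_group: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise InvalidInputError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_years < 0:
            raise InvalidInputError("age must be non-negative")
        if self.os_days <= 0:
            raise InvalidInputError("overall survival must be positive")
        if self.event not in (0, 1):
            raise InvalidInputError("event indicator must be 0 or 1")
        for name in ("t1gd_radius_mm", "t2flair_radius_mm", "necrosis_radius_mm"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        t1, t2, nec = self.t1gd_radius_mm, self.t2flair_radius_mm, self.necrosis_radius_mm
        if not math.isnan(t1) and not math.isnan(nec) and nec > t1 + 1e-9:
            raise InvalidInputError("necrosis radius exceeds T1Gd radius")
        if not math.isnan(t1) and not math.isnan(t2) and t2 < t1 - 1e-9:
            raise InvalidInputError("T2/FLAIR radius smaller than T1Gd radius")
        if math.isnan(self.ce_thickness_mm) and not math.isnan(t1) and not math.isnan(nec):
            self.ce_thickness_mm = t1 - nec
        if not self.survival_group:
            self.survival_group = classify_survival_group(self.os_days)
        for name, levels in (
            ("laterality", LATERALITY_LEVELS),
            ("eor", EOR_LEVELS),
            ("idh1", IDH1_LEVELS),
            ("mgmt", MGMT_LEVELS),
        ):
            if getattr(self, name) not in levels:
                raise InvalidInputError(f"{name} must be one of {levels}")

    @property
    def has_kinetics(self) -> bool:
        """Whether the subject belongs to the imaging sub-cohort (T2/FLAIR present)."""
        return not math.isnan(self.t2flair_radius_mm)


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Tabulate patient records as a DataFrame with canonical column names."""
    cols = [f.name for f in fields(PatientRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    cols = {f.name for f in fields(PatientRecord)}
    out = []
    for _, row in frame.iterrows():
        kwargs = {k: v for k, v in row.items() if k in cols}
        out.append(PatientRecord(**kwargs))
    return out


#: canonical key -> default file column name; the loader also accepts the
#: short key itself (e.g. a column literally named "t1gd") as a fallback
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "id": "id",
    "sex": "sex",
    "age_years": "age_years",
    "os_days": "os_days",
    "event": "event",
    "t1gd": "t1gd_radius_mm",
    "t2flair": "t2flair_radius_mm",
    "necrosis": "necrosis_radius_mm",
    "pihna_D": "pihna_D",
    "pihna_rho": "pihna_rho",
    "pi_D_over_rho": "pi_D_over_rho",
    "laterality": "laterality",
    "eor": "eor",
    "idh1": "idh1",
    "mgmt": "mgmt",
}


def read_cohort(
    path,
    column_map: Mapping[str, str] | None = None,
    volumes: bool = False,
    sep: str | None = None,
    exs_threshold: float = EXS_THRESHOLD_DAYS,
    sts_threshold: float = STS_THRESHOLD_DAYS,
) -> list[PatientRecord]:
    """Load a delimiter-separated patient table into validated records.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    column_map
        Mapping from canonical keys (``id, sex, age_years, os_days, event,
        t1gd, t2flair, necrosis, pihna_D, pihna_rho, pi_D_over_rho,
        laterality, eor, idh1, mgmt``) to the column names in the file.
        Defaults assume canonical names.
    volumes
        If True the three imaging columns hold volumes in mm^3 and are
        converted to spherically-equivalent radii on load.
    sep
        Field delimiter; sniffed by pandas when None.

    Rows violating a record invariant are rejected with a logged reason.
    Missing optional fields become NaN / ``"unknown"``.  If the event column
    is absent every subject is treated as having an observed death (event=1)
    and a warning is logged.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, engine="python")
    # accept the short canonical key itself as a column-name fallback
    for key, col in list(cmap.items()):
        if col not in df.columns and key in df.columns:
            cmap[key] = key
    missing = [k for k in MANDATORY_COLUMNS if cmap[k] not in df.columns]
    if missing:
        raise SchemaError(f"mandatory columns missing from {path}: {missing}")
    if cmap["event"] not in df.columns:
        logger.warning("no event column in %s; assuming event=1 (death observed) for all", path)

    def _imaging(row, key):
        col = cmap.get(key)
        if col is None or col not in df.columns or pd.isna(row[col]):
            return float("nan")
        val = float(row[col])
        return volume_to_radius(val) if volumes else val

    records: list[PatientRecord] = []
    for idx, row in df.iterrows():
        try:
            sex = str(row[cmap["sex"]]).strip().lower()
            sex = {"m": "male", "f": "female"}.get(sex, sex)
            nec = _imaging(row, "necrosis")
            rec = PatientRecord(
                id=str(row[cmap["id"]]),
                sex=sex,
                age_years=float(row[cmap["age_years"]]),
                os_days=float(row[cmap["os_days"]]),
                event=int(row[cmap["event"]]) if cmap["event"] in df.columns else 1,
                t1gd_radius_mm=_imaging(row, "t1gd"),
                t2flair_radius_mm=_imaging(row, "t2flair"),
                necrosis_radius_mm=0.0 if math.isnan(nec) else nec,
                **{
                    k: float(row[cmap[k]])
                    for k in ("pihna_D", "pihna_rho", "pi_D_over_rho")
                    if cmap[k] in df.columns and not pd.isna(row[cmap[k]])
                },
                **{
                    k: str(row[cmap[k]])
                    for k in ("laterality", "eor", "idh1", "mgmt")
                    if cmap[k] in df.columns and not pd.isna(row[cmap[k]])
                },
                survival_group=classify_survival_group(
                    float(row[cmap["os_days"]]), exs_threshold, sts_threshold
                ),
            )
        except (InvalidInputError, ValueError) as exc:
            logger.warning("rejecting row %s of %s: %s", idx, path, exc)
            continue
        records.append(rec)
    return records


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    """Write a normalized cohort CSV with derived columns."""
    records_to_frame(records).to_csv(path, index=False)


def composition_table(
    n_male_all: int,
    n_female_all: int,
    n_male_exs: int,
    n_female_exs: int,
    n_male_sts: int,
    n_female_sts: int,
) -> pd.DataFrame:
    """Sex-by-survival-group composition with within-row percentages.

    Each row gives male and female counts and the percentage each sex
    contributes to that survival group, rounded to one decimal place.
    """
    rows = []
    for label, m, f in (
        ("all", n_male_all, n_female_all),
        ("EXS", n_male_exs, n_female_exs),
        ("STS", n_male_sts, n_female_sts),
    ):
        total = m + f
        rows.append(
            {
                "group": label,
                "n_male": m,
                "n_female": f,
                "pct_male": round(100.0 * m / total, 1) if total else float("nan"),
                "pct_female": round(100.0 * f / total, 1) if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def cohort_composition(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Composition table computed from a labeled cohort."""
    df = records_to_frame(records)
    male = df["sex"] == "male"
    return composition_table(
        int(male.sum()),
        int((~male).sum()),
        int((male & (df["survival_group"] == "EXS")).sum()),
        int((~male & (df["survival_group"] == "EXS")).sum()),
        int((male & (df["survival_group"] == "STS")).sum()),
        int((~male & (df["survival_group"] == "STS")).sum()),
    )
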