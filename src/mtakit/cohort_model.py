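"""Domain types, CSV I/O, CSF A/T stratification, and QC filtering.

A cohort is a long-format table: one row per (subject, visit, rater,
hemisphere). Subject-level columns (CSF chemistry, diagnosis) are repeated
on every row and checked for internal consistency at load time.

Stratification follows the conventional CSF A/T dichotomisation: amyloid
positive (A+) when the Aβ42/Aβ40 ratio falls *below* its cut-off, tau
positive (T+) when phosphorylated tau rises *above* its cut-off. Values
exactly on a cut-off map to the normal side (strict inequalities).
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

HEMISPHERES = ("left", "right")

CSV_HEADER = [
    "subject_id",
    "visit_index",
    "age_at_scan",
    "diagnosis",
    "csf_ab42_40",
    "csf_ptau",
    "rater",
    "hemisphere",
    "mta",
    "hc_vol_mm3",
    "ilv_vol_mm3",
    "qc_pass",
    "mmse",
    "adas_dwr",
    "dementia_dx",
]


class CohortLoadError(ValueError):
    """Malformed cohort table; message names the offending row."""


class DomainError(ValueError):
    """Input outside the valid domain of an operation."""


class ATGroup(str, Enum):
    """CSF amyloid/tau group."""

    AnTn = "AnTn"
    ApTn = "ApTn"
    ApTp = "ApTp"
    AnTp = "AnTp"


class Diagnosis(str, Enum):
    SCD = "SCD"
    MCI = "MCI"


@dataclass(frozen=True)
class CSFCutoffs:
    """Dichotomisation cut-offs: A+ iff ab42_40 < ab42_40 cut-off, T+ iff
    p-tau > ptau cut-off (pg/ml). Equality maps to the normal side."""

    ab42_40: float = 0.10
    ptau: float = 72.0


def stratify_csf(
    ab42_40: float, ptau: float, cutoffs: CSFCutoffs = CSFCutoffs()
) -> ATGroup:
    """Assign a CSF A/T group from the Aβ42/40 ratio and p-tau (pg/ml).

    Raises
    ------
    DomainError
        If either value is non-positive or non-finite.
    """
    for name, v in (("ab42_40", ab42_40), ("ptau", ptau)):
        if not math.isfinite(v) or v <= 0:
            raise DomainError(f"{name} must be positive and finite, got {v!r}")
    a_pos = ab42_40 < cutoffs.ab42_40
    t_pos = ptau > cutoffs.ptau
    if a_pos and t_pos:
        return ATGroup.ApTp
    if a_pos:
        return ATGroup.ApTn
    if t_pos:
        return ATGroup.AnTp
    return ATGroup.AnTn


@dataclass
class SubjectProfile:
    """Per-subject constants: CSF chemistry and derived A/T group."""

    subject_id: str
    csf_ab42_40: float
    csf_ptau: float
    at_group: ATGroup
    apoe4: bool | None = None
    sex: str | None = None
    education_years: float | None = None


@dataclass
class VisitRecord:
    """One subject-visit observation.

    ``ratings`` maps (rater_id, hemisphere) to the MTA rating (integer-valued
    for discrete human raters, any float in [0, 4] for continuous automated
    raters). Volumes are per hemisphere in mm³, ``None`` when missing.
    """

    subject_id: str
    visit_index: int
    age_at_scan: float
    diagnosis: Diagnosis
    ratings: dict[tuple[str, str], float] = field(default_factory=dict)
    hc_vol: dict[str, float | None] = field(default_factory=dict)
    ilv_vol: dict[str, float | None] = field(default_factory=dict)
    qc_pass: bool = True
    mmse: int | None = None
    adas_dwr: float | None = None
    dementia_dx: bool = False


@dataclass
class Cohort:
    """A validated longitudinal cohort.

    ``rater_registry`` maps rater_id to its scale type, ``"discrete"`` or
    ``"continuous"``.
    """

    subjects: dict[str, SubjectProfile]
    visits: list[VisitRecord]
    rater_registry: dict[str, str]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def visits_of(self, subject_id: str) -> list[VisitRecord]:
        out = [v for v in self.visits if v.subject_id == subject_id]
        out.sort(key=lambda v: v.visit_index)
        return out

    def by_subject(self) -> dict[str, list[VisitRecord]]:
        out: dict[str, list[VisitRecord]] = {}
        for v in self.visits:
            out.setdefault(v.subject_id, []).append(v)
        for vs in out.values():
            vs.sort(key=lambda v: v.visit_index)
        return out

    def discrete_raters(self) -> list[str]:
        return [r for r, s in self.rater_registry.items() if s == "discrete"]

    def continuous_raters(self) -> list[str]:
        return [r for r, s in self.rater_registry.items() if s == "continuous"]

    def validate(self) -> None:
        """Check referential integrity and the per-type invariants."""
        for v in self.visits:
            if v.subject_id not in self.subjects:
                raise CohortLoadError(
                    f"visit references unknown subject {v.subject_id!r}"
                )
            for (rater, hemi), val in v.ratings.items():
                if val is None:
                    continue
                scale = self.rater_registry.get(rater)
                if scale is None:
                    raise CohortLoadError(f"unregistered rater {rater!r}")
                _check_rating(val, scale, f"subject {v.subject_id} visit {v.visit_index} rater {rater}/{hemi}")
        for sid, vs in self.by_subject().items():
            idxs = [v.visit_index for v in vs]
            if len(set(idxs)) != len(idxs):
                raise CohortLoadError(f"duplicate visit_index for subject {sid}")
            ages = [v.age_at_scan for v in vs]
            if any(b <= a for a, b in zip(ages, ages[1:])):
                raise CohortLoadError(
                    f"age_at_scan not strictly increasing for subject {sid}"
                )


def _check_rating(val: float, scale: str, where: str) -> None:
    if not (0.0 <= val <= 4.0):
        raise CohortLoadError(f"rating {val} outside [0, 4] at {where}")
    if scale == "discrete" and float(val) != int(val):
        raise CohortLoadError(
            f"non-integer rating {val} for discrete rater at {where}"
        )


# --- measure addressing -------------------------------------------------
#
# Analyses address columns through compact measure keys:
#   "mta:<rater>:<hemi>"   an MTA rating series
#   "hc:<hemi>"            hippocampal volume (mm³)
#   "ilv:<hemi>"           inferior lateral ventricle volume (mm³)
#   "mmse", "adas_dwr"     cognitive scores


def measure_value(visit: VisitRecord, measure: str) -> float | None:
    parts = measure.split(":")
    if parts[0] == "mta" and len(parts) == 3:
        return visit.ratings.get((parts[1], parts[2]))
    if parts[0] == "hc" and len(parts) == 2:
        return visit.hc_vol.get(parts[1])
    if parts[0] == "ilv" and len(parts) == 2:
        return visit.ilv_vol.get(parts[1])
    if measure == "mmse":
        return None if visit.mmse is None else float(visit.mmse)
    if measure == "adas_dwr":
        return visit.adas_dwr
    raise ValueError(f"unknown measure key {measure!r}")


def all_measures(cohort: Cohort) -> list[str]:
    """Every measure key present in the cohort, in stable order."""
    keys = []
    for rater in cohort.rater_registry:
        for hemi in HEMISPHERES:
            keys.append(f"mta:{rater}:{hemi}")
    for vol in ("hc", "ilv"):
        for hemi in HEMISPHERES:
            keys.append(f"{vol}:{hemi}")
    keys += ["mmse", "adas_dwr"]
    return keys


# --- CSV I/O ------------------------------------------------------------


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "true" if x else "false"
    if isinstance(x, float):
        return repr(x)
    return str(x)


def _parse_float(cell: str, row: int, col: str) -> float | None:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise CohortLoadError(f"row {row}: bad float {cell!r} in {col}")


def _parse_bool(cell: str, row: int, col: str) -> bool:
    if cell.lower() in ("true", "1"):
        return True
    if cell.lower() in ("false", "0"):
        return False
    raise CohortLoadError(f"row {row}: bad boolean {cell!r} in {col}")


def read_cohort(
    path: str | Path,
    cutoffs: CSFCutoffs = CSFCutoffs(),
    raters: Mapping[str, str] | None = None,
) -> Cohort:
    """Read and validate a long-format cohort CSV.

    Parameters
    ----------
    path:
        CSV with header ``CSV_HEADER``, one row per
        (subject, visit, rater, hemisphere).
    cutoffs:
        CSF dichotomisation cut-offs used to populate each subject's A/T
        group.
    raters:
        rater_id -> "discrete"|"continuous". When omitted, a rater whose
        ratings are all integer-valued is registered as discrete, else
        continuous (logged).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortLoadError("empty file")
        if header != CSV_HEADER:
            raise CohortLoadError(
                f"malformed header: expected {CSV_HEADER}, got {header}"
            )
        rows = list(reader)

    rater_values: dict[str, list[float]] = {}
    visit_map: dict[tuple[str, int], VisitRecord] = {}
    subj_csf: dict[str, tuple[float, float]] = {}
    seen_cells: set[tuple[str, int, str, str]] = set()

    for i, row in enumerate(rows, start=2):  # 1-based incl. header
        if len(row) != len(CSV_HEADER):
            raise CohortLoadError(f"row {i}: expected {len(CSV_HEADER)} cells")
        rec = dict(zip(CSV_HEADER, row))
        sid = rec["subject_id"]
        if not sid:
            raise CohortLoadError(f"row {i}: empty subject_id")
        try:
            vidx = int(rec["visit_index"])
        except ValueError:
            raise CohortLoadError(f"row {i}: bad visit_index {rec['visit_index']!r}")
        if vidx < 0:
            raise CohortLoadError(f"row {i}: negative visit_index")
        rater = rec["rater"]
        hemi = rec["hemisphere"]
        if hemi not in HEMISPHERES:
            raise CohortLoadError(f"row {i}: bad hemisphere {hemi!r}")
        cell = (sid, vidx, rater, hemi)
        if cell in seen_cells:
            raise CohortLoadError(
                f"row {i}: duplicate (subject, visit, rater, hemisphere) {cell}"
            )
        seen_cells.add(cell)

        age = _parse_float(rec["age_at_scan"], i, "age_at_scan")
        if age is None:
            raise CohortLoadError(f"row {i}: missing age_at_scan")
        try:
            diagnosis = Diagnosis(rec["diagnosis"])
        except ValueError:
            raise CohortLoadError(f"row {i}: bad diagnosis {rec['diagnosis']!r}")
        ab = _parse_float(rec["csf_ab42_40"], i, "csf_ab42_40")
        ptau = _parse_float(rec["csf_ptau"], i, "csf_ptau")
        if ab is None or ptau is None:
            raise CohortLoadError(f"row {i}: missing CSF values")
        if sid in subj_csf and subj_csf[sid] != (ab, ptau):
            raise CohortLoadError(f"row {i}: inconsistent CSF values for {sid}")
        subj_csf[sid] = (ab, ptau)

        mta = _parse_float(rec["mta"], i, "mta")
        if mta is not None and not (0.0 <= mta <= 4.0):
            raise CohortLoadError(f"row {i}: MTA rating {mta} outside [0, 4]")
        hc = _parse_float(rec["hc_vol_mm3"], i, "hc_vol_mm3")
        ilv = _parse_float(rec["ilv_vol_mm3"], i, "ilv_vol_mm3")
        for name, vol in (("hc_vol_mm3", hc), ("ilv_vol_mm3", ilv)):
            if vol is not None and vol <= 0:
                raise CohortLoadError(f"row {i}: non-positive {name}")
        qc = _parse_bool(rec["qc_pass"], i, "qc_pass")
        mmse_f = _parse_float(rec["mmse"], i, "mmse")
        if mmse_f is not None and not (0 <= mmse_f <= 30 and mmse_f == int(mmse_f)):
            raise CohortLoadError(f"row {i}: MMSE must be an integer in [0, 30]")
        mmse = None if mmse_f is None else int(mmse_f)
        adas = _parse_float(rec["adas_dwr"], i, "adas_dwr")
        if adas is not None and adas < 0:
            raise CohortLoadError(f"row {i}: negative adas_dwr")
        dem = _parse_bool(rec["dementia_dx"], i, "dementia_dx")

        key = (sid, vidx)
        v = visit_map.get(key)
        if v is None:
            v = VisitRecord(
                subject_id=sid,
                visit_index=vidx,
                age_at_scan=age,
                diagnosis=diagnosis,
                qc_pass=qc,
                mmse=mmse,
                adas_dwr=adas,
                dementia_dx=dem,
            )
            visit_map[key] = v
        else:
            if (v.age_at_scan, v.diagnosis, v.qc_pass, v.mmse, v.adas_dwr, v.dementia_dx) != (
                age, diagnosis, qc, mmse, adas, dem
            ):
                raise CohortLoadError(
                    f"row {i}: inconsistent visit-level fields for {sid} visit {vidx}"
                )
        if mta is not None:
            v.ratings[(rater, hemi)] = mta
            rater_values.setdefault(rater, []).append(mta)
        prev_hc = v.hc_vol.get(hemi)
        if prev_hc is not None and hc is not None and prev_hc != hc:
            raise CohortLoadError(f"row {i}: inconsistent hc_vol for {sid}/{hemi}")
        if hc is not None or hemi not in v.hc_vol:
            v.hc_vol[hemi] = hc if hc is not None else v.hc_vol.get(hemi)
        prev_ilv = v.ilv_vol.get(hemi)
        if prev_ilv is not None and ilv is not None and prev_ilv != ilv:
            raise CohortLoadError(f"row {i}: inconsistent ilv_vol for {sid}/{hemi}")
        if ilv is not None or hemi not in v.ilv_vol:
            v.ilv_vol[hemi] = ilv if ilv is not None else v.ilv_vol.get(hemi)

    if raters is None:
        raters = {
            r: ("discrete" if all(float(x) == int(x) for x in vals) else "continuous")
            for r, vals in rater_values.items()
        }
        log.info("inferred rater scales: %s", raters)
    registry = dict(raters)

    subjects: dict[str, SubjectProfile] = {}
    for sid, (ab, ptau) in subj_csf.items():
        group = stratify_csf(ab, ptau, cutoffs)
        if group is ATGroup.AnTp:
            warnings.warn(
                f"subject {sid} has the CSF combination A-T+ (ab={ab}, ptau={ptau});"
                " this combination is atypical in amyloid-first cohorts",
                stacklevel=2,
            )
        subjects[sid] = SubjectProfile(sid, ab, ptau, group)

    visits = sorted(visit_map.values(), key=lambda v: (v.subject_id, v.visit_index))
    cohort = Cohort(subjects=subjects, visits=visits, rater_registry=registry)
    # registry-aware integrality check, naming the offending visit
    for v in visits:
        for (rater, hemi), val in v.ratings.items():
            scale = registry.get(rater)
            if scale is None:
                raise CohortLoadError(f"unregistered rater {rater!r}")
            _check_rating(val, scale, f"subject {v.subject_id} visit {v.visit_index} rater {rater}/{hemi}")
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the long-format CSV; floats at full (repr) precision so a
    read-back round-trips bit-for-bit."""
    path = Path(path)
    raters = sorted(cohort.rater_registry)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_HEADER)
        for v in sorted(cohort.visits, key=lambda v: (v.subject_id, v.visit_index)):
            prof = cohort.subjects[v.subject_id]
            # one row per rater x hemisphere; volumes repeat across raters
            for rater in raters:
                for hemi in HEMISPHERES:
                    w.writerow(
                        [
                            v.subject_id,
                            _fmt(v.visit_index),
                            _fmt(v.age_at_scan),
                            v.diagnosis.value,
                            _fmt(prof.csf_ab42_40),
                            _fmt(prof.csf_ptau),
                            rater,
                            hemi,
                            _fmt(v.ratings.get((rater, hemi))),
                            _fmt(v.hc_vol.get(hemi)),
                            _fmt(v.ilv_vol.get(hemi)),
                            _fmt(v.qc_pass),
                            _fmt(v.mmse),
                            _fmt(v.adas_dwr),
                            _fmt(v.dementia_dx),
                        ]
                    )


@dataclass
class QCViews:
    """The two provenance-tracked views produced by QC filtering.

    ``volume_view`` keeps only QC-pass visits (for volume-based analyses);
    ``rating_view`` keeps every visit (ratings are never discarded by QC).
    """

    rating_view: Cohort
    volume_view: Cohort
    n_visits_total: int
    n_visits_excluded: int
    subjects_excluded: tuple[str, ...]


def qc_filter(cohort: Cohort) -> QCViews:
    """Split a cohort into volume-analysis and rating-analysis views."""
    passing = [v for v in cohort.visits if v.qc_pass]
    kept_subjects = {v.subject_id for v in passing}
    dropped_subjects = tuple(
        sorted(set(cohort.subjects) - kept_subjects)
    )
    volume_view = Cohort(
        subjects={s: p for s, p in cohort.subjects.items() if s in kept_subjects},
        visits=passing,
        rater_registry=dict(cohort.rater_registry),
    )
    n_excl = cohort.n_visits - len(passing)
    if n_excl:
        log.info(
            "QC filter: excluded %d of %d visits (%d subjects lost entirely)",
            n_excl,
            cohort.n_visits,
            len(dropped_subjects),
        )
    return QCViews(
        rating_view=cohort,
        volume_view=volume_view,
        n_visits_total=cohort.n_visits,
        n_visits_excluded=n_excl,
        subjects_excluded=dropped_subjects,
    )
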