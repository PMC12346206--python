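"""Synthetic patient cohorts for surgically treated diabetic hand infections.

Two generation modes are provided.  The stochastic generator draws cohorts
of arbitrary size whose categorical fields follow the study prevalences
(sex split, type-2 fraction, eight surgical-intervention groups, admission
clinical signs) and whose continuous fields follow distributions matched to
the published summary statistics: truncated normals for admission labs,
right-skewed truncated log-normals for cost components (median < mean
throughout the cost table), and a shifted negative binomial for the
over-dispersed outpatient-visit counts (mean 22.29, SD 11.01, minimum 7).

The deterministic *reference fixture* is a 75-patient cohort, built with no
random number generator, that reproduces every published marginal count
exactly: 11 female / 64 male; 62 type-2 diabetics; intervention group sizes
24/4/5/18/7/10/6/1; 15 patients with 30 or more outpatient visits; 59
right-handed patients with the dominant hand infected in 58.  Continuous
fields are deterministic spreads pinned to each published median and
min–max range; only the marginal counts are claimed exact, since the
underlying per-patient data are unpublished.

Cost items are drawn on the USD target-period scale (matching the published
cost summaries) and then back-converted to nominal Turkish lira for a year
inside the study window, so that downstream aggregation exercises the full
FX + CPI conversion pipeline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .currency import ConversionTables, packaged_tables
from .distributions import DistributionSpec, draw
from .errors import ConfigurationError, DataError

# ---------------------------------------------------------------------------
# Canonical categories and study constants

COST_CATEGORIES = (
    "drug",
    "clinic_stay",
    "icu_stay",
    "outpatient",
    "surgical",
    "incapacity",
    "other",
)

#: Canonical surgical-intervention labels with study group sizes (n=75).
INTERVENTION_COUNTS = {
    "Drainage": 24,
    "Drainage + VAC": 4,
    "Open Amputation + VAC": 5,
    "Ray Amputation": 18,
    "Fasciotomy + VAC": 7,
    "Fasciotomy + Ray Amputation": 10,
    "Amputation + Flap Reconstruction": 6,
    "Fasciotomy + VAC + Flap Reconstruction": 1,
}
INTERVENTIONS = tuple(INTERVENTION_COUNTS)

CLINICAL_SIGNS = (
    "purulent_discharge",
    "erythema",
    "swelling",
    "gangrene",
    "limited_joint_motion",
)

#: Admission clinical-sign prevalences observed in the study.
SIGN_PREVALENCES = {
    "purulent_discharge": 0.52,
    "erythema": 0.68,
    "swelling": 0.74,
    "gangrene": 0.29,
    "limited_joint_motion": 0.35,
}

STUDY_N = 75
STUDY_SEX_COUNTS = {"female": 11, "male": 64}
STUDY_TYPE2_COUNT = 62
STUDY_YEAR_WINDOW = (2015, 2020)

#: Daily wage used for human-capital incapacity costs (USD, 2020): chosen so
#: that the maximum observed incapacity spell (102 days) prices out near the
#: published maximum (~1002 USD in target-period dollars).
DEFAULT_DAILY_WAGE = 8.54
DEFAULT_WAGE_YEAR = 2020


@dataclass(frozen=True)
class CostItem:
    """One itemised cost line: category, amount in a tagged currency-year."""

    category: str
    amount: float
    currency: str
    year: int

    def __post_init__(self) -> None:
        if self.category not in COST_CATEGORIES:
            raise DataError(f"unknown cost category {self.category!r}")
        if self.amount < 0:
            raise DataError(f"cost amount must be nonnegative, got {self.amount}")


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient: demographics, clinical course, cost lines."""

    patient_id: str
    sex: str
    age_years: float
    diabetes_type: str
    dominant_hand: str
    infected_side: str
    intervention: str
    clinical_signs: frozenset
    hba1c_percent: float
    glucose_mg_dl: float
    sedimentation_mm_h: float
    crp_mg_l: float
    wbc_per_mcl: float
    clinic_days: int
    icu_days: int
    outpatient_visits: int
    incapacity_days: int
    cost_items: tuple = ()

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise DataError(f"{self.patient_id}: invalid sex {self.sex!r}")
        if self.diabetes_type not in ("type1", "type2", "other"):
            raise DataError(
                f"{self.patient_id}: invalid diabetes type {self.diabetes_type!r}"
            )
        for side in (self.dominant_hand, self.infected_side):
            if side not in ("left", "right"):
                raise DataError(f"{self.patient_id}: invalid side {side!r}")
        if self.intervention not in INTERVENTIONS:
            raise DataError(
                f"{self.patient_id}: unknown intervention {self.intervention!r}"
            )
        unknown = set(self.clinical_signs) - set(CLINICAL_SIGNS)
        if unknown:
            raise DataError(f"{self.patient_id}: unknown clinical signs {unknown}")
        if self.outpatient_visits < 1:
            raise DataError(f"{self.patient_id}: outpatient_visits must be >= 1")
        for name in ("clinic_days", "icu_days", "incapacity_days"):
            if getattr(self, name) < 0:
                raise DataError(f"{self.patient_id}: {name} must be nonnegative")
        for name in (
            "age_years",
            "hba1c_percent",
            "glucose_mg_dl",
            "sedimentation_mm_h",
            "crp_mg_l",
            "wbc_per_mcl",
        ):
            if getattr(self, name) < 0:
                raise DataError(f"{self.patient_id}: {name} must be nonnegative")


# ---------------------------------------------------------------------------
# Default distribution specs matched to the published summary tables

def _normal(name, mean, sd, lo, hi):
    return DistributionSpec(
        name, "normal", {"mean": mean, "sd": sd}, bounds=(lo, hi)
    )


def _lognormal(name, mean, sd, lo, hi):
    return DistributionSpec(
        name, "lognormal", {"mean": mean, "sd": sd}, units="USD", bounds=(lo, hi)
    )


def default_lab_specs() -> dict:
    """Admission labs and age: truncated normals pinned to published ranges."""
    return {
        "age_years": _normal("age_years", 57.01, 11.09, 28, 68),
        "hba1c_percent": _normal("hba1c_percent", 8.27, 1.15, 6, 13),
        "glucose_mg_dl": _normal("glucose_mg_dl", 335.81, 88.14, 216, 365),
        "sedimentation_mm_h": _normal("sedimentation_mm_h", 33.75, 10.16, 16, 65),
        "crp_mg_l": _normal("crp_mg_l", 49.83, 15.72, 25, 102),
        "wbc_per_mcl": _normal("wbc_per_mcl", 11440.80, 3151.65, 2400, 19820),
    }


def default_day_specs() -> dict:
    """Lengths of stay and incapacity spells (days).

    Ward stay is a truncated normal; ICU stay and incapacity have median 0
    and heavy right tails, modelled as over-dispersed negative binomials.
    """
    return {
        "clinic_days": _normal("clinic_days", 19.36, 10.45, 0, 48),
        "icu_days": DistributionSpec(
            "icu_days", "negbinom", {"mean": 3.31, "sd": 6.80, "shift": 0},
            bounds=(0, 30),
        ),
        "incapacity_days": DistributionSpec(
            "incapacity_days", "negbinom", {"mean": 7.85, "sd": 21.69, "shift": 0},
            bounds=(0, 102),
        ),
    }


def default_visit_spec() -> DistributionSpec:
    """Outpatient visits: shifted negative binomial, hard floor at 7 visits."""
    return DistributionSpec(
        "outpatient_visits", "negbinom",
        {"mean": 22.29, "sd": 11.01, "shift": 7}, bounds=(7, 59),
    )


def default_cost_specs() -> dict:
    """Direct-cost components on the USD target-period scale.

    Log-normals matched to the published mean/SD and clipped to the printed
    min–max: cost components are nonnegative and right-skewed.
    """
    return {
        "drug": _lognormal("drug", 5542.426, 3519.60, 1006, 19873),
        "clinic_stay": _lognormal("clinic_stay", 6222.64, 4377.76, 400, 18473),
        "icu_stay": _lognormal("icu_stay", 2256.09, 388.44, 800, 18567),
        "outpatient": _lognormal("outpatient", 5162.41, 3838.55, 384, 15635),
        "surgical": _lognormal("surgical", 3607.33, 5290.70, 21, 19407),
    }


@dataclass
class CohortConfig:
    """Configuration for :func:`generate_cohort`.

    In stochastic mode categorical fields are drawn from probabilities and
    continuous fields from the distribution specs; in fixture mode the
    deterministic 75-patient reference cohort is returned.
    """

    n_patients: int = STUDY_N
    mode: str = "stochastic"
    seed: int = 0
    sex_probs: dict = field(
        default_factory=lambda: {"female": 11 / 75, "male": 64 / 75}
    )
    diabetes_probs: dict = field(
        default_factory=lambda: {"type2": 62 / 75, "type1": 13 / 75, "other": 0.0}
    )
    group_probs: dict = field(
        default_factory=lambda: {k: v / 75 for k, v in INTERVENTION_COUNTS.items()}
    )
    sign_prevalences: dict = field(default_factory=lambda: dict(SIGN_PREVALENCES))
    p_right_handed: float = 59 / 75
    p_dominant_infected: float = 58 / 75
    lab_specs: dict = field(default_factory=default_lab_specs)
    day_specs: dict = field(default_factory=default_day_specs)
    visit_spec: DistributionSpec = field(default_factory=default_visit_spec)
    cost_specs: dict = field(default_factory=default_cost_specs)
    daily_wage: float = DEFAULT_DAILY_WAGE
    wage_year: int = DEFAULT_WAGE_YEAR
    year_window: tuple = STUDY_YEAR_WINDOW
    tables: ConversionTables | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be nonnegative")
        if self.mode not in ("stochastic", "fixture"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        for name, probs in (
            ("sex_probs", self.sex_probs),
            ("diabetes_probs", self.diabetes_probs),
            ("group_probs", self.group_probs),
            ("sign_prevalences", self.sign_prevalences),
        ):
            for key, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"{name}[{key!r}] = {p} outside [0, 1]"
                    )
        for p in (self.p_right_handed, self.p_dominant_infected):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("hand probabilities must lie in [0, 1]")
        unknown = set(self.group_probs) - set(INTERVENTIONS)
        if unknown:
            raise ConfigurationError(f"unknown intervention labels {unknown}")
        if self.mode == "fixture" and self.n_patients != STUDY_N:
            raise ConfigurationError(
                f"fixture mode is defined for n_patients={STUDY_N}"
            )


def study_config(
    n_patients: int = STUDY_N, seed: int = 0, mode: str = "stochastic"
) -> CohortConfig:
    """Config pre-filled with every published study prevalence and summary."""
    return CohortConfig(n_patients=n_patients, seed=seed, mode=mode)


# ---------------------------------------------------------------------------
# Stochastic generation

def _usd_to_nominal_try(usd, year, tables):
    """Back-convert a target-period USD value to nominal TRY of ``year``."""
    cpi = tables.cpi
    return usd * tables.fx[year] * cpi[str(year)] / cpi[tables.target_period]


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate a cohort; deterministic given ``config.seed``.

    All draws come from a single seeded generator in a fixed, documented
    order (sex, labs, diabetes type, handedness, intervention, signs, days,
    visits, cost years, cost amounts), so cohorts are bit-reproducible.
    """
    if config.mode == "fixture":
        return build_reference_fixture()
    n = config.n_patients
    if n == 0:
        return []
    tables = config.tables if config.tables is not None else packaged_tables()
    rng = np.random.default_rng(config.seed)

    p_female = config.sex_probs.get("female", 0.0)
    sex = np.where(rng.random(n) < p_female, "female", "male")

    labs = {k: draw(spec, rng, n) for k, spec in config.lab_specs.items()}

    diab_labels = list(config.diabetes_probs)
    diab_p = np.array([config.diabetes_probs[k] for k in diab_labels], dtype=float)
    if abs(diab_p.sum() - 1.0) > 1e-9:
        raise ConfigurationError("diabetes_probs must sum to 1")
    diabetes = rng.choice(diab_labels, size=n, p=diab_p)

    dominant = np.where(rng.random(n) < config.p_right_handed, "right", "left")
    dom_infected = rng.random(n) < config.p_dominant_infected
    infected = np.where(
        dom_infected, dominant,
        np.where(dominant == "right", "left", "right"),
    )

    grp_labels = list(config.group_probs)
    grp_p = np.array([config.group_probs[k] for k in grp_labels], dtype=float)
    if abs(grp_p.sum() - 1.0) > 1e-9:
        raise ConfigurationError("group_probs must sum to 1")
    intervention = rng.choice(grp_labels, size=n, p=grp_p)

    sign_flags = {
        s: rng.random(n) < config.sign_prevalences.get(s, 0.0)
        for s in CLINICAL_SIGNS
    }

    days = {
        k: np.rint(draw(config.day_specs[k], rng, n)).astype(int)
        for k in ("clinic_days", "icu_days", "incapacity_days")
    }
    visits = np.rint(draw(config.visit_spec, rng, n)).astype(int)
    visits = np.maximum(visits, 1)

    lo_year, hi_year = config.year_window
    item_years = rng.integers(lo_year, hi_year + 1, size=n)
    usd_draws = {
        cat: draw(spec, rng, n) for cat, spec in config.cost_specs.items()
    }

    records = []
    for i in range(n):
        year = int(item_years[i])
        items = []
        for cat in ("drug", "clinic_stay", "icu_stay", "outpatient", "surgical"):
            if cat not in usd_draws:
                continue
            usd = float(usd_draws[cat][i])
            if cat == "icu_stay" and days["icu_days"][i] == 0:
                usd = 0.0
            if cat == "clinic_stay" and days["clinic_days"][i] == 0:
                usd = 0.0
            items.append(
                CostItem(cat, round(_usd_to_nominal_try(usd, year, tables), 2),
                         "TRY", year)
            )
        items.append(
            CostItem(
                "incapacity",
                round(float(days["incapacity_days"][i]) * config.daily_wage, 2),
                "USD",
                config.wage_year,
            )
        )
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:05d}",
                sex=str(sex[i]),
                age_years=round(float(labs["age_years"][i]), 2),
                diabetes_type=str(diabetes[i]),
                dominant_hand=str(dominant[i]),
                infected_side=str(infected[i]),
                intervention=str(intervention[i]),
                clinical_signs=frozenset(
                    s for s in CLINICAL_SIGNS if sign_flags[s][i]
                ),
                hba1c_percent=round(float(labs["hba1c_percent"][i]), 2),
                glucose_mg_dl=round(float(labs["glucose_mg_dl"][i]), 2),
                sedimentation_mm_h=round(float(labs["sedimentation_mm_h"][i]), 2),
                crp_mg_l=round(float(labs["crp_mg_l"][i]), 2),
                wbc_per_mcl=round(float(labs["wbc_per_mcl"][i]), 2),
                clinic_days=int(days["clinic_days"][i]),
                icu_days=int(days["icu_days"][i]),
                outpatient_visits=int(visits[i]),
                incapacity_days=int(days["incapacity_days"][i]),
                cost_items=tuple(items),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Deterministic reference fixture

def _spread(lo: float, med: float, hi: float, n: int = STUDY_N) -> list[float]:
    """Sorted deterministic values with exact min, median and max."""
    mid = (n - 1) // 2
    lower = [lo + (med - lo) * i / mid for i in range(mid + 1)]
    upper = [med + (hi - med) * (i - mid) / (n - 1 - mid) for i in range(mid + 1, n)]
    return lower + upper


def _perm(stride: int, offset: int = 0, n: int = STUDY_N) -> list[int]:
    # stride coprime to n gives a bijection on 0..n-1
    return [(i * stride + offset) % n for i in range(n)]


def _assign(sorted_values, stride, offset=0):
    perm = _perm(stride, offset)
    return [sorted_values[perm[i]] for i in range(STUDY_N)]


def _fixture_visits() -> list[int]:
    # 60 values spanning 7..29 (sorted index 37 pinned at the median 20)
    # plus 15 values spanning 30..59 — exactly 15 patients at >= 30 visits.
    lower = [7 + (i * 22) // 59 for i in range(60)]
    upper = [30 + (j * 29) // 14 for j in range(15)]
    return lower + upper


def build_reference_fixture() -> list[PatientRecord]:
    """The deterministic 75-patient reference cohort (no RNG involved).

    Every published marginal count is reproduced exactly; continuous fields
    are deterministic spreads pinned to each published median and min–max,
    assigned across patients through fixed coprime-stride permutations so
    fields are not artificially co-monotone.
    """
    n = STUDY_N
    tables = packaged_tables()

    interventions: list[str] = []
    for label, count in INTERVENTION_COUNTS.items():
        interventions.extend([label] * count)

    female_idx = set(_perm(7)[:11])
    type1_idx = set(_perm(11, 3)[:13])

    # Handedness joint counts: (right-handed, right infected) 48,
    # (right, left) 11, (left, right) 6, (left, left) 10 — so 59 are
    # right-handed and the dominant hand is infected in 58 of 75.
    hand_order = _perm(13, 2)
    dominant = [""] * n
    infected = [""] * n
    for rank, i in enumerate(hand_order):
        if rank < 48:
            dominant[i], infected[i] = "right", "right"
        elif rank < 59:
            dominant[i], infected[i] = "right", "left"
        elif rank < 65:
            dominant[i], infected[i] = "left", "right"
        else:
            dominant[i], infected[i] = "left", "left"

    sign_members = {}
    sign_strides = (7, 19, 31, 43, 53)  # each coprime to 75
    for k, (sign, prev) in enumerate(SIGN_PREVALENCES.items()):
        count = int(round(prev * n))
        sign_members[sign] = set(_perm(sign_strides[k], 5 * k)[:count])

    age = _assign(_spread(28, 62, 68), 7)
    hba1c = _assign(_spread(6, 8.30, 13), 11)
    glucose = _assign(_spread(216, 324.0, 365), 13)
    sed = _assign(_spread(16, 34.0, 65), 17)
    crp = _assign(_spread(25, 50.0, 102), 19)
    wbc = _assign(_spread(2400, 11440.0, 19820), 23)

    clinic_days_sorted = [int(round(v)) for v in _spread(0, 21, 48)]
    clinic_days = _assign(clinic_days_sorted, 29)
    # ICU: 50 patients never admitted; 25 stays spread over 1..30 days.
    icu_days_sorted = [0] * 50 + [
        int(round(1 + 29 * j / 24)) for j in range(25)
    ]
    icu_days = _assign(icu_days_sorted, 41)
    incap_sorted = [0] * 57 + [int(round(6 + 96 * j / 17)) for j in range(18)]
    incapacity_days = _assign(incap_sorted, 43)
    visits = _assign(_fixture_visits(), 29, 5)

    drug_usd = _assign(_spread(1006, 4473.0, 19873), 37)
    # clinic / ICU costs share the day permutations: zero days, zero cost
    clinic_usd_sorted = _spread(400, 5534.0, 18473)
    clinic_usd = _assign(clinic_usd_sorted, 29)
    icu_usd_sorted = [0.0] * 50 + [800 + (18567 - 800) * j / 24 for j in range(25)]
    icu_usd = _assign(icu_usd_sorted, 41)
    outpatient_usd = _assign(_spread(384, 4382.0, 15635), 29, 5)
    surgical_usd = _assign(_spread(21, 521.0, 19407), 47)

    records = []
    for i in range(n):
        year = 2015 + (i % 6)
        clinic_cost = 0.0 if clinic_days[i] == 0 else clinic_usd[i]
        items = tuple(
            CostItem(cat, round(_usd_to_nominal_try(usd, year, tables), 2),
                     "TRY", year)
            for cat, usd in (
                ("drug", drug_usd[i]),
                ("clinic_stay", clinic_cost),
                ("icu_stay", icu_usd[i]),
                ("outpatient", outpatient_usd[i]),
                ("surgical", surgical_usd[i]),
            )
        ) + (
            CostItem(
                "incapacity",
                round(incapacity_days[i] * DEFAULT_DAILY_WAGE, 2),
                "USD",
                DEFAULT_WAGE_YEAR,
            ),
        )
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:05d}",
                sex="female" if i in female_idx else "male",
                age_years=round(age[i], 2),
                diabetes_type="type1" if i in type1_idx else "type2",
                dominant_hand=dominant[i],
                infected_side=infected[i],
                intervention=interventions[i],
                clinical_signs=frozenset(
                    s for s in CLINICAL_SIGNS if i in sign_members[s]
                ),
                hba1c_percent=round(hba1c[i], 2),
                glucose_mg_dl=round(glucose[i], 2),
                sedimentation_mm_h=round(sed[i], 2),
                crp_mg_l=round(crp[i], 2),
                wbc_per_mcl=round(wbc[i], 2),
                clinic_days=clinic_days[i],
                icu_days=icu_days[i],
                outpatient_visits=visits[i],
                incapacity_days=incapacity_days[i],
                cost_items=items,
            )
        )
    return records


# ---------------------------------------------------------------------------
# CSV round-trip

_CSV_FIELDS = [
    "patient_id", "sex", "age_years", "diabetes_type", "dominant_hand",
    "infected_side", "intervention", "clinical_signs", "hba1c_percent",
    "glucose_mg_dl", "sedimentation_mm_h", "crp_mg_l", "wbc_per_mcl",
    "clinic_days", "icu_days", "outpatient_visits", "incapacity_days",
    "cost_category", "cost_amount", "cost_currency", "cost_year",
]

_FLOAT_FIELDS = (
    "age_years", "hba1c_percent", "glucose_mg_dl",
    "sedimentation_mm_h", "crp_mg_l", "wbc_per_mcl",
)
_INT_FIELDS = ("clinic_days", "icu_days", "outpatient_visits", "incapacity_days")


def write_cohort(cohort: list[PatientRecord], path: str | Path) -> None:
    """Write one row per (patient, cost item); amounts with 2 decimals."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for rec in cohort:
            base = [
                rec.patient_id, rec.sex, repr(rec.age_years), rec.diabetes_type,
                rec.dominant_hand, rec.infected_side, rec.intervention,
                ";".join(sorted(rec.clinical_signs)), repr(rec.hba1c_percent),
                repr(rec.glucose_mg_dl), repr(rec.sedimentation_mm_h),
                repr(rec.crp_mg_l), repr(rec.wbc_per_mcl), rec.clinic_days,
                rec.icu_days, rec.outpatient_visits, rec.incapacity_days,
            ]
            if not rec.cost_items:
                writer.writerow(base + ["", "", "", ""])
            for item in rec.cost_items:
                writer.writerow(
                    base + [item.category, f"{item.amount:.2f}",
                            item.currency, item.year]
                )


def read_cohort(
    path: str | Path, year_window: tuple = STUDY_YEAR_WINDOW
) -> list[PatientRecord]:
    """Read a cohort CSV; ``read(write(c)) == c`` field for field.

    Raises :class:`DataError` naming the offending row for unknown
    intervention labels, negative amounts, or years outside the window.
    """
    records: list[PatientRecord] = []
    current_id = None
    current: dict = {}
    items: list[CostItem] = []

    def flush():
        if current_id is not None:
            records.append(PatientRecord(cost_items=tuple(items), **current))

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _CSV_FIELDS:
            raise DataError(f"{path}: unexpected cohort CSV header")
        for lineno, row in enumerate(reader, start=2):
            try:
                fields = {
                    "patient_id": row["patient_id"],
                    "sex": row["sex"],
                    "diabetes_type": row["diabetes_type"],
                    "dominant_hand": row["dominant_hand"],
                    "infected_side": row["infected_side"],
                    "intervention": row["intervention"],
                    "clinical_signs": frozenset(
                        s for s in row["clinical_signs"].split(";") if s
                    ),
                }
                for f in _FLOAT_FIELDS:
                    fields[f] = float(row[f])
                for f in _INT_FIELDS:
                    fields[f] = int(row[f])
                if row["cost_category"]:
                    amount = float(row["cost_amount"])
                    year = int(row["cost_year"])
                    if not year_window[0] <= year <= year_window[1]:
                        # the wage year may legitimately sit at the window edge
                        raise DataError(
                            f"cost year {year} outside window {year_window}"
                        )
                    item = CostItem(
                        row["cost_category"], amount, row["cost_currency"], year
                    )
                else:
                    item = None
                if fields["patient_id"] != current_id:
                    flush()
                    current_id = fields["patient_id"]
                    current = fields
                    items = []
                if item is not None:
                    items.append(item)
            except (DataError, ValueError) as exc:
                raise DataError(f"{path}, row {lineno}: {exc}") from None
    flush()
    return records
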