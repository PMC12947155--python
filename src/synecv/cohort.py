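"""Synthetic patient-cohort generator.

The clinical data behind the synHct/synECV calibration study are not publicly
deposited, so this module generates cohorts with the statistical structure the
analysis assumes, calibrated to the printed cohort summaries: 75 male and 33
female patients, per-sex BMI/age/eGFR/creatinine distributions, a cohort mean
serum haematocrit of 0.40 (fraction) and a median ground-truth LV ECV of 0.32.

The generator *inverts* the fitted calibration family: each (sex, BMI)
subgroup carries a true line ``Hct% = slope * HU_blood + intercept`` plus
Gaussian residual noise.  Blood-pool HU means are obtained by inverting the
line at the subgroup's target mean Hct-percent; HU spread and residual SD are
solved from the target R^2 and the target Hct-percent SD:

    var(signal) = R^2 * var(Hct%)   =>  hu_sd  = hct_sd * sqrt(R^2) / |slope|
    var(noise)  = (1-R^2) * var(Hct%) => eps_sd = hct_sd * sqrt(1 - R^2)

Females with BMI below 22.4 kg/m^2 keep the same line with a deliberately
inflated residual SD, emulating the subgroup in which no significant
calibration relationship could be established.

Units: serum haematocrit and ECV are stored as *fractions* in patient tables;
all regression lines operate in Hct-*percent*.  Demographics not tied to the
calibration (age, eGFR, creatinine) are drawn independently of haematocrit,
encoding the study's null result for those covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import DomainError, ValidationError

__all__ = [
    "PatientRecord",
    "SubgroupSpec",
    "SexDemographics",
    "CohortSpec",
    "default_cohort_spec",
    "load_cohort_spec",
    "spec_from_dict",
    "spec_to_dict",
    "generate_cohort",
    "generate_subgroup",
    "write_cohort",
    "read_cohort",
    "iter_records",
]

_Z75 = float(stats.norm.ppf(0.75))  # 0.6745: IQR of a standard normal is 2 * _Z75

COHORT_COLUMNS = [
    "patient_id",
    "sex",
    "age",
    "bmi",
    "egfr",
    "creatinine",
    "hct",
    "hu_blood",
    "ecv_true",
    "dhu_blood",
    "dhu_myo",
    "subgroup",
]


@dataclass(frozen=True)
class PatientRecord:
    """One subject: demographics, serum haematocrit (fraction) and mean
    baseline blood-pool attenuation (HU)."""

    patient_id: str
    sex: str
    age: float
    bmi: float
    egfr: float
    creatinine: float
    hct: float
    hu_blood: float
    ecv_true: Optional[float] = None
    dhu_blood: Optional[float] = None
    dhu_myo: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not 0.0 < self.hct < 1.0:
            raise ValidationError(f"hct must lie in (0, 1), got {self.hct}")
        if not self.bmi > 0:
            raise ValidationError(f"bmi must be positive, got {self.bmi}")
        if not math.isfinite(self.hu_blood):
            raise ValidationError("hu_blood must be finite")
        if self.ecv_true is not None and not 0.0 < self.ecv_true < 1.0:
            raise ValidationError(f"ecv_true must lie in (0, 1), got {self.ecv_true}")


@dataclass(frozen=True)
class SubgroupSpec:
    """Generative truth for one (sex, BMI-interval) subgroup.

    ``slope``/``intercept`` define the true HU_blood -> Hct-percent line;
    ``hu_mean``/``hu_sd`` the Gaussian blood-pool HU distribution; ``eps_sd``
    the Gaussian residual SD of Hct-percent around the line.
    """

    name: str
    sex: str
    bmi_low: float
    bmi_high: float
    slope: float
    intercept: float
    hu_mean: float
    hu_sd: float
    eps_sd: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"subgroup {self.name}: sex must be 'male' or 'female'")
        if not self.bmi_low < self.bmi_high:
            raise ValidationError(f"subgroup {self.name}: bmi_low must be < bmi_high")
        if self.hu_sd < 0:
            raise ValidationError(f"subgroup {self.name}: hu_sd must be >= 0, got {self.hu_sd}")
        if self.eps_sd < 0:
            raise ValidationError(f"subgroup {self.name}: eps_sd must be >= 0, got {self.eps_sd}")

    @property
    def implied_r_squared(self) -> float:
        """R^2 implied by the signal/noise split, slope^2 var(HU) / var(Hct%)."""
        signal = (self.slope * self.hu_sd) ** 2
        total = signal + self.eps_sd**2
        return signal / total if total > 0 else 0.0

    @classmethod
    def calibrated(
        cls,
        name: str,
        sex: str,
        bmi_low: float,
        bmi_high: float,
        slope: float,
        intercept: float,
        mean_hct_pct: float,
        sd_hct_pct: float,
        r_squared: float,
    ) -> "SubgroupSpec":
        """Solve (hu_mean, hu_sd, eps_sd) from target mean/SD Hct% and R^2."""
        if not 0.0 < r_squared < 1.0:
            raise ValidationError(f"subgroup {name}: r_squared must lie in (0, 1)")
        if slope == 0:
            raise ValidationError(f"subgroup {name}: slope must be nonzero to calibrate")
        return cls(
            name=name,
            sex=sex,
            bmi_low=bmi_low,
            bmi_high=bmi_high,
            slope=slope,
            intercept=intercept,
            hu_mean=(mean_hct_pct - intercept) / slope,
            hu_sd=sd_hct_pct * math.sqrt(r_squared) / abs(slope),
            eps_sd=sd_hct_pct * math.sqrt(1.0 - r_squared),
        )


@dataclass(frozen=True)
class SexDemographics:
    """Per-sex distribution parameters for non-modelled demographics.

    Medians/IQRs follow log-normal (BMI, creatinine) or normal (age)
    conventions; eGFR is normal from mean/SD.  Hct-percent mean/SD are the
    targets the subgroup calibration solves against.
    """

    bmi_median: float
    bmi_iqr: float
    age_median: float
    age_iqr: float
    egfr_mean: float
    egfr_sd: float
    creatinine_median: float
    creatinine_iqr: float
    hct_mean_pct: float
    hct_sd_pct: float

    def __post_init__(self) -> None:
        for name in ("bmi_iqr", "age_iqr", "egfr_sd", "creatinine_iqr", "hct_sd_pct"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.bmi_median <= 0 or self.creatinine_median <= 0:
            raise ValidationError("bmi_median and creatinine_median must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Full generative specification of a synthetic cohort."""

    n_male: int
    n_female: int
    demographics: dict  # sex -> SexDemographics
    subgroups: tuple  # tuple[SubgroupSpec, ...]
    ecv_median: float = 0.32
    ecv_iqr: float = 0.05
    dhu_blood_mean: float = 60.0
    dhu_blood_sd: float = 8.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "subgroups", tuple(self.subgroups))
        if self.n_male < 0 or self.n_female < 0 or self.n_male + self.n_female == 0:
            raise ValidationError("n_male + n_female must be positive")
        if self.ecv_iqr < 0:
            raise ValidationError(f"ecv_iqr must be >= 0, got {self.ecv_iqr}")
        if self.dhu_blood_sd < 0:
            raise ValidationError(f"dhu_blood_sd must be >= 0, got {self.dhu_blood_sd}")
        if not 0 < self.ecv_median < 1:
            raise ValidationError(f"ecv_median must lie in (0, 1), got {self.ecv_median}")
        for sex in ("male", "female"):
            if sex not in self.demographics:
                raise ValidationError(f"demographics missing entry for sex {sex!r}")
        for sex in ("male", "female"):
            covered = [g for g in self.subgroups if g.sex == sex]
            if not covered:
                raise ValidationError(f"no subgroup covers sex {sex!r}")

    def subgroup_for(self, sex: str, bmi: float) -> SubgroupSpec:
        """Subgroup owning a (sex, bmi) pair; BMI exactly on a boundary goes up."""
        for g in self.subgroups:
            if g.sex == sex and g.bmi_low <= bmi < g.bmi_high:
                return g
        raise ValidationError(f"no subgroup covers sex={sex!r}, bmi={bmi}")

    def subgroup(self, name: str) -> SubgroupSpec:
        for g in self.subgroups:
            if g.name == name:
                return g
        raise ValidationError(f"unknown subgroup {name!r}")


# ---------------------------------------------------------------------------
# spec <-> dict / YAML


def _lognormal_sigma(median: float, iqr: float) -> float:
    # IQR of lognormal(mu, sigma) is median * (e^{z75 s} - e^{-z75 s}) = 2 median sinh(z75 s)
    return math.asinh(iqr / (2.0 * median)) / _Z75


def spec_from_dict(payload: dict) -> CohortSpec:
    demo = {}
    for sex in ("male", "female"):
        d = payload["demographics"][sex]
        demo[sex] = SexDemographics(
            bmi_median=d["bmi"]["median"],
            bmi_iqr=d["bmi"]["iqr"],
            age_median=d["age"]["median"],
            age_iqr=d["age"]["iqr"],
            egfr_mean=d["egfr"]["mean"],
            egfr_sd=d["egfr"]["sd"],
            creatinine_median=d["creatinine"]["median"],
            creatinine_iqr=d["creatinine"]["iqr"],
            hct_mean_pct=d["hct_pct"]["mean"],
            hct_sd_pct=d["hct_pct"]["sd"],
        )
    def _bound(g, key, default):
        value = g.get(key)
        return default if value is None else value

    raw_groups = payload["subgroups"]
    by_name: dict[str, SubgroupSpec] = {}
    deferred = []
    for g in raw_groups:
        sex = g["sex"]
        lo = _bound(g, "bmi_low", -math.inf)
        hi = _bound(g, "bmi_high", math.inf)
        if "r_squared" in g:
            by_name[g["name"]] = SubgroupSpec.calibrated(
                g["name"], sex, lo, hi, g["slope"], g["intercept"],
                demo[sex].hct_mean_pct, demo[sex].hct_sd_pct, g["r_squared"],
            )
        elif "eps_sd" in g:
            deferred.append(g)
        else:
            raise ValidationError(f"subgroup {g['name']}: give either r_squared or eps_sd")
    for g in deferred:
        if "hu_mean" in g and "hu_sd" in g:
            hu_mean, hu_sd = g["hu_mean"], g["hu_sd"]
        elif "hu_from" in g:
            ref = by_name.get(g["hu_from"])
            if ref is None:
                raise ValidationError(f"subgroup {g['name']}: hu_from references unknown subgroup")
            hu_mean, hu_sd = ref.hu_mean, ref.hu_sd
        else:
            raise ValidationError(f"subgroup {g['name']}: give hu_mean/hu_sd or hu_from")
        by_name[g["name"]] = SubgroupSpec(
            name=g["name"],
            sex=g["sex"],
            bmi_low=_bound(g, "bmi_low", -math.inf),
            bmi_high=_bound(g, "bmi_high", math.inf),
            slope=g["slope"],
            intercept=g["intercept"],
            hu_mean=hu_mean,
            hu_sd=hu_sd,
            eps_sd=g["eps_sd"],
        )
    subgroups = tuple(by_name[g["name"]] for g in raw_groups)
    return CohortSpec(
        n_male=payload["n_male"],
        n_female=payload["n_female"],
        demographics=demo,
        subgroups=subgroups,
        ecv_median=payload.get("ecv", {}).get("median", 0.32),
        ecv_iqr=payload.get("ecv", {}).get("iqr", 0.05),
        dhu_blood_mean=payload.get("dhu_blood", {}).get("mean", 60.0),
        dhu_blood_sd=payload.get("dhu_blood", {}).get("sd", 8.0),
    )


def spec_to_dict(spec: CohortSpec) -> dict:
    """Fully resolved form (subgroups carry explicit hu_mean/hu_sd/eps_sd)."""
    return {
        "n_male": spec.n_male,
        "n_female": spec.n_female,
        "demographics": {
            sex: {
                "bmi": {"median": d.bmi_median, "iqr": d.bmi_iqr},
                "age": {"median": d.age_median, "iqr": d.age_iqr},
                "egfr": {"mean": d.egfr_mean, "sd": d.egfr_sd},
                "creatinine": {"median": d.creatinine_median, "iqr": d.creatinine_iqr},
                "hct_pct": {"mean": d.hct_mean_pct, "sd": d.hct_sd_pct},
            }
            for sex, d in spec.demographics.items()
        },
        "ecv": {"median": spec.ecv_median, "iqr": spec.ecv_iqr},
        "dhu_blood": {"mean": spec.dhu_blood_mean, "sd": spec.dhu_blood_sd},
        "subgroups": [
            {
                "name": g.name,
                "sex": g.sex,
                "bmi_low": None if math.isinf(g.bmi_low) else g.bmi_low,
                "bmi_high": None if math.isinf(g.bmi_high) else g.bmi_high,
                "slope": g.slope,
                "intercept": g.intercept,
                "hu_mean": g.hu_mean,
                "hu_sd": g.hu_sd,
                "eps_sd": g.eps_sd,
            }
            for g in spec.subgroups
        ],
    }


def load_cohort_spec(path) -> CohortSpec:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return spec_from_dict(payload)


def default_cohort_spec() -> CohortSpec:
    """The packaged specification reproducing the study's cohort summaries."""
    text = resources.files("synecv").joinpath("data/default_cohort.yaml").read_text()
    return spec_from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# generation


def _draw_lognormal(rng, median, iqr, n):
    if iqr == 0:
        return np.full(n, median, dtype=float)
    sigma = _lognormal_sigma(median, iqr)
    return np.exp(rng.normal(math.log(median), sigma, n))


def _draw_normal_median_iqr(rng, median, iqr, n):
    return rng.normal(median, iqr / (2.0 * _Z75) if iqr else 0.0, n)


def _draw_truncated(rng, draw, low, high, n, max_rounds=1000):
    """Rejection-sample ``draw(k)`` into the half-open interval [low, high)."""
    out = np.empty(n, dtype=float)
    filled = 0
    for _ in range(max_rounds):
        cand = draw(max(n - filled, 16))
        keep = cand[(cand >= low) & (cand < high)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
        if filled == n:
            return out
    raise ValidationError(f"could not sample interval [{low}, {high}) — is it too narrow?")


def _generate_sex(rng, spec: CohortSpec, sex: str, n: int, bmi: Optional[np.ndarray] = None):
    demo = spec.demographics[sex]
    if bmi is None:
        bmi = _draw_lognormal(rng, demo.bmi_median, demo.bmi_iqr, n)
    age = _draw_normal_median_iqr(rng, demo.age_median, demo.age_iqr, n)
    egfr = np.clip(rng.normal(demo.egfr_mean, demo.egfr_sd, n), 5.0, None)
    creat = _draw_lognormal(rng, demo.creatinine_median, demo.creatinine_iqr, n)
    ecv = np.clip(
        _draw_normal_median_iqr(rng, spec.ecv_median, spec.ecv_iqr, n), 0.01, 0.99
    )
    dhu_blood = np.clip(rng.normal(spec.dhu_blood_mean, spec.dhu_blood_sd, n), 20.0, None)

    hu = np.empty(n)
    hct_pct = np.empty(n)
    groups = [spec.subgroup_for(sex, b) for b in bmi]
    names = np.array([g.name for g in groups])
    for g in {id(g): g for g in groups}.values():
        idx = np.flatnonzero(names == g.name)
        hu[idx] = rng.normal(g.hu_mean, g.hu_sd, idx.size)
        hct_pct[idx] = g.slope * hu[idx] + g.intercept + rng.normal(0.0, g.eps_sd, idx.size)
        # keep serum haematocrit physically meaningful: redraw residuals that
        # would push Hct outside (1%, 99%); only relevant at inflated eps_sd
        bad = idx[(hct_pct[idx] <= 1.0) | (hct_pct[idx] >= 99.0)]
        while bad.size:
            hct_pct[bad] = g.slope * hu[bad] + g.intercept + rng.normal(0.0, g.eps_sd, bad.size)
            bad = bad[(hct_pct[bad] <= 1.0) | (hct_pct[bad] >= 99.0)]

    hct = hct_pct / 100.0
    dhu_myo = ecv * dhu_blood / (1.0 - hct)
    return pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "egfr": egfr,
            "creatinine": creat,
            "hct": hct,
            "hu_blood": hu,
            "ecv_true": ecv,
            "dhu_blood": dhu_blood,
            "dhu_myo": dhu_myo,
            "subgroup": names,
        }
    )


def generate_cohort(
    spec: CohortSpec,
    seed: int,
    n_male: Optional[int] = None,
    n_female: Optional[int] = None,
) -> pd.DataFrame:
    """Generate a patient table with exact per-sex counts.

    All randomness flows from ``seed`` through one ``numpy`` generator; the
    same (spec, seed) pair always yields an identical table.  ``n_male`` /
    ``n_female`` override the spec's counts (e.g. for large-n calibration
    checks) without touching any distributional parameter.
    """
    rng = np.random.default_rng(seed)
    nm = spec.n_male if n_male is None else int(n_male)
    nf = spec.n_female if n_female is None else int(n_female)
    if nm < 0 or nf < 0 or nm + nf == 0:
        raise ValidationError("n_male + n_female must be positive")
    parts = []
    if nm:
        parts.append(_generate_sex(rng, spec, "male", nm))
    if nf:
        parts.append(_generate_sex(rng, spec, "female", nf))
    frame = pd.concat(parts, ignore_index=True)
    width = max(4, len(str(len(frame))))
    frame.insert(0, "patient_id", [f"P{i + 1:0{width}d}" for i in range(len(frame))])
    return frame[COHORT_COLUMNS]


def generate_subgroup(spec: CohortSpec, name: str, n: int, seed: int) -> pd.DataFrame:
    """Generate ``n`` records from a single subgroup (BMI truncated to its range)."""
    g = spec.subgroup(name)
    rng = np.random.default_rng(seed)
    demo = spec.demographics[g.sex]
    bmi = _draw_truncated(
        rng,
        lambda k: _draw_lognormal(rng, demo.bmi_median, demo.bmi_iqr, k),
        g.bmi_low,
        g.bmi_high,
        n,
    )
    frame = _generate_sex(rng, spec, g.sex, n, bmi=bmi)
    width = max(4, len(str(len(frame))))
    frame.insert(0, "patient_id", [f"P{i + 1:0{width}d}" for i in range(len(frame))])
    return frame[COHORT_COLUMNS]


# ---------------------------------------------------------------------------
# I/O and record views


def write_cohort(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"patient_id", "sex", "hct", "hu_blood"} - set(frame.columns)
    if missing:
        raise ValidationError(f"cohort CSV missing required columns: {sorted(missing)}")
    bad_sex = set(frame["sex"].unique()) - {"male", "female"}
    if bad_sex:
        raise ValidationError(f"sex column contains values other than male/female: {sorted(bad_sex)}")
    return frame


def iter_records(frame: pd.DataFrame):
    """Yield :class:`PatientRecord` views of a cohort table."""
    optional = [c for c in ("ecv_true", "dhu_blood", "dhu_myo") if c in frame.columns]
    for row in frame.itertuples(index=False):
        yield PatientRecord(
            patient_id=str(row.patient_id),
            sex=row.sex,
            age=float(row.age),
            bmi=float(row.bmi),
            egfr=float(row.egfr),
            creatinine=float(row.creatinine),
            hct=float(row.hct),
            hu_blood=float(row.hu_blood),
            **{name: float(getattr(row, name)) for name in optional},
        )
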