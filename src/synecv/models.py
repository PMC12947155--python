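"""Linear blood-pool-attenuation -> haematocrit models.

A synthetic haematocrit (synHct) model maps the mean pre-contrast Hounsfield
units of the left-ventricular blood pool (``hu_blood``) to a haematocrit value
in **percent** (a model evaluated at HU ~ 50 returns synHct ~ 40, i.e. 40%).
Serum haematocrit in patient tables is stored as a *fraction*; the conversion
(divide by 100) happens only at the boundary where a model prediction is
combined with fractional quantities such as ECV.

Three kinds of model live here:

* :class:`LinearHctModel` -- a single ``slope * HU + intercept`` calibration
  line, either published or freshly fitted by :func:`fit_linear`;
* :class:`StratifiedHctModel` -- an ordered routing table of
  ``(ModelPredicate, LinearHctModel)`` pairs dispatching on patient sex and
  body-mass index, with a configurable fallback for uncovered subgroups;
* :func:`published_models` -- the published calibration family: a literature
  model, a single-cohort baseline refit, the three sex- and BMI-specific
  lines, and the combined dispatcher assembled from them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, DomainError, InsufficientDataError, ValidationError

__all__ = [
    "LinearHctModel",
    "ModelPredicate",
    "StratifiedHctModel",
    "predict_hct",
    "fit_linear",
    "route",
    "published_models",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class LinearHctModel:
    """A straight-line HU_blood -> Hct-percent calibration.

    Parameters
    ----------
    slope : float
        Hct-percent per Hounsfield unit.
    intercept : float
        Hct-percent at HU = 0.
    label : str
        Human-readable name ("literature", "baseline", ...).
    n_fit : int
        Number of points used to fit the model; 0 for published coefficients.
    r_squared : float, optional
        Coefficient of determination of the fit, in [0, 1].
    slope_se, intercept_se : float, optional
        Standard errors of the fitted coefficients (``None`` for published
        models).
    """

    slope: float
    intercept: float
    label: str = ""
    n_fit: int = 0
    r_squared: Optional[float] = None
    slope_se: Optional[float] = None
    intercept_se: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValidationError("slope and intercept must be finite")
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    def predict(self, hu_blood):
        """Predicted haematocrit in percent; see :func:`predict_hct`."""
        return predict_hct(self, hu_blood)


def predict_hct(model: LinearHctModel, hu_blood):
    """Evaluate ``slope * hu_blood + intercept`` (Hct in percent).

    Accepts a scalar or array of Hounsfield units.  Predictions are *not*
    clamped to a physiological range: a caller that cares about plausibility
    should flag out-of-range outputs itself.
    """
    hu = np.asarray(hu_blood, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise DomainError("hu_blood must be finite")
    out = model.slope * hu + model.intercept
    return float(out) if np.isscalar(hu_blood) or out.ndim == 0 else out


def fit_linear(x, y, label: str = "fitted") -> LinearHctModel:
    """Ordinary-least-squares fit of Hct-percent on HU_blood.

    Two distinct points define the interpolating line (R^2 = 1); a constant
    ``x`` raises :class:`DegenerateDesignError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be one-dimensional arrays of equal length")
    if x.size < 2:
        raise InsufficientDataError(f"need at least 2 points to fit a line, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("x is constant; slope is unidentifiable")
    res = stats.linregress(x, y)
    return LinearHctModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        label=label,
        n_fit=int(x.size),
        r_squared=float(min(res.rvalue**2, 1.0)),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
    )


@dataclass(frozen=True)
class ModelPredicate:
    """Sex/BMI membership test for one route of a stratified model.

    The BMI interval is half-open, ``[bmi_low, bmi_high)``: a record whose BMI
    sits exactly on a published threshold (30.7 for males, 22.4 for females)
    routes to the *upper* bin.  ``sex="any"`` matches both sexes.
    """

    sex: str = "any"  # "male" | "female" | "any"
    bmi_low: float = -math.inf
    bmi_high: float = math.inf

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "any"):
            raise ValidationError(f"sex must be 'male', 'female' or 'any', got {self.sex!r}")
        if not self.bmi_low < self.bmi_high:
            raise ValidationError(f"bmi_low ({self.bmi_low}) must be < bmi_high ({self.bmi_high})")

    def matches(self, sex: str, bmi: float) -> bool:
        if self.sex != "any" and sex != self.sex:
            return False
        return self.bmi_low <= bmi < self.bmi_high


FALLBACK_POLICIES = ("flag_missing", "baseline_model", "literature_model")


@dataclass(frozen=True)
class StratifiedHctModel:
    """Ordered (predicate -> line) routing table over sex and BMI.

    ``fallback`` controls what happens to a record no predicate covers:

    * ``"flag_missing"`` (default): :meth:`route` returns ``None`` -- the
      caller must propagate a missing value.  The published combined model
      deliberately makes no prediction for females with BMI < 22.4.
    * ``"baseline_model"`` / ``"literature_model"``: substitute the named
      published single-line model.
    """

    routes: tuple  # tuple[(ModelPredicate, LinearHctModel), ...]
    fallback: str = "flag_missing"
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "routes", tuple(self.routes))
        if not self.routes:
            raise ValidationError("routes must be non-empty")
        if self.fallback not in FALLBACK_POLICIES:
            raise ValidationError(f"fallback must be one of {FALLBACK_POLICIES}, got {self.fallback!r}")
        # routes must partition BMI within each sex: no overlapping intervals
        for i, (pa, _) in enumerate(self.routes):
            for pb, _ in self.routes[i + 1 :]:
                if pa.sex != pb.sex and "any" not in (pa.sex, pb.sex):
                    continue
                if pa.bmi_low < pb.bmi_high and pb.bmi_low < pa.bmi_high:
                    raise ValidationError(
                        f"overlapping routes: {pa} and {pb} cover a common (sex, bmi) region"
                    )

    def route(self, record) -> Optional[LinearHctModel]:
        """First matching route wins; see module-level :func:`route`."""
        return route(self, record)

    def predict(self, record) -> Optional[float]:
        """Route then predict (Hct-percent); ``None`` if the record is unroutable."""
        model = self.route(record)
        if model is None:
            return None
        return model.predict(_get(record, "hu_blood"))


def _get(record, name):
    """Field access that works for dataclasses, namedtuples and pandas rows."""
    if hasattr(record, name):
        return getattr(record, name)
    return record[name]


def route(model: StratifiedHctModel, record) -> Optional[LinearHctModel]:
    """Dispatch a record to its calibration line.

    ``record`` needs ``sex`` and ``bmi`` attributes (or keys).  Returns the
    first matching route's model, the fallback model, or ``None`` under the
    ``flag_missing`` policy.  The function is total and deterministic: every
    (sex, bmi) pair maps to exactly one outcome.
    """
    sex = _get(record, "sex")
    bmi = float(_get(record, "bmi"))
    for predicate, line in model.routes:
        if predicate.matches(sex, bmi):
            return line
    if model.fallback == "flag_missing":
        return None
    published = published_models()
    return published["baseline" if model.fallback == "baseline_model" else "literature"]


def published_models() -> dict:
    """The published synHct calibration family, coefficients exactly as printed.

    Keys
    ----
    ``literature``
        synHct = 0.51 x HU_blood + 17.4 (earlier single-energy CT study).
    ``baseline``
        synHct = 0.864 x HU_blood - 2.09 (whole-cohort univariable refit).
    ``male_low_bmi`` / ``male_high_bmi`` / ``female_high_bmi``
        The sex- and BMI-specific lines (threshold 30.7 kg/m^2 for males,
        22.4 kg/m^2 for females).
    ``combined``
        :class:`StratifiedHctModel` assembling the three stratified lines;
        females with BMI < 22.4 are flagged as missing.
    """
    literature = LinearHctModel(0.51, 17.4, label="literature")
    baseline = LinearHctModel(0.864, -2.09, label="baseline")
    male_low = LinearHctModel(1.16, -17.2, label="male_low_bmi")
    male_high = LinearHctModel(0.669, 8.38, label="male_high_bmi")
    female_high = LinearHctModel(0.669, 8.19, label="female_high_bmi")
    combined = StratifiedHctModel(
        routes=(
            (ModelPredicate(sex="male", bmi_high=30.7), male_low),
            (ModelPredicate(sex="male", bmi_low=30.7), male_high),
            (ModelPredicate(sex="female", bmi_low=22.4), female_high),
        ),
        fallback="flag_missing",
        label="combined",
    )
    return {
        "literature": literature,
        "baseline": baseline,
        "male_low_bmi": male_low,
        "male_high_bmi": male_high,
        "female_high_bmi": female_high,
        "combined": combined,
    }


# ---------------------------------------------------------------------------
# JSON serialization


def model_to_dict(model: Union[LinearHctModel, StratifiedHctModel]) -> dict:
    if isinstance(model, LinearHctModel):
        return {
            "type": "linear",
            "label": model.label,
            "slope": model.slope,
            "intercept": model.intercept,
            "n_fit": model.n_fit,
            "r_squared": model.r_squared,
            "slope_se": model.slope_se,
            "intercept_se": model.intercept_se,
        }
    if isinstance(model, StratifiedHctModel):
        return {
            "type": "stratified",
            "label": model.label,
            "fallback": model.fallback,
            "routes": [
                {
                    "predicate": {
                        "sex": p.sex,
                        "bmi_low": None if math.isinf(p.bmi_low) else p.bmi_low,
                        "bmi_high": None if math.isinf(p.bmi_high) else p.bmi_high,
                    },
                    "model": model_to_dict(m),
                }
                for p, m in model.routes
            ],
        }
    raise ValidationError(f"cannot serialize object of type {type(model).__name__}")


def model_from_dict(payload: dict) -> Union[LinearHctModel, StratifiedHctModel]:
    kind = payload.get("type")
    if kind == "linear":
        return LinearHctModel(
            slope=payload["slope"],
            intercept=payload["intercept"],
            label=payload.get("label", ""),
            n_fit=payload.get("n_fit", 0),
            r_squared=payload.get("r_squared"),
            slope_se=payload.get("slope_se"),
            intercept_se=payload.get("intercept_se"),
        )
    if kind == "stratified":
        routes = []
        for entry in payload["routes"]:
            pd_ = entry["predicate"]
            predicate = ModelPredicate(
                sex=pd_.get("sex", "any"),
                bmi_low=-math.inf if pd_.get("bmi_low") is None else pd_["bmi_low"],
                bmi_high=math.inf if pd_.get("bmi_high") is None else pd_["bmi_high"],
            )
            routes.append((predicate, model_from_dict(entry["model"])))
        return StratifiedHctModel(
            routes=tuple(routes),
            fallback=payload.get("fallback", "flag_missing"),
            label=payload.get("label", ""),
        )
    raise ValidationError(f"unknown model type {kind!r}")


def save_model(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2)


def load_model(path):
    with open(path) as fh:
        return model_from_dict(json.load(fh))
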