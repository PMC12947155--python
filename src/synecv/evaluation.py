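"""Scoring of synthetic-haematocrit models against a cohort.

Metrics follow the study's reporting conventions: mean absolute error (MAE)
and Pearson R, for haematocrit (fraction units) and for the downstream
per-patient mean-LV ECV; Pearson R carries a 95% confidence interval from the
Fisher z transformation, tanh(atanh(r) +/- z* / sqrt(n - 3)).  The Fisher
interval is adopted because it reproduces, at two-decimal rounding, every
published interval for which the subgroup size is known.

ECV metrics need a per-record (dHU_myo, dHU_blood) pair.  Synthetic cohorts
carry these as table columns (drawn once by the generator, so evaluations are
reproducible); for tables without them a fixed dHU_blood convention combined
with the ground-truth ECV column is used instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import iter_records
from .errors import (
    DegenerateDesignError,
    EmptyEvaluationError,
    InsufficientDataError,
    ValidationError,
)
from .models import LinearHctModel, StratifiedHctModel, fit_linear, published_models

__all__ = [
    "ModelEvaluation",
    "mae",
    "pearson_r",
    "pearson_ci",
    "evaluate_model",
    "comparison_table",
    "table2_models",
    "TABLE2_ORDER",
]

TABLE2_ORDER = [
    "Literature model",
    "Baseline model",
    "Male model",
    "Male model w/BMI",
    "Female model",
    "Female model w/BMI",
    "Combined model",
]


def mae(pred, truth) -> float:
    """Mean absolute difference, in the units of its inputs."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValidationError(f"length mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.size == 0:
        raise ValidationError("mae of empty arrays is undefined")
    return float(np.mean(np.abs(pred - truth)))


def pearson_r(x, y) -> float:
    """Pearson correlation, with a guarded degenerate case.

    If either input is constant the coefficient is undefined; when the two
    vectors are additionally *identical to within rounding* (a perfect
    predictor evaluated on a constant truth) 1.0 is returned with a warning,
    otherwise NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("length mismatch between x and y")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        if np.allclose(x, y):
            warnings.warn("correlation of a constant perfect prediction reported as 1.0")
            return 1.0
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def pearson_ci(r: float, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation.

    ``tanh(atanh(r) +/- z* / sqrt(n - 3))`` with the two-sided normal
    quantile ``z*`` for the requested level.  Returns the unrounded bounds;
    round to two decimals for display.
    """
    if not np.isfinite(r) or abs(r) >= 1.0:
        raise DegenerateDesignError(f"|r| must be < 1 for a Fisher interval, got {r}")
    if n < 4:
        raise InsufficientDataError(f"need n >= 4 for a Fisher interval, got {n}")
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must lie in (0, 1), got {level}")
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


@dataclass
class ModelEvaluation:
    """Performance of one model on one cohort (haematocrit and ECV)."""

    label: str
    mae_hct: float
    r_hct: float
    r_hct_ci: Tuple[float, float]
    mae_ecv: Optional[float]
    r_ecv: Optional[float]
    r_ecv_ci: Optional[Tuple[float, float]]
    n_scored: int
    n_unroutable: int

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mae_hct": self.mae_hct,
            "r_hct": self.r_hct,
            "r_hct_ci_low": self.r_hct_ci[0],
            "r_hct_ci_high": self.r_hct_ci[1],
            "mae_ecv": self.mae_ecv,
            "r_ecv": None if self.r_ecv is None else self.r_ecv,
            "r_ecv_ci_low": None if self.r_ecv_ci is None else self.r_ecv_ci[0],
            "r_ecv_ci_high": None if self.r_ecv_ci is None else self.r_ecv_ci[1],
            "n_scored": self.n_scored,
            "n_unroutable": self.n_unroutable,
        }


def predict_cohort(model, frame: pd.DataFrame) -> np.ndarray:
    """Per-record synHct prediction in percent; NaN where unroutable."""
    if isinstance(model, LinearHctModel):
        return model.predict(frame["hu_blood"].to_numpy(dtype=float))
    if isinstance(model, StratifiedHctModel):
        out = np.full(len(frame), np.nan)
        for i, rec in enumerate(frame.itertuples(index=False)):
            line = model.route(rec)
            if line is not None:
                out[i] = line.predict(float(rec.hu_blood))
        return out
    raise ValidationError(f"unsupported model type {type(model).__name__}")


def _dhu_columns(frame: pd.DataFrame, dhu_blood_default: float):
    """Per-record (dhu_myo, dhu_blood); derived from ecv_true when absent."""
    if "dhu_myo" in frame.columns and "dhu_blood" in frame.columns:
        return frame["dhu_myo"].to_numpy(float), frame["dhu_blood"].to_numpy(float)
    if "ecv_true" in frame.columns:
        dhu_blood = np.full(len(frame), float(dhu_blood_default))
        hct = frame["hct"].to_numpy(float)
        dhu_myo = frame["ecv_true"].to_numpy(float) * dhu_blood / (1.0 - hct)
        return dhu_myo, dhu_blood
    return None, None


def evaluate_model(
    model,
    cohort: pd.DataFrame,
    label: Optional[str] = None,
    dhu_blood_default: float = 60.0,
    ci_level: float = 0.95,
) -> ModelEvaluation:
    """Score a model on a cohort table.

    Unroutable records (stratified model, uncovered subgroup) are excluded
    from the metrics and counted in ``n_unroutable``.  Haematocrit metrics
    are in fraction units; ECV metrics compare per-record conventional and
    synthetic mean-LV ECV.
    """
    if len(cohort) == 0:
        raise EmptyEvaluationError("cohort is empty")
    if label is None:
        label = getattr(model, "label", "") or "model"
    pred_pct = predict_cohort(model, cohort)
    routable = np.isfinite(pred_pct)
    n_unroutable = int((~routable).sum())
    if not routable.any():
        raise EmptyEvaluationError(f"no record of the cohort is routable under model {label!r}")
    sub = cohort.loc[routable]
    pred_frac = pred_pct[routable] / 100.0
    truth = sub["hct"].to_numpy(float)
    n = int(routable.sum())

    mae_hct = mae(pred_frac, truth)
    r_hct = pearson_r(pred_frac, truth)
    r_hct_ci = (
        pearson_ci(r_hct, n, ci_level)
        if np.isfinite(r_hct) and abs(r_hct) < 1 and n >= 4
        else (r_hct, r_hct)
    )

    dhu_myo, dhu_blood = _dhu_columns(sub, dhu_blood_default)
    if dhu_myo is None:
        mae_ecv = r_ecv = r_ecv_ci = None
    else:
        con = (1.0 - truth) * dhu_myo / dhu_blood
        syn = (1.0 - pred_frac) * dhu_myo / dhu_blood
        mae_ecv = mae(syn, con)
        r_ecv = pearson_r(syn, con)
        r_ecv_ci = (
            pearson_ci(r_ecv, n, ci_level)
            if np.isfinite(r_ecv) and abs(r_ecv) < 1 and n >= 4
            else (r_ecv, r_ecv)
        )
    return ModelEvaluation(
        label=label,
        mae_hct=mae_hct,
        r_hct=r_hct,
        r_hct_ci=r_hct_ci,
        mae_ecv=mae_ecv,
        r_ecv=r_ecv,
        r_ecv_ci=r_ecv_ci,
        n_scored=n,
        n_unroutable=n_unroutable,
    )


def table2_models(cohort: pd.DataFrame) -> dict:
    """The seven-column model family of the study's comparison table.

    Literature, baseline and the stratified models use the published
    coefficients; the sex-only models ("Male model", "Female model") are not
    printed in the study and are refitted on the given cohort.  Sex-specific
    models are wrapped so that they only score records of their own sex.
    """
    pub = published_models()

    def sex_only(line: LinearHctModel, sex: str, **bmi) -> StratifiedHctModel:
        from .models import ModelPredicate

        return StratifiedHctModel(
            routes=((ModelPredicate(sex=sex, **bmi), line),),
            fallback="flag_missing",
            label=line.label,
        )

    males = cohort[cohort["sex"] == "male"]
    females = cohort[cohort["sex"] == "female"]
    male_fit = fit_linear(males["hu_blood"], males["hct"] * 100.0, label="male_refit")
    female_fit = fit_linear(females["hu_blood"], females["hct"] * 100.0, label="female_refit")
    from .models import ModelPredicate

    male_bmi = StratifiedHctModel(
        routes=(
            (ModelPredicate(sex="male", bmi_high=30.7), pub["male_low_bmi"]),
            (ModelPredicate(sex="male", bmi_low=30.7), pub["male_high_bmi"]),
        ),
        fallback="flag_missing",
        label="male_w_bmi",
    )
    return {
        "Literature model": pub["literature"],
        "Baseline model": pub["baseline"],
        "Male model": sex_only(male_fit, "male"),
        "Male model w/BMI": male_bmi,
        "Female model": sex_only(female_fit, "female"),
        "Female model w/BMI": sex_only(pub["female_high_bmi"], "female", bmi_low=22.4),
        "Combined model": pub["combined"],
    }


def comparison_table(
    models: dict,
    cohort: pd.DataFrame,
    dhu_blood_default: float = 60.0,
) -> pd.DataFrame:
    """One :class:`ModelEvaluation` row per model, in the given order."""
    if not models:
        raise ValidationError("need at least one model to compare")
    rows = [
        evaluate_model(m, cohort, label=name, dhu_blood_default=dhu_blood_default).to_dict()
        for name, m in models.items()
    ]
    return pd.DataFrame(rows)
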