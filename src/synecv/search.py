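"""Covariate-influence procedures for the HU_blood -> Hct calibration.

Three stages, applied in the order the study used them:

1. :func:`fit_interaction` -- does a covariate modify the HU-Hct slope?
   OLS of Hct-percent on {1, HU, X, HU*X} with a two-sided t-test on the
   product term (sex is coded male = 0, female = 1).
2. :func:`bin_search` -- significance-gated enumeration of 2-5 bins of the
   covariate with varying widths.  A candidate binning is retained only if
   every bin shows a significant HU-Hct Pearson correlation *and* every bin
   boundary shows a significant change of slope; among retained candidates
   the one with the best combined MAE / Pearson-R score wins, with parsimony
   tie-breaks (fewer bins, then smaller first edge).
3. :func:`window_search` -- if no binning survives, slide windows of varying
   widths across the covariate range and look for a sub-range on which a
   significant calibration exists (this is how the female BMI > 22.4
   restriction arises).

Candidate grids are built on empirical percentile lattices so that every bin
is occupied and the search space is finite and reproducible.  Because the
candidate metrics are in-sample, differences smaller than their estimation
noise are treated as ties: metrics are quantized (MAE to 1e-4 in fraction
units, R to 1e-2) before ranking, and window selection applies a
one-standard-error rule on the Fisher-z scale, preferring the widest window
among the statistically indistinguishable best (the same parsimony logic as
the one-SE rule in cross-validated model selection).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError, InsufficientDataError, ValidationError
from .models import LinearHctModel, fit_linear

__all__ = [
    "InteractionFit",
    "BinConfig",
    "WindowResult",
    "fit_interaction",
    "bin_search",
    "window_search",
    "fit_window",
    "combined_score",
    "CONTINUOUS_COVARIATES",
]

CONTINUOUS_COVARIATES = ("bmi", "age", "egfr", "creatinine")

#: metric quantization used before ranking candidates (fraction units / R units)
MAE_DECIMALS = 4
R_DECIMALS = 2

DEFAULT_WIDTH_FRACS = tuple(np.linspace(0.25, 0.90, 5))  # of the covariate range


# ---------------------------------------------------------------------------
# interaction model


@dataclass(frozen=True)
class InteractionFit:
    """OLS fit of Hct% = a + b1*HU + b2*X + b3*(HU*X) with the t-test P of b3."""

    covariate: str
    alpha_hat: float
    beta1_hat: float
    beta2_hat: float
    beta3_hat: float
    p_beta3: float
    n: int


def _ols(X: np.ndarray, y: np.ndarray):
    """Closed-form OLS with coefficient t-test p-values.

    Returns (beta, pvalues).  Raises on rank deficiency.
    """
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(f"need more than {p} observations, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise DegenerateDesignError(
            f"design matrix is rank deficient (rank {rank} < {p} columns)"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return beta, pvals


def fit_interaction(frame: pd.DataFrame, covariate: str = "sex") -> InteractionFit:
    """Test whether ``covariate`` modifies the HU_blood -> Hct slope.

    ``covariate`` is ``"sex"`` (binary, male = 0 / female = 1) or one of the
    continuous demographics.  Requires n >= 10 and a full-rank design (a
    single-sex cohort with ``covariate="sex"`` is degenerate).
    """
    if len(frame) < 10:
        raise InsufficientDataError(f"need n >= 10 for the interaction fit, got {len(frame)}")
    hu = frame["hu_blood"].to_numpy(float)
    y = frame["hct"].to_numpy(float) * 100.0
    if covariate == "sex":
        x = (frame["sex"].to_numpy() == "female").astype(float)
    else:
        x = frame[covariate].to_numpy(float)
    if np.ptp(x) == 0:
        raise DegenerateDesignError(f"covariate {covariate!r} does not vary")
    X = np.column_stack([np.ones_like(hu), hu, x, hu * x])
    beta, pvals = _ols(X, y)
    return InteractionFit(
        covariate=covariate,
        alpha_hat=float(beta[0]),
        beta1_hat=float(beta[1]),
        beta2_hat=float(beta[2]),
        beta3_hat=float(beta[3]),
        p_beta3=float(pvals[3]),
        n=len(frame),
    )


# ---------------------------------------------------------------------------
# metrics and combined score


def _candidate_metrics(frame: pd.DataFrame, pred_pct: np.ndarray) -> dict:
    """Quantized MAE / Pearson-R metrics for one candidate's predictions."""
    truth = frame["hct"].to_numpy(float)
    pred = pred_pct / 100.0
    out = {
        "mae_hct": round(float(np.mean(np.abs(pred - truth))), MAE_DECIMALS),
        "r_hct": round(float(stats.pearsonr(pred, truth).statistic), R_DECIMALS),
    }
    if {"dhu_myo", "dhu_blood"} <= set(frame.columns):
        dhu_myo = frame["dhu_myo"].to_numpy(float)
        dhu_blood = frame["dhu_blood"].to_numpy(float)
        con = (1.0 - truth) * dhu_myo / dhu_blood
        syn = (1.0 - pred) * dhu_myo / dhu_blood
        out["mae_ecv"] = round(float(np.mean(np.abs(syn - con))), MAE_DECIMALS)
        out["r_ecv"] = round(float(stats.pearsonr(syn, con).statistic), R_DECIMALS)
    return out


def combined_score(metrics: pd.DataFrame) -> np.ndarray:
    """Equal-weight min-max combination of candidate metrics; higher is better.

    Columns named ``mae_*`` are inverted (lower error is better), ``r_*``
    taken as-is; each is min-max normalized across the candidate set and the
    normalized metrics are averaged.  A metric constant across the set
    contributes 0.5 to every candidate; a single candidate scores 1.0.
    """
    if len(metrics) == 0:
        raise ValidationError("candidate set is empty")
    if not np.isfinite(metrics.to_numpy(float)).all():
        raise ValidationError("candidate metrics must be finite")
    if len(metrics) == 1:
        return np.array([1.0])
    parts = []
    for col in metrics.columns:
        v = metrics[col].to_numpy(float)
        lo, hi = v.min(), v.max()
        if hi == lo:
            parts.append(np.full(len(v), 0.5))
        elif col.startswith("mae"):
            parts.append((hi - v) / (hi - lo))
        else:
            parts.append((v - lo) / (hi - lo))
    return np.mean(parts, axis=0)


def _percentile_lattice(values: np.ndarray, step: float) -> np.ndarray:
    pcts = np.arange(10.0, 90.0 + 1e-9, step)
    return np.unique(np.percentile(values, pcts))


# ---------------------------------------------------------------------------
# bin search


@dataclass
class BinConfig:
    """A retained bin configuration: edges, per-bin models and gate P values."""

    covariate: str
    edges: Tuple[float, ...]
    models: Tuple[LinearHctModel, ...]
    per_bin_p: Tuple[float, ...]  # Pearson correlation P within each bin
    boundary_p: Tuple[float, ...]  # slope-change P at each boundary
    n_per_bin: Tuple[int, ...]
    metrics: dict
    score: float = float("nan")
    alpha: float = 0.05

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "edges": list(self.edges),
            "per_bin": [
                {
                    "slope": m.slope,
                    "intercept": m.intercept,
                    "r_squared": m.r_squared,
                    "p": p,
                    "n": n,
                }
                for m, p, n in zip(self.models, self.per_bin_p, self.n_per_bin)
            ],
            "boundary_p": list(self.boundary_p),
            "metrics": self.metrics,
            "score": self.score,
            "alpha": self.alpha,
        }


def _evaluate_binning(hu, y_pct, cov, edges, alpha, min_bin_n):
    """Gate one candidate edge set; return a BinConfig draft or None."""
    bin_idx = np.searchsorted(edges, cov, side="right")  # value == edge -> upper bin
    k = len(edges) + 1
    counts = np.bincount(bin_idx, minlength=k)
    if counts.min() < max(min_bin_n, 3):
        return None
    models, pearson_p = [], []
    for b in range(k):
        sel = bin_idx == b
        xb, yb = hu[sel], y_pct[sel]
        if np.ptp(xb) == 0:
            return None
        r, p = stats.pearsonr(xb, yb)
        if not p < alpha:
            return None
        pearson_p.append(float(p))
        res = stats.linregress(xb, yb)
        models.append(
            LinearHctModel(
                slope=float(res.slope),
                intercept=float(res.intercept),
                n_fit=int(sel.sum()),
                r_squared=float(min(res.rvalue**2, 1.0)),
                slope_se=float(res.stderr),
                intercept_se=float(res.intercept_stderr),
                label=f"bin{b}",
            )
        )
    # boundary gate: each bin boundary must carry a significant slope change.
    # Segmented coding -- per boundary j, an intercept step 1[bin >= j] and a
    # slope step HU * 1[bin >= j] -- so each interaction coefficient tests the
    # change of slope *across that boundary* (not against a reference bin).
    cols = [np.ones_like(hu), hu]
    for j in range(1, k):
        ind = (bin_idx >= j).astype(float)
        cols.extend([ind, ind * hu])
    try:
        _, pvals = _ols(np.column_stack(cols), y_pct)
    except (DegenerateDesignError, InsufficientDataError):
        return None
    boundary_p = [float(pvals[2 + 2 * j + 1]) for j in range(k - 1)]
    if not all(p < alpha for p in boundary_p):
        return None
    pred = np.empty_like(y_pct)
    for b, m in enumerate(models):
        sel = bin_idx == b
        pred[sel] = m.slope * hu[sel] + m.intercept
    return models, pearson_p, boundary_p, counts, pred


def bin_search(
    frame: pd.DataFrame,
    covariate: str,
    k_range: Sequence[int] = (2, 3, 4, 5),
    alpha: float = 0.05,
    lattice_step: float = 5.0,
    max_candidates_per_k: int = 2000,
    min_bin_n: int = 5,
    bonferroni: bool = False,
) -> Optional[BinConfig]:
    """Significance-gated enumeration of covariate binnings.

    Candidate edges for k bins are all strictly increasing (k-1)-subsets of
    the covariate's empirical percentile lattice (p10..p90 in steps of
    ``lattice_step``); if a k exceeds ``max_candidates_per_k`` candidates the
    lattice is coarsened (step doubled) until it fits, keeping the search
    space finite and deterministic.  ``bonferroni=True`` divides the gate
    alpha by the total number of gate tests the search performs, controlling
    the familywise chance of retaining any configuration under a null
    covariate; the default (no correction) mirrors the study's practice.

    Returns the best retained configuration or ``None`` when no candidate
    passes the gates.  Ranking uses the quantized combined MAE/R score, but
    candidates whose every metric lies within one quantum of the top scorer
    are treated as indistinguishable and the most parsimonious of them wins
    (fewest bins, then smaller first edge).  The result is invariant to
    record order.
    """
    if len(frame) == 0:
        raise InsufficientDataError("empty cohort")
    if covariate not in frame.columns:
        raise ValidationError(f"covariate {covariate!r} not in cohort columns")
    hu = frame["hu_blood"].to_numpy(float)
    y_pct = frame["hct"].to_numpy(float) * 100.0
    cov = frame[covariate].to_numpy(float)
    if np.ptp(cov) == 0:
        raise DegenerateDesignError(f"covariate {covariate!r} does not vary")

    grid = []  # (k, edges)
    for k in sorted(set(int(k) for k in k_range)):
        if k < 2:
            raise ValidationError("k_range entries must be >= 2 (at least two bins)")
        step = lattice_step
        lattice = _percentile_lattice(cov, step)
        while math.comb(len(lattice), k - 1) > max_candidates_per_k:
            step *= 2.0
            lattice = _percentile_lattice(cov, step)
        grid.extend((k, edges) for edges in itertools.combinations(lattice, k - 1))
    # optional Bonferroni over *every* gate test the search performs
    # (k Pearson tests + k-1 boundary tests per candidate)
    n_tests = sum(2 * k - 1 for k, _ in grid)
    alpha_gate = alpha / n_tests if (bonferroni and n_tests) else alpha

    candidates = []  # (metrics row, BinConfig)
    for k, edges in grid:
        res = _evaluate_binning(hu, y_pct, cov, np.asarray(edges), alpha_gate, min_bin_n)
        if res is None:
            continue
        models, pearson_p, boundary_p, counts, pred = res
        metrics = _candidate_metrics(frame, pred)
        candidates.append(
            (
                metrics,
                BinConfig(
                    covariate=covariate,
                    edges=tuple(float(e) for e in edges),
                    models=tuple(models),
                    per_bin_p=tuple(pearson_p),
                    boundary_p=tuple(boundary_p),
                    n_per_bin=tuple(int(c) for c in counts),
                    metrics=metrics,
                    alpha=alpha_gate,
                ),
            )
        )
    if not candidates:
        return None
    table = pd.DataFrame([m for m, _ in candidates])
    scores = combined_score(table)
    i_top = int(np.lexsort((
        [candidates[i][1].edges[0] for i in range(len(candidates))],
        [candidates[i][1].n_bins for i in range(len(candidates))],
        -scores,
    ))[0])
    # parsimony within the noise floor: a candidate whose every quantized
    # metric sits within one quantum of the top scorer is statistically
    # indistinguishable from it in-sample (an extra gate-passing boundary
    # typically buys exactly that much), so among those the fewest bins win,
    # then the smaller first edge — the binning analogue of the one-SE rule.
    quanta = {c: 10.0 ** -(MAE_DECIMALS if c.startswith("mae") else R_DECIMALS) for c in table.columns}
    top = table.iloc[i_top]
    near = [
        i
        for i in range(len(candidates))
        if all(abs(table.iloc[i][c] - top[c]) <= quanta[c] + 1e-12 for c in table.columns)
    ]
    i_sel = min(near, key=lambda i: (candidates[i][1].n_bins, candidates[i][1].edges[0], -scores[i]))
    best = candidates[i_sel][1]
    best.score = float(scores[i_sel])
    return best


# ---------------------------------------------------------------------------
# window search


@dataclass
class WindowResult:
    """A covariate sub-range on which a significant calibration exists."""

    covariate: str
    low: float
    high: float
    model: LinearHctModel
    correlation_p: float
    n: int
    metrics: dict
    score: float = float("nan")
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "window": [self.low, self.high],
            "model": {
                "slope": self.model.slope,
                "intercept": self.model.intercept,
                "r_squared": self.model.r_squared,
            },
            "correlation_p": self.correlation_p,
            "n": self.n,
            "metrics": self.metrics,
            "score": self.score,
            "alpha": self.alpha,
        }


def fit_window(frame: pd.DataFrame, covariate: str, low: float, high: float):
    """Fit the calibration on records with ``low <= covariate <= high``.

    Returns ``(model, correlation_p, subframe)``.
    """
    cov = frame[covariate].to_numpy(float)
    sel = (cov >= low) & (cov <= high)
    sub = frame.loc[sel]
    if len(sub) < 3:
        raise InsufficientDataError(f"window [{low}, {high}] holds only {len(sub)} records")
    model = fit_linear(sub["hu_blood"], sub["hct"] * 100.0, label=f"{covariate}[{low:g},{high:g}]")
    _, p = stats.pearsonr(sub["hu_blood"], sub["hct"])
    return model, float(p), sub


def window_search(
    frame: pd.DataFrame,
    covariate: str,
    width_fracs: Sequence[float] = DEFAULT_WIDTH_FRACS,
    alpha: float = 0.05,
    lattice_step: float = 5.0,
    min_n: int = 10,
    bonferroni: bool = False,
) -> Optional[WindowResult]:
    """Slide windows of varying widths across the covariate range.

    Window lower edges run over the empirical percentile lattice; widths are
    fractions of the covariate range, upper edges clamped to the data
    maximum.  Windows whose Pearson correlation P is below alpha pass the
    gate.  Among passers, windows whose Fisher-z correlation lies within one
    standard error of the best are considered statistically indistinguishable
    and the one covering the most records wins (ties: smaller lower edge) —
    in-sample metrics cannot meaningfully rank windows of different size
    beyond that resolution.  Returns ``None`` when no window passes.
    """
    if len(frame) == 0:
        raise InsufficientDataError("empty cohort")
    if len(width_fracs) == 0:
        raise ValidationError("width_fracs must be non-empty")
    cov = frame[covariate].to_numpy(float)
    if np.ptp(cov) == 0:
        raise DegenerateDesignError(f"covariate {covariate!r} does not vary")
    lo_lattice = _percentile_lattice(cov, lattice_step)
    span = float(cov.max() - cov.min())
    cmax = float(cov.max())

    passers = []
    seen = set()
    n_windows = 0
    grid = []
    for w in sorted(width_fracs):
        if not 0 < w <= 1:
            raise ValidationError(f"width fractions must lie in (0, 1], got {w}")
        for lo in lo_lattice:
            hi = min(lo + w * span, cmax)
            sel = (cov >= lo) & (cov <= hi)
            key = sel.tobytes()
            if key in seen or sel.sum() < max(min_n, 4):
                continue
            seen.add(key)
            grid.append((float(lo), float(hi), sel))
    alpha_gate = alpha / len(grid) if (bonferroni and grid) else alpha
    for lo, hi, sel in grid:
        sub = frame.loc[sel]
        model = fit_linear(sub["hu_blood"], sub["hct"] * 100.0, label=f"window[{lo:g},{hi:g}]")
        _, p = stats.pearsonr(sub["hu_blood"], sub["hct"])
        if not p < alpha_gate:
            continue
        metrics = _candidate_metrics(sub, model.predict(sub["hu_blood"].to_numpy(float)))
        passers.append(
            WindowResult(
                covariate=covariate,
                low=lo,
                high=hi,
                model=model,
                correlation_p=float(p),
                n=int(sel.sum()),
                metrics=metrics,
                alpha=alpha_gate,
            )
        )
    if not passers:
        return None
    z = np.array([math.atanh(max(min(w.model.r_squared, 1 - 1e-12), 0.0) ** 0.5) for w in passers])
    # signed correlation on the z scale; recover the sign from the slope
    z *= np.sign([w.model.slope for w in passers])
    se = np.array([1.0 / math.sqrt(max(w.n - 3, 1)) for w in passers])
    i_best = int(np.argmax(z))
    near = z >= z[i_best] - se[i_best]
    table = pd.DataFrame([w.metrics for w in passers])
    scores = combined_score(table)
    order = sorted(
        (i for i in range(len(passers)) if near[i]),
        key=lambda i: (-passers[i].n, passers[i].low),
    )
    best = passers[order[0]]
    best.score = float(scores[order[0]])
    return best
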