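"""Interaction testing and the significance-gated bin / window searches."""

import numpy as np
import pandas as pd
import pytest

from synecv import (
    bin_search,
    combined_score,
    fit_interaction,
    fit_linear,
    fit_window,
    generate_cohort,
    generate_subgroup,
    window_search,
)
from synecv.errors import DegenerateDesignError, InsufficientDataError, ValidationError


class TestInteractionFit:
    def test_identical_sexes_give_zero_interaction(self, homogeneous_spec):
        from dataclasses import replace

        spec = replace(
            homogeneous_spec,
            subgroups=tuple(replace(g, eps_sd=0.0) for g in homogeneous_spec.subgroups),
        )
        frame = generate_cohort(spec, seed=4, n_male=60, n_female=60)
        fit = fit_interaction(frame, "sex")
        assert fit.beta3_hat == pytest.approx(0.0, abs=1e-9)

    def test_distinct_sex_slopes_detected(self, spec):
        frame = generate_cohort(spec, seed=5, n_male=2500, n_female=2500)
        fit = fit_interaction(frame, "sex")
        assert fit.p_beta3 < 0.001
        assert fit.n == 5000

    def test_single_sex_cohort_is_degenerate(self, spec):
        males = generate_cohort(spec, seed=6, n_male=100, n_female=0)
        with pytest.raises(DegenerateDesignError):
            fit_interaction(males, "sex")

    def test_too_few_records_rejected(self, cohort):
        with pytest.raises(InsufficientDataError):
            fit_interaction(cohort.head(5), "sex")

    def test_null_interaction_rejection_rate(self, homogeneous_spec):
        """Under a shared true model the sex-interaction test holds its size."""
        hits = 0
        reps = 200
        for seed in range(reps):
            frame = generate_cohort(homogeneous_spec, seed=seed, n_male=50, n_female=50)
            if fit_interaction(frame, "sex").p_beta3 < 0.05:
                hits += 1
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se + 1e-9


class TestBinSearch:
    def test_output_satisfies_its_own_gates(self, spec):
        males = generate_cohort(spec, seed=0, n_male=1200, n_female=0)
        cfg = bin_search(males, "bmi")
        assert cfg is not None
        assert all(p < cfg.alpha for p in cfg.per_bin_p)
        assert all(p < cfg.alpha for p in cfg.boundary_p)
        assert len(cfg.models) == cfg.n_bins == len(cfg.edges) + 1
        assert list(cfg.edges) == sorted(cfg.edges)
        assert min(cfg.n_per_bin) >= 5

    def test_recovers_injected_bmi_break(self, spec):
        males = generate_cohort(spec, seed=42, n_male=2000, n_female=0)
        cfg = bin_search(males, "bmi")
        assert cfg is not None
        assert cfg.n_bins == 2
        assert cfg.edges[0] == pytest.approx(30.7, abs=1.5)
        assert cfg.models[0].slope == pytest.approx(1.16, abs=0.15)
        assert cfg.models[1].slope == pytest.approx(0.669, abs=0.15)

    def test_record_order_invariance(self, spec):
        males = generate_cohort(spec, seed=13, n_male=800, n_female=0)
        cfg_a = bin_search(males, "bmi")
        shuffled = males.sample(frac=1.0, random_state=99).reset_index(drop=True)
        cfg_b = bin_search(shuffled, "bmi")
        assert (cfg_a is None) == (cfg_b is None)
        if cfg_a is not None:
            assert cfg_a.edges == cfg_b.edges

    def test_homogeneous_cohort_yields_none_or_global_fit(self, homogeneous_spec):
        frame = generate_cohort(homogeneous_spec, seed=21, n_male=600, n_female=0)
        cfg = bin_search(frame, "bmi", bonferroni=True)
        if cfg is not None:
            global_fit = fit_linear(frame["hu_blood"], frame["hct"] * 100)
            for m in cfg.models:
                assert m.slope == pytest.approx(global_fit.slope, abs=0.3)

    def test_null_covariates_rarely_retained(self, spec):
        """Age/eGFR/creatinine are independent of Hct; with familywise-corrected
        gates the search should almost never retain a binning for them."""
        hits = 0
        trials = 0
        for seed in range(4):
            sub = generate_subgroup(spec, "male_low_bmi", 300, seed=300 + seed)
            for cov in ("age", "egfr", "creatinine"):
                trials += 1
                if bin_search(sub, cov, k_range=(2, 3), bonferroni=True) is not None:
                    hits += 1
        assert hits <= 1, f"{hits}/{trials} null covariates retained"

    def test_matches_brute_force_enumeration(self, spec):
        """An independent loop over the same candidate grid selects the same
        configuration."""
        import itertools
        import math

        from scipy import stats as sps

        from synecv.search import (
            MAE_DECIMALS,
            R_DECIMALS,
            _candidate_metrics,
            _evaluate_binning,
            _percentile_lattice,
        )

        frame = generate_cohort(spec, seed=17, n_male=200, n_female=0)
        cfg = bin_search(frame, "bmi", k_range=(2, 3))
        hu = frame["hu_blood"].to_numpy()
        y = frame["hct"].to_numpy() * 100
        cov = frame["bmi"].to_numpy()
        rows = []
        for k in (2, 3):
            lattice = _percentile_lattice(cov, 5.0)
            for edges in itertools.combinations(lattice, k - 1):
                res = _evaluate_binning(hu, y, cov, np.asarray(edges), 0.05, 5)
                if res is None:
                    continue
                rows.append((k, edges, _candidate_metrics(frame, res[4])))
        if not rows:
            assert cfg is None
            return
        table = pd.DataFrame([m for _, _, m in rows])
        scores = combined_score(table)
        i_top = min(range(len(rows)), key=lambda i: (-scores[i], rows[i][0], rows[i][1][0]))
        quanta = {
            c: 10.0 ** -(MAE_DECIMALS if c.startswith("mae") else R_DECIMALS)
            for c in table.columns
        }
        near = [
            i
            for i in range(len(rows))
            if all(
                abs(table.iloc[i][c] - table.iloc[i_top][c]) <= quanta[c] + 1e-12
                for c in table.columns
            )
        ]
        i_sel = min(near, key=lambda i: (rows[i][0], rows[i][1][0], -scores[i]))
        assert cfg is not None
        assert cfg.edges == tuple(float(e) for e in rows[i_sel][1])

    def test_empty_input_rejected(self, cohort):
        with pytest.raises(InsufficientDataError):
            bin_search(cohort.iloc[0:0], "bmi")


class TestWindowSearch:
    def test_recovers_female_low_bmi_cutoff(self, spec):
        females = generate_cohort(spec, seed=42, n_male=0, n_female=1000)
        win = window_search(females, "bmi")
        assert win is not None
        assert win.low == pytest.approx(22.4, abs=1.5)
        assert win.high == pytest.approx(females["bmi"].max(), abs=1e-9)
        assert win.correlation_p < 0.05

    def test_full_window_reproduces_global_fit(self, spec):
        sub = generate_subgroup(spec, "female_high_bmi", 400, seed=8)
        model, p, picked = fit_window(sub, "bmi", sub["bmi"].min(), sub["bmi"].max())
        global_fit = fit_linear(sub["hu_blood"], sub["hct"] * 100)
        assert len(picked) == len(sub)
        assert model.slope == pytest.approx(global_fit.slope, abs=1e-12)
        assert model.intercept == pytest.approx(global_fit.intercept, abs=1e-12)

    def test_pure_noise_usually_yields_none(self, spec):
        """With a zero slope everywhere and familywise-corrected gates, no
        window should be selected in the vast majority of seeds."""
        from dataclasses import replace

        flat = replace(
            spec,
            subgroups=tuple(
                replace(g, slope=0.0, intercept=38.7, hu_mean=46.0, hu_sd=3.4, eps_sd=4.0)
                for g in spec.subgroups
            ),
        )
        hits = 0
        for seed in range(10):
            frame = generate_cohort(flat, seed=500 + seed, n_male=0, n_female=300)
            if window_search(frame, "bmi", bonferroni=True) is not None:
                hits += 1
        assert hits <= 1

    def test_empty_width_grid_rejected(self, cohort):
        with pytest.raises(ValidationError):
            window_search(cohort, "bmi", width_fracs=())


class TestCombinedScore:
    def test_dominating_candidate_ranks_first(self):
        table = pd.DataFrame(
            {
                "mae_hct": [0.020, 0.030, 0.040],
                "r_hct": [0.80, 0.70, 0.60],
                "mae_ecv": [0.010, 0.015, 0.020],
                "r_ecv": [0.90, 0.85, 0.80],
            }
        )
        scores = combined_score(table)
        assert np.argmax(scores) == 0
        assert scores[0] == pytest.approx(1.0)

    def test_identical_candidates_tie(self):
        table = pd.DataFrame({"mae_hct": [0.03, 0.03], "r_hct": [0.7, 0.7]})
        scores = combined_score(table)
        assert scores[0] == scores[1]

    def test_single_candidate_scores_one(self):
        assert combined_score(pd.DataFrame({"mae_hct": [0.03], "r_hct": [0.7]})) == [1.0]

    def test_matches_manual_normalization(self):
        """Hand-built three-candidate table against a spreadsheet-style oracle."""
        table = pd.DataFrame(
            {
                "mae_hct": [0.030, 0.025, 0.035],
                "r_hct": [0.70, 0.75, 0.72],
                "mae_ecv": [0.016, 0.017, 0.015],
                "r_ecv": [0.88, 0.86, 0.90],
            }
        )
        scores = combined_score(table)
        # manual min-max: mae inverted, equal weights
        expected = [
            np.mean([(0.035 - 0.030) / 0.010, 0.0, (0.017 - 0.016) / 0.002, 0.5]),
            np.mean([1.0, 1.0, 0.0, 0.0]),
            np.mean([0.0, 0.4, 1.0, 1.0]),
        ]
        assert np.allclose(scores, expected)
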