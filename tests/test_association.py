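"""Case-only chronicity regressions: transforms, OLS, stratification, interaction."""

import numpy as np
import pandas as pd
import pytest

from chronoprs import (
    CHRONICITY_MARKERS,
    GRPSVector,
    OutcomeVector,
    fit_case_only,
    fit_interaction,
    make_outcome,
)
from chronoprs.errors import CollinearityError, DegenerateOutcomeError, ValidationError


def case_table(n, rng=None, sex=None, followup=None, markers=None):
    rng = rng or np.random.default_rng(0)
    ids = np.array([f"c{i}" for i in range(n)])
    df = pd.DataFrame(
        {
            "individual_id": ids,
            "case_status": 1,
            "sex": sex if sex is not None else rng.choice(["F", "M"], size=n),
            "age_at_diagnosis": rng.normal(28, 5, size=n),
            "follow_up_years": followup if followup is not None else rng.uniform(5, 30, n),
        }
    )
    for m in CHRONICITY_MARKERS:
        df[m] = markers[m] if markers and m in markers else rng.poisson(10, n).astype(float)
    return df


def grps_vec(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids if ids is not None else np.array([f"c{i}" for i in range(len(values))])
    return GRPSVector(ids, values, 0.05, 10, standardized=True)


class TestMakeOutcome:
    def test_hand_computed_three_rows(self):
        """Counts (0,9,99) over 1y follow-up: log1p rates (0, log10, log100), z-scored."""
        pheno = case_table(3, followup=np.ones(3), markers={"n_total": np.array([0.0, 9.0, 99.0])})
        out = make_outcome(pheno, "n_total")
        t = np.array([0.0, np.log(10.0), np.log(100.0)])
        expected = (t - t.mean()) / t.std(ddof=1)
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_follow_up_weighting_changes_rates(self):
        markers = {"n_total": np.array([10.0, 10.0])}
        p1 = case_table(2, followup=np.array([1.0, 10.0]), markers=markers)
        out = make_outcome(p1, "n_total")
        assert out.values[0] > out.values[1]  # same count, shorter follow-up -> higher rate

    def test_identical_cases_degenerate(self):
        pheno = case_table(4, followup=np.full(4, 5.0), markers={"n_total": np.full(4, 10.0)})
        with pytest.raises(DegenerateOutcomeError):
            make_outcome(pheno, "n_total")

    def test_admissible_markers_are_the_four_chronicity_markers(self):
        pheno = case_table(5)
        for marker in CHRONICITY_MARKERS:
            assert make_outcome(pheno, marker).marker == marker
        with pytest.raises(ValidationError):
            make_outcome(pheno, "n_admissions")

    def test_nonpositive_followup_lists_ids(self):
        pheno = case_table(3, followup=np.array([5.0, -1.0, 0.0]))
        with pytest.raises(ValidationError) as err:
            make_outcome(pheno, "n_total")
        assert "c1" in str(err.value) and "c2" in str(err.value)

    def test_zero_mean_unit_sd_after_transform(self):
        pheno = case_table(50, rng=np.random.default_rng(5))
        out = make_outcome(pheno, "n_inpatient")
        assert abs(out.values.mean()) < 1e-9
        assert abs(out.values.std(ddof=1) - 1) < 1e-9


def normal_equations(X, y):
    """Independent OLS oracle: pinv-based normal equations with classic se."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    s2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(np.diag(s2 * XtX_inv))
    return beta, se


class TestFitCaseOnly:
    def test_outcome_equal_to_score_recovers_unity(self):
        score = np.linspace(-2, 2, 20)
        pheno = case_table(20)
        out = OutcomeVector(pheno["individual_id"].to_numpy(), score, "n_total", "raw")
        res = fit_case_only(out, grps_vec(score), None, pheno, adjust=())
        assert res.B == pytest.approx(1.0, abs=1e-10)
        assert res.P < 1e-30

    def test_matches_normal_equations_on_12_rows(self):
        rng = np.random.default_rng(12)
        n = 12
        pheno = case_table(n, rng=rng)
        covars = pd.DataFrame(
            {
                "individual_id": pheno["individual_id"],
                "pc_1": rng.normal(size=n),
                "pc_2": rng.normal(size=n),
                "batch": ["batch_1"] * n,
            }
        )
        score = rng.normal(size=n)
        y = rng.normal(size=n)
        out = OutcomeVector(pheno["individual_id"].to_numpy(), y, "n_total", "raw")
        res = fit_case_only(out, grps_vec(score), covars, pheno, adjust=("pcs",))
        X = np.column_stack([np.ones(n), score, covars["pc_1"], covars["pc_2"]])
        beta, se = normal_equations(X, y)
        assert res.B == pytest.approx(beta[1], abs=1e-10)
        assert res.se == pytest.approx(se[1], abs=1e-10)

    def test_invariant_to_row_and_column_order(self):
        rng = np.random.default_rng(3)
        n = 40
        pheno = case_table(n, rng=rng)
        covars = pd.DataFrame(
            {
                "individual_id": pheno["individual_id"],
                "pc_1": rng.normal(size=n),
                "pc_2": rng.normal(size=n),
                "batch": rng.choice(["batch_1", "batch_2"], size=n),
            }
        )
        score = rng.normal(size=n)
        out = OutcomeVector(pheno["individual_id"].to_numpy(), rng.normal(size=n), "n_total", "raw")
        res = fit_case_only(out, grps_vec(score), covars, pheno)

        perm = rng.permutation(n)
        pheno_p = pheno.iloc[perm].reset_index(drop=True)
        covars_p = covars.iloc[perm].reset_index(drop=True)[
            ["individual_id", "pc_2", "pc_1", "batch"]
        ]
        ids_p = pheno_p["individual_id"].to_numpy()
        lookup = dict(zip(pheno["individual_id"], zip(score, out.values)))
        score_p = np.array([lookup[i][0] for i in ids_p])
        y_p = np.array([lookup[i][1] for i in ids_p])
        out_p = OutcomeVector(ids_p, y_p, "n_total", "raw")
        res_p = fit_case_only(out_p, grps_vec(score_p, ids_p), covars_p, pheno_p)
        assert res_p.B == pytest.approx(res.B, abs=1e-10)
        assert res_p.se == pytest.approx(res.se, abs=1e-10)

    def test_strata_partition_the_cases(self):
        rng = np.random.default_rng(8)
        n = 60
        pheno = case_table(n, rng=rng)
        score = rng.normal(size=n)
        out = OutcomeVector(pheno["individual_id"].to_numpy(), rng.normal(size=n), "n_total", "raw")
        r_all = fit_case_only(out, grps_vec(score), None, pheno, stratum="all", adjust=())
        r_f = fit_case_only(out, grps_vec(score), None, pheno, stratum="female", adjust=())
        r_m = fit_case_only(out, grps_vec(score), None, pheno, stratum="male", adjust=())
        assert r_f.n + r_m.n == r_all.n == n

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(4)
        n = 30
        pheno = case_table(n, rng=rng)
        covars = pd.DataFrame(
            {
                "individual_id": pheno["individual_id"],
                "pc_1": rng.normal(size=n),
                "pc_2": np.zeros(n),
                "batch": ["batch_1"] * n,
            }
        )
        covars["pc_3"] = covars["pc_1"] * 2  # exact alias
        score = rng.normal(size=n)
        out = OutcomeVector(pheno["individual_id"].to_numpy(), rng.normal(size=n), "n_total", "raw")
        with pytest.raises(CollinearityError) as err:
            fit_case_only(out, grps_vec(score), covars, pheno, adjust=("pcs",))
        assert err.value.aliased


class TestInteraction:
    def _exact_sexwise(self, slope_f, slope_m, n=30):
        ids = np.array([f"c{i}" for i in range(2 * n)])
        sex = np.array(["F"] * n + ["M"] * n)
        score = np.tile(np.linspace(-1.5, 1.5, n), 2)
        y = np.where(sex == "F", slope_f * score, slope_m * score)
        pheno = case_table(2 * n, sex=sex)
        pheno["individual_id"] = ids
        out = OutcomeVector(ids, y, "n_total", "raw")
        return out, grps_vec(score, ids), pheno

    def test_exact_interaction_coefficient(self):
        """Noiseless slopes 0.5 (F) and 1.0 (M) give interaction B = 0.5."""
        out, grps, pheno = self._exact_sexwise(0.5, 1.0)
        res = fit_interaction(out, grps, None, pheno, adjust=())
        assert res.B == pytest.approx(0.5, abs=1e-10)

    def test_reference_swap_negates_coefficient(self):
        rng = np.random.default_rng(9)
        n = 80
        pheno = case_table(n, rng=rng)
        score = rng.normal(size=n)
        y = 0.3 * score + rng.normal(size=n)
        out = OutcomeVector(pheno["individual_id"].to_numpy(), y, "n_total", "raw")
        r1 = fit_interaction(out, grps_vec(score), None, pheno, adjust=(), sex_ref="F")
        r2 = fit_interaction(out, grps_vec(score), None, pheno, adjust=(), sex_ref="M")
        assert r1.B == pytest.approx(-r2.B, abs=1e-10)
        assert r1.P == pytest.approx(r2.P, abs=1e-10)

    def test_single_sex_raises(self):
        pheno = case_table(20, sex=np.array(["M"] * 20))
        score = np.linspace(-1, 1, 20)
        out = OutcomeVector(pheno["individual_id"].to_numpy(), score, "n_total", "raw")
        with pytest.raises(ValidationError):
            fit_interaction(out, grps_vec(score), None, pheno, adjust=())
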