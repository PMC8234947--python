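"""MR estimators: IVW, Egger, weighted median, OR arithmetic, model surface."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clustmr.datasets import reported_mr_estimates
from clustmr.exceptions import NotEstimableError, ParameterError
from clustmr.meta import ivw_fixed_meta
from clustmr.mr import (
    MRInput,
    MRModel,
    _weighted_median,
    mr_egger,
    mr_ivw,
    mr_weighted_median,
    run_mr_suite,
    to_odds_ratio,
)
from clustmr.simulate import simulate_mr_dataset
from clustmr.sumstats import AssociationRecord, flip_record


def mk_input(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    return MRInput(bx, sx, np.asarray(by, float), np.asarray(sy, float))


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------


def test_ivw_exact_proportional_data():
    bx = np.array([0.1, 0.2, 0.3])
    est = mr_ivw(mk_input(bx, 0.4 * bx, [0.05, 0.05, 0.05]))
    assert est.beta == pytest.approx(0.4, abs=1e-12)
    assert est.extras["phi"] <= 1e-8  # zero residuals


def test_ivw_hand_computed_three_instruments():
    # (bx, by, sy) = (1, .2, .1), (2, .3, .1), (1, .1, .2)
    # num = 1*.2*100 + 2*.3*100 + 1*.1*25 = 82.5 ; den = 100 + 400 + 25 = 525
    est = mr_ivw(mk_input([1, 2, 1], [0.2, 0.3, 0.1], [0.1, 0.1, 0.2]), se_mode="fixed")
    assert est.beta == pytest.approx(82.5 / 525, abs=1e-12)
    assert est.se == pytest.approx(525**-0.5, abs=1e-12)


def test_ivw_equals_meta_of_ratio_estimates():
    """Cross-module identity: IVW(fixed) == fixed-effect pooling of per-
    instrument ratios with first-order weights, over random instances."""
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = rng.integers(2, 12)
        bx = rng.uniform(0.05, 0.5, n) * rng.choice([-1, 1], n)
        by = rng.normal(0.3 * bx, 0.05)
        sy = rng.uniform(0.01, 0.2, n)
        est = mr_ivw(mk_input(bx, by, sy), se_mode="fixed")
        pooled = ivw_fixed_meta(list(zip(by / bx, sy / np.abs(bx))))
        assert est.beta == pytest.approx(pooled.beta, abs=1e-10)
        assert est.se == pytest.approx(pooled.se, abs=1e-10)


def test_ivw_multiplicative_inflation_floor():
    # strongly heterogeneous ratios -> phi > 1 inflates the SE; floor keeps
    # homogeneous data at the fixed SE
    het = mk_input([0.1, 0.2, 0.3], [0.5, -0.4, 0.8], [0.05, 0.05, 0.05])
    assert mr_ivw(het).se > mr_ivw(het, se_mode="fixed").se
    hom = mk_input([0.1, 0.2], [0.05, 0.10], [0.05, 0.05])
    assert mr_ivw(hom).se == mr_ivw(hom, se_mode="fixed").se


def test_ivw_parameter_errors():
    with pytest.raises(ParameterError):
        mr_ivw(mk_input([0.1], [0.1], [0.1]))
    with pytest.raises(NotEstimableError):
        mr_ivw(mk_input([0.0, 0.0], [0.1, 0.2], [0.1, 0.1]))
    with pytest.raises(ParameterError):
        mr_ivw(mk_input([0.1, 0.2], [0.1, 0.2], [0.1, 0.1]), se_mode="bogus")


# ---------------------------------------------------------------------------
# Egger
# ---------------------------------------------------------------------------


def test_egger_exact_affine_data():
    bx = np.array([0.1, 0.2, 0.3, 0.4])
    est = mr_egger(mk_input(bx, 0.02 + 0.5 * bx, np.full(4, 0.05)))
    assert est.beta == pytest.approx(0.5, abs=1e-10)
    assert est.extras["egger_intercept"] == pytest.approx(0.02, abs=1e-10)


def test_egger_matches_normal_equations():
    """4-point weighted regression equals an independent lstsq solve."""
    bx = np.array([0.05, 0.15, 0.22, 0.4])
    by = np.array([0.03, 0.02, 0.15, 0.18])
    sy = np.array([0.02, 0.05, 0.03, 0.08])
    est = mr_egger(mk_input(bx, by, sy))
    sw = np.sqrt(1 / sy**2)
    A = np.column_stack([sw, sw * bx])
    coef, *_ = np.linalg.lstsq(A, sw * by, rcond=None)
    assert est.extras["egger_intercept"] == pytest.approx(coef[0], abs=1e-10)
    assert est.beta == pytest.approx(coef[1], abs=1e-10)


def test_egger_orientation_invariance():
    """Negating an instrument's allele coding must not change the estimate."""
    bx = np.array([0.1, -0.2, 0.3, 0.25])
    by = np.array([0.04, -0.12, 0.2, 0.1])
    sy = np.full(4, 0.05)
    a = mr_egger(mk_input(bx, by, sy))
    flip = np.array([1, -1, -1, 1.0])
    b = mr_egger(mk_input(bx * flip, by * flip, sy))
    assert a.beta == pytest.approx(b.beta, abs=1e-12)
    assert a.extras["egger_intercept"] == pytest.approx(b.extras["egger_intercept"], abs=1e-12)


def test_egger_requires_three_instruments():
    with pytest.raises(ParameterError):
        mr_egger(mk_input([0.1, 0.2], [0.1, 0.2], [0.1, 0.1]))
    with pytest.raises(NotEstimableError):
        mr_egger(mk_input([0.2, 0.2, -0.2], [0.1, 0.1, -0.1], [0.1, 0.1, 0.1]))


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------


def test_equal_weights_odd_n_is_middle_ratio():
    est = mr_weighted_median(
        mk_input([0.1, 0.1, 0.1], [0.01, 0.03, 0.07], np.full(3, 0.05)), seed=0
    )
    assert est.beta == pytest.approx(0.3)  # middle ratio 0.03/0.1


def test_interpolation_matches_bruteforce_definition():
    """Hand-chosen weights: the interpolated value equals a direct evaluation
    of the cumulative-weight definition."""
    ratios = np.array([0.1, 0.25, 0.4, 0.9])
    weights = np.array([1.0, 3.0, 2.0, 2.0])
    # brute force: p_j = (S_j - w_j/2)/S ; piecewise-linear inverse at 0.5
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    S = np.cumsum(w)
    p = (S - w / 2) / S[-1]
    j = np.searchsorted(p, 0.5)
    expected = r[j - 1] + (0.5 - p[j - 1]) / (p[j] - p[j - 1]) * (r[j] - r[j - 1])
    assert _weighted_median(ratios, weights) == pytest.approx(expected, abs=1e-12)
    # sanity: with these weights the estimate sits between the 2nd and 3rd ratio
    assert 0.25 < expected < 0.4


def test_zero_beta_x_instruments_rejected_with_warning():
    data = mk_input([0.0, 0.1, 0.2, 0.3], [0.0, 0.05, 0.1, 0.15], np.full(4, 0.05))
    with pytest.warns(UserWarning):
        est = mr_weighted_median(data, seed=0)
    assert est.n_snv == 3


def test_weighted_median_too_few_instruments():
    with pytest.raises(ParameterError):
        mr_weighted_median(mk_input([0.1, 0.2], [0.1, 0.2], [0.1, 0.1]), seed=0)
    with pytest.raises(ParameterError):
        mr_weighted_median(mk_input([0.1] * 3, [0.1] * 3, [0.1] * 3), n_boot=10, seed=0)


def test_bootstrap_se_deterministic_given_seed():
    d, _ = simulate_mr_dataset(seed=5)
    a = mr_weighted_median(d, seed=9)
    b = mr_weighted_median(d, seed=9)
    assert a.se == b.se and a.beta == b.beta


# ---------------------------------------------------------------------------
# odds-ratio arithmetic
# ---------------------------------------------------------------------------


def test_or_published_rows_reproduced():
    # printed protective and risk-effect rows
    or_, lo, hi = to_odds_ratio(-0.0120, 0.0035)
    assert (round(or_, 3), round(lo, 3), round(hi, 3)) == (0.988, 0.981, 0.995)
    or_, lo, hi = to_odds_ratio(0.8842, 0.1209)
    assert (round(or_, 3), round(lo, 3), round(hi, 3)) == (2.421, 1.910, 3.068)


def test_or_zero_beta_symmetric():
    or_, lo, hi = to_odds_ratio(0.0, 0.3)
    assert or_ == 1.0
    assert lo * hi == pytest.approx(1.0, abs=1e-12)


@given(
    beta=st.floats(-2, 2, allow_nan=False),
    se=st.floats(0.001, 1, allow_nan=False),
    level=st.floats(0.5, 0.99),
)
def test_or_log_symmetry_and_level_monotonicity(beta, se, level):
    or_, lo, hi = to_odds_ratio(beta, se, level)
    assert lo < or_ < hi
    assert lo * hi == pytest.approx(np.exp(2 * beta), rel=1e-9)
    _, lo2, hi2 = to_odds_ratio(beta, se, min(level + 0.005, 0.995))
    assert lo2 <= lo and hi2 >= hi


# ---------------------------------------------------------------------------
# properties across methods
# ---------------------------------------------------------------------------


def test_scale_equivariance_all_methods():
    """Multiplying all exposure effects by c divides every estimate by c."""
    d, _ = simulate_mr_dataset(seed=3)
    c = 2.5
    scaled = MRInput(
        d.beta_exposure * c, d.se_exposure * c, d.beta_outcome, d.se_outcome
    )
    assert mr_ivw(scaled).beta == pytest.approx(mr_ivw(d).beta / c, rel=1e-10)
    assert mr_egger(scaled).beta == pytest.approx(mr_egger(d).beta / c, rel=1e-10)
    a = mr_weighted_median(d, seed=7)
    b = mr_weighted_median(scaled, seed=7)
    assert b.beta == pytest.approx(a.beta / c, rel=1e-6)


def test_methods_agree_without_pleiotropy():
    d, truth = simulate_mr_dataset(n_instruments=200, theta=0.5, seed=21)
    estimates = [mr_ivw(d).beta, mr_egger(d).beta, mr_weighted_median(d, seed=1).beta]
    assert max(estimates) - min(estimates) < 0.02
    assert all(abs(e - 0.5) < 0.02 for e in estimates)


def test_directional_pleiotropy_biases_ivw_not_egger():
    biases = {"ivw": [], "egger": []}
    for s in range(40):
        d, _ = simulate_mr_dataset(
            theta=0.3, pleiotropy_mean=0.1, pleiotropy_sd=0.05, invalid_frac=0.3, seed=300 + s
        )
        biases["ivw"].append(mr_ivw(d).beta - 0.3)
        biases["egger"].append(mr_egger(d).beta - 0.3)
    assert np.mean(biases["ivw"]) > 0.05  # biased in the planted direction
    assert abs(np.mean(biases["egger"])) < 0.03


# ---------------------------------------------------------------------------
# model surface and suite
# ---------------------------------------------------------------------------


def exposure_outcome_tables(seed=2, n=20, theta=0.4):
    d, _ = simulate_mr_dataset(n_instruments=n, theta=theta, seed=seed)
    exp_recs, out_recs = [], []
    for i in range(n):
        vid = f"rs{i + 1}"
        exp_recs.append(
            AssociationRecord(
                variant_id=vid, effect_allele="A", other_allele="G",
                beta=float(d.beta_exposure[i]), se=float(d.se_exposure[i]), pval=0.5,
                eaf=0.3,
            )
        )
        rec = AssociationRecord(
            variant_id=vid, effect_allele="A", other_allele="G",
            beta=float(d.beta_outcome[i]), se=float(d.se_outcome[i]), pval=0.5, eaf=0.3,
        )
        out_recs.append(flip_record(rec) if i % 2 else rec)
    return exp_recs, out_recs, d


def test_model_from_summary_tables_harmonizes_outcome():
    exp_recs, out_recs, d = exposure_outcome_tables()
    model = MRModel.from_summary_tables(exp_recs, out_recs)
    assert model.data.n_snv == 20
    assert np.allclose(model.data.beta_outcome, d.beta_outcome)


def test_run_mr_suite_emits_all_methods():
    exp_recs, out_recs, _ = exposure_outcome_tables()
    ests = run_mr_suite(exp_recs, out_recs, seed=0)
    assert [e.method for e in ests] == ["ivw", "egger", "weighted_median"]
    assert all(e.estimable for e in ests)
    assert all(e.or_point == pytest.approx(np.exp(e.beta)) for e in ests)
    assert "instruments" in ests[0].summary()


def test_suite_flags_underpowered_methods():
    exp_recs, out_recs, _ = exposure_outcome_tables(n=2)
    ests = run_mr_suite(exp_recs, out_recs, seed=0)
    by_method = {e.method: e for e in ests}
    assert by_method["ivw"].estimable
    assert not by_method["egger"].estimable
    assert not by_method["weighted_median"].estimable


def test_reported_estimates_fixture_shape():
    df = reported_mr_estimates()
    assert set(df.method) == {"ivw", "egger", "weighted_median"}
    assert len(df) == 36 and df.n_snv.min() >= 8
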