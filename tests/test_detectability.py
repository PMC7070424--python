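"""Binomial GLM detectability analysis, D95 and the drop experiment."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from sklearn.base import clone

from irsring import (
    LOGIT95,
    DetectabilityFit,
    DetectabilityGLM,
    FrontEndConfig,
    NonIdentifiableError,
    ObjectDescriptor,
    SeparationWarning,
    ST100,
    d95,
    d95_standard_error,
    fit_detectability,
    grain_population,
    run_drop_experiment,
)


def _logistic_trials(beta0, beta1, n, seed, lo=0.0, hi=2.0):
    rng = np.random.default_rng(seed)
    sizes = rng.uniform(lo, hi, size=n)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * sizes)))
    return sizes, (rng.uniform(size=n) < p).astype(int)


def _direct_mle(sizes, y):
    """Independent oracle: numerical maximisation of the binomial
    log-likelihood (no IRLS involved)."""
    X = np.column_stack([np.ones_like(sizes), sizes])

    def nll(beta):
        eta = X @ beta
        return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)

    res = minimize(nll, x0=np.zeros(2), method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 500})
    return res.x


def test_irls_matches_direct_likelihood_maximisation():
    sizes, y = _logistic_trials(-3.0, 4.0, 200, seed=17)
    model = DetectabilityGLM().fit(sizes, y)
    ref = _direct_mle(sizes, y)
    assert model.intercept_ == pytest.approx(ref[0], abs=1e-6)
    assert model.coef_[0] == pytest.approx(ref[1], abs=1e-6)
    assert model.converged_ and model.n_iter_ <= 100


def test_parameter_recovery_within_three_standard_errors():
    beta0, beta1 = -6.0, 6.0
    sizes, y = _logistic_trials(beta0, beta1, 2000, seed=23)
    model = DetectabilityGLM().fit(sizes, y)
    se = np.sqrt(np.diag(model.cov_params_))
    assert abs(model.intercept_ - beta0) < 3 * se[0]
    assert abs(model.coef_[0] - beta1) < 3 * se[1]
    # D95 of the generating truth is (logit(0.95) + 6) / 6 ~ 1.49 mm
    truth = (LOGIT95 + 6.0) / 6.0
    assert truth == pytest.approx(1.4907, abs=1e-3)
    assert abs(model.d95_ - truth) < 3 * model.d95_se_


def _fit(beta0, beta1):
    return DetectabilityFit(group="g", beta0=beta0, beta1=beta1,
                            covariance=np.eye(2), d95=math.nan, d95_se=math.nan,
                            n_trials=0)


def test_d95_closed_forms():
    assert d95(_fit(0.0, 1.0)) == pytest.approx(LOGIT95)
    assert d95(_fit(0.0, 1.0)) == pytest.approx(2.9444, abs=1e-4)
    assert d95(_fit(-LOGIT95, LOGIT95)) == pytest.approx(2.0)
    # doubling the slope halves D95 at zero intercept
    assert d95(_fit(0.0, 2.0)) == pytest.approx(d95(_fit(0.0, 1.0)) / 2.0)
    with pytest.raises(NonIdentifiableError):
        d95(_fit(0.0, -1.0))
    with pytest.raises(NonIdentifiableError):
        d95_standard_error(_fit(0.0, 0.0))


def test_d95_delta_method_matches_finite_differences():
    sizes, y = _logistic_trials(-4.0, 5.0, 500, seed=3)
    model = DetectabilityGLM().fit(sizes, y)
    b0, b1 = model.intercept_, model.coef_[0]
    grad = np.array([-1.0 / b1, -(LOGIT95 - b0) / b1 ** 2])
    eps = 1e-6
    num = np.array([
        ((LOGIT95 - (b0 + eps)) / b1 - (LOGIT95 - b0) / b1) / eps,
        ((LOGIT95 - b0) / (b1 + eps) - (LOGIT95 - b0) / b1) / eps,
    ])
    assert grad == pytest.approx(num, rel=1e-4)
    assert model.d95_se_ == pytest.approx(
        math.sqrt(grad @ model.cov_params_ @ grad))


def test_single_outcome_rejected_and_separation_flagged():
    sizes = np.linspace(0.2, 1.8, 40)
    with pytest.raises(ValueError):  # everything detected: no curve exists
        DetectabilityGLM().fit(sizes, np.ones(40))
    y = (sizes > 1.0).astype(int)  # perfectly separated
    with pytest.warns(SeparationWarning):
        model = DetectabilityGLM().fit(sizes, y)
    assert model.separation_
    below = sizes[y == 0].max()
    above = sizes[y == 1].min()
    assert model.d95_ == pytest.approx((below + above) / 2.0)
    assert math.isnan(model.d95_se_)


def test_estimator_is_sklearn_compatible():
    model = DetectabilityGLM(tol=1e-9, max_iter=50)
    assert model.get_params() == {"tol": 1e-9, "max_iter": 50}
    cloned = clone(model)
    sizes, y = _logistic_trials(-2.0, 3.0, 300, seed=5)
    cloned.fit(sizes, y)
    proba = cloned.predict_proba(np.array([[0.1], [2.0]]))
    assert proba.shape == (2, 2)
    assert np.allclose(proba.sum(axis=1), 1.0)
    assert proba[1, 1] > proba[0, 1]  # bigger objects: more detectable
    assert set(cloned.predict(np.array([[0.0], [5.0]]))) <= {0, 1}


def test_fit_detectability_per_group_and_pooled():
    frames = []
    for g, b0, b1 in [("a", -4.0, 5.0), ("b", -2.0, 5.0)]:
        sizes, y = _logistic_trials(b0, b1, 400, seed=hash(g) % 1000)
        frames.append(pd.DataFrame({"group": g, "size_mm": sizes, "detected": y}))
    trials = pd.concat(frames, ignore_index=True)
    fits = fit_detectability(trials)
    assert set(fits) == {"a", "b"}
    assert fits["a"].d95 > fits["b"].d95  # lower intercept: harder to detect
    pooled = fit_detectability(trials, pooled=True)
    assert pooled["a"].beta1 == pooled["b"].beta1  # shared slope
    assert pooled["a"].d95 > pooled["b"].d95
    with pytest.raises(ValueError):
        fit_detectability(trials.drop(columns=["detected"]))
    with pytest.raises(ValueError):
        fit_detectability(trials.iloc[:0])


def test_drop_experiment_is_reproducible(ring1):
    pop = [ObjectDescriptor(size=s) for s in (0.6, 1.2)]
    fe = FrontEndConfig()
    a = run_drop_experiment(ring1, ST100, fe, pop, n_per_size=6, seed=99)
    b = run_drop_experiment(ring1, ST100, fe, pop, n_per_size=6, seed=99)
    pd.testing.assert_frame_equal(a, b)
    assert len(a) == 12
    assert (a["entry_x"] ** 2 + a["entry_y"] ** 2 <= (35.0 / 2) ** 2).all()
    c = run_drop_experiment(ring1, ST100, fe, pop, n_per_size=6, seed=100)
    assert not a["seed"].equals(c["seed"])


def test_transparent_objects_detected_at_most_at_noise_rate(ring1):
    """Opacity-0 drops cannot beat the false-positive rate of pure noise."""
    fe = FrontEndConfig()  # default noise
    pop = [ObjectDescriptor(size=1.0, opacity=0.0)] * 40
    trials = run_drop_experiment(ring1, ST100, fe, pop, seed=8)
    assert trials["detected"].mean() <= 0.05


def test_grain_population_matches_the_binned_protocol():
    pop = grain_population(n_per_bin=20, seed=1)
    sizes = np.array([o.size for o in pop])
    assert len(pop) == 8 * 20  # eight 0.2 mm bins spanning 0.2-1.8 mm
    assert sizes.min() >= 0.2 and sizes.max() <= 1.8
    for lo in np.arange(0.2, 1.7, 0.2):
        assert ((sizes >= lo) & (sizes < lo + 0.2)).sum() >= 19
    assert all(o.group_label == "grain" and o.opacity == 1.0 for o in pop)
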