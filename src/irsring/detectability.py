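"""Simulated drop experiments and the logistic detectability analysis.

The laboratory protocol drops ~20 objects per 0.2 mm size bin through the
ring and records for each whether at least one detection event was
produced.  Detection (yes/no) is then modelled as a binomial GLM with a
logit link,

    logit P(detected) = beta0 + beta1 * size,

fitted per group (species or grain) by iteratively reweighted least squares
(own implementation).  The headline summary is D95, the body size at which
the fitted curve reaches 95% detectability,

    D95 = (logit(0.95) - beta0) / beta1,

with a delta-method standard error from the coefficient covariance.

``calibrate_noise`` is the bridge between the simulator and the physical
instrument's reported sensitivity: it bisects the front-end noise level
until the simulated grain experiment reproduces a target D95.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .detector import DetectorConfig, ST100, detect_stream
from .fall import ChannelSignal, DropParams, FrontEndConfig, simulate_signal
from .geometry import ObjectDescriptor, RingGeometry
from .presets import GRAIN, with_size

__all__ = [
    "LOGIT95",
    "SeparationWarning",
    "NonIdentifiableError",
    "CalibrationError",
    "DetectabilityFit",
    "DetectabilityGLM",
    "NoiseCalibration",
    "grain_population",
    "binned_population",
    "run_drop_experiment",
    "fit_detectability",
    "d95",
    "d95_standard_error",
    "calibrate_noise",
]

LOGIT95 = math.log(0.95 / 0.05)  # = logit(0.95) ~ 2.9444


class SeparationWarning(UserWarning):
    """The detected/undetected sizes are perfectly separated; the MLE is
    not regular and D95 is reported as the separation midpoint."""


class NonIdentifiableError(ValueError):
    """D95 is undefined because the fitted slope is not positive."""


class CalibrationError(RuntimeError):
    """The noise calibration target cannot be reached within the bounds."""


# ---------------------------------------------------------------------
# binomial GLM (logit link), own IRLS
# ---------------------------------------------------------------------

def _irls_logit(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """IRLS for a binomial GLM with logit link.

    Returns (beta, covariance, n_iter, converged).  Covariance is the
    inverse Fisher information at the estimate.
    """
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1.0 - p), 1e-12)
        z = eta + (y - p) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30.0, 30.0)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(p * (1.0 - p), 1e-12)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, cov, it, converged


def _perfectly_separated(size: np.ndarray, y: np.ndarray) -> bool:
    """True when every detected size exceeds every undetected size."""
    return float(size[y == 0].max()) < float(size[y == 1].min())


@dataclass
class DetectabilityFit:
    """Per-group logistic detectability model."""

    group: str
    beta0: float
    beta1: float
    covariance: np.ndarray  # 2x2, order (beta0, beta1)
    d95: float
    d95_se: float
    n_trials: int
    converged: bool = True
    separation: bool = False

    def prob(self, size: Sequence[float] | np.ndarray) -> np.ndarray:
        """Fitted detection probability at the given sizes."""
        eta = self.beta0 + self.beta1 * np.asarray(size, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))

    def to_dict(self) -> dict:
        return {"group": self.group, "beta0": self.beta0, "beta1": self.beta1,
                "d95": self.d95, "d95_se": self.d95_se, "n": self.n_trials,
                "converged": self.converged, "separation": self.separation}


def d95(fit: "DetectabilityFit | DetectabilityGLM") -> float:
    """Size at which the fitted logistic curve reaches 95% detectability."""
    b0, b1 = _coefs(fit)
    if b1 <= 0:
        raise NonIdentifiableError("D95 requires a positive size slope")
    return (LOGIT95 - b0) / b1


def d95_standard_error(fit: "DetectabilityFit | DetectabilityGLM") -> float:
    """Delta-method standard error of D95 from the coefficient covariance."""
    b0, b1 = _coefs(fit)
    if b1 <= 0:
        raise NonIdentifiableError("D95 requires a positive size slope")
    cov = fit.covariance if isinstance(fit, DetectabilityFit) else fit.cov_params_
    grad = np.array([-1.0 / b1, -(LOGIT95 - b0) / b1 ** 2])
    return float(math.sqrt(grad @ cov @ grad))


def _coefs(fit) -> tuple[float, float]:
    if isinstance(fit, DetectabilityFit):
        return fit.beta0, fit.beta1
    return float(fit.intercept_), float(fit.coef_[0])


class DetectabilityGLM(ClassifierMixin, BaseEstimator):
    """Binomial GLM of detection on body size, scikit-learn style.

    A single-feature logistic regression fitted by the package's own IRLS
    (no penalty), exposing the detectability quantities as fitted
    attributes: ``intercept_``, ``coef_``, ``cov_params_``, ``d95_`` and
    ``d95_se_``.  Perfect separation is reported through ``separation_``
    (with :class:`SeparationWarning`); D95 is then the midpoint between the
    largest undetected and smallest detected size, flagged non-regular.

    Parameters
    ----------
    tol : float
        IRLS convergence tolerance on the max coefficient step.
    max_iter : int
        Maximum IRLS iterations.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y) -> "DetectabilityGLM":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("DetectabilityGLM models detection on a single size column")
        y = np.asarray(y).astype(float).ravel()
        if X.shape[0] != y.size or y.size == 0:
            raise ValueError("X and y sizes do not match or are empty")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("y must be binary (detected yes/no)")
        size = X[:, 0]
        if np.unique(size).size < 2:
            raise ValueError("need at least two distinct sizes")
        if y.min() == y.max():
            raise ValueError("both outcomes (detected and undetected) are required")

        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 1
        design = np.column_stack([np.ones_like(size), size])
        beta, cov, n_iter, converged = _irls_logit(design, y, self.tol, self.max_iter)
        self.intercept_ = float(beta[0])
        self.coef_ = np.array([beta[1]])
        self.cov_params_ = cov
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.separation_ = _perfectly_separated(size, y)
        if self.separation_:
            mid = 0.5 * (float(size[y == 0].max()) + float(size[y == 1].min()))
            warnings.warn(
                "perfect separation: the MLE is not regular; D95 reported "
                f"as the separation midpoint {mid:.3g}", SeparationWarning,
                stacklevel=2)
            self.d95_ = mid
            self.d95_se_ = math.nan
        else:
            self.d95_ = d95(self)
            self.d95_se_ = d95_standard_error(self)
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X[:, 0] * self.coef_[0]

    def predict_proba(self, X) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0.0).astype(int)

    def to_fit(self, group: str = "", n_trials: int | None = None) -> DetectabilityFit:
        return DetectabilityFit(
            group=group, beta0=self.intercept_, beta1=float(self.coef_[0]),
            covariance=self.cov_params_, d95=self.d95_, d95_se=self.d95_se_,
            n_trials=n_trials if n_trials is not None else 0,
            converged=self.converged_, separation=self.separation_)


# ---------------------------------------------------------------------
# drop experiments
# ---------------------------------------------------------------------

def binned_population(template: ObjectDescriptor,
                      bin_edges: Sequence[float],
                      n_per_bin: int,
                      seed: int) -> list[ObjectDescriptor]:
    """Objects with sizes drawn uniformly inside consecutive size bins.

    The default grain protocol uses 0.2 mm bins spanning 0.2-1.8 mm (eight
    bins) with ~20 particles each.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with at least two entries")
    rng = np.random.default_rng(seed)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        for s in rng.uniform(lo, hi, size=n_per_bin):
            out.append(with_size(template, float(s)))
    return out


def grain_population(n_per_bin: int = 20, seed: int = 0,
                     bin_edges: Sequence[float] | None = None) -> list[ObjectDescriptor]:
    """The grain drop protocol population (0.2 mm bins over 0.2-1.8 mm)."""
    edges = np.arange(0.2, 1.8001, 0.2) if bin_edges is None else bin_edges
    return binned_population(GRAIN, edges, n_per_bin, seed)


def _trial_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    # counter-based child derivation: reproducible and order-independent
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))


def run_drop_experiment(
    geom: RingGeometry,
    cfg: DetectorConfig,
    fe: FrontEndConfig,
    population: Sequence[ObjectDescriptor],
    n_per_size: int = 1,
    seed: int = 0,
    drop_height: float = 38.0,
    keep_signals: bool = False,
) -> pd.DataFrame:
    """Drop every object of ``population`` (``n_per_size`` times each)
    through the ring and record whether it was detected.

    Each trial draws an independent entry position, uniform over the
    sensing aperture disk, and an independent noise stream, all derived
    from the master seed by counter-based child seeding, so the whole
    experiment is reproducible.  Returns a tidy trial table with one row
    per drop.
    """
    if not population:
        raise ValueError("population must not be empty")
    if n_per_size < 1:
        raise ValueError("n_per_size must be >= 1")
    rows = []
    signals: list[ChannelSignal] = []
    idx = 0
    r_ap = geom.aperture_diameter / 2.0
    for obj in population:
        for _ in range(n_per_size):
            ss = _trial_seed(seed, idx)
            child = int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF
            rng = np.random.default_rng(ss)
            r = r_ap * math.sqrt(rng.uniform())
            th = rng.uniform(0.0, 2.0 * math.pi)
            entry = (r * math.cos(th), r * math.sin(th))
            drop = DropParams(entry=entry, drop_height=drop_height)
            try:
                sig = simulate_signal(geom, obj, fe, drop, seed=child)
                events = detect_stream(sig, cfg)
            except Exception as exc:  # noqa: BLE001 - logged fault, not silent miss
                warnings.warn(f"trial {idx} aborted: {exc}", RuntimeWarning, stacklevel=2)
                idx += 1
                continue
            rows.append({
                "trial": idx, "group": obj.group_label, "size_mm": obj.size,
                "entry_x": entry[0], "entry_y": entry[1], "seed": child,
                "detected": bool(events),
                "n_events": len(events),
                "amplitude": events[0].normalized_amplitude if events else 0,
            })
            if keep_signals:
                signals.append(sig)
            idx += 1
    frame = pd.DataFrame(rows)
    if keep_signals:
        frame.attrs["signals"] = signals
    return frame


def fit_detectability(trials: pd.DataFrame, pooled: bool = False,
                      tol: float = 1e-8, max_iter: int = 100) -> dict[str, DetectabilityFit]:
    """Fit the logistic detectability model per group.

    ``trials`` needs columns ``group``, ``size_mm`` and ``detected``.  With
    ``pooled=True`` a single model with group-specific intercepts and a
    shared size slope is fitted instead of independent per-group models.
    """
    required = {"group", "size_mm", "detected"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trials table needs columns {sorted(required)}")
    if len(trials) == 0:
        raise ValueError("empty trials table")
    if pooled:
        return _fit_pooled(trials, tol, max_iter)
    fits: dict[str, DetectabilityFit] = {}
    for group, sub in trials.groupby("group", sort=True):
        model = DetectabilityGLM(tol=tol, max_iter=max_iter)
        model.fit(sub["size_mm"].to_numpy(), sub["detected"].to_numpy().astype(int))
        fits[str(group)] = model.to_fit(group=str(group), n_trials=len(sub))
    return fits


def _fit_pooled(trials: pd.DataFrame, tol: float, max_iter: int) -> dict[str, DetectabilityFit]:
    """Shared-slope model: one size coefficient, one intercept per group."""
    groups = sorted(map(str, trials["group"].unique()))
    size = trials["size_mm"].to_numpy(dtype=float)
    y = trials["detected"].to_numpy().astype(float)
    dummies = np.column_stack([(trials["group"].astype(str) == g).to_numpy(float)
                               for g in groups])
    X = np.column_stack([dummies, size])  # coef order: intercepts..., slope
    beta, cov, _, converged = _irls_logit(X, y, tol, max_iter)
    slope = float(beta[-1])
    fits = {}
    for j, g in enumerate(groups):
        b0 = float(beta[j])
        sub_cov = cov[np.ix_([j, len(groups)], [j, len(groups)])]
        if slope > 0:
            d = (LOGIT95 - b0) / slope
            grad = np.array([-1.0 / slope, -(LOGIT95 - b0) / slope ** 2])
            se = float(math.sqrt(grad @ sub_cov @ grad))
        else:
            d, se = math.nan, math.nan
        fits[g] = DetectabilityFit(group=g, beta0=b0, beta1=slope,
                                   covariance=sub_cov, d95=d, d95_se=se,
                                   n_trials=int((trials["group"].astype(str) == g).sum()),
                                   converged=converged)
    return fits


# ---------------------------------------------------------------------
# noise calibration
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseCalibration:
    noise_sigma: float
    achieved_d95: float
    n_evaluations: int


def _experiment_d95(geom: RingGeometry, cfg: DetectorConfig, fe: FrontEndConfig,
                    population: Sequence[ObjectDescriptor], seed: int,
                    size_lo: float, size_hi: float) -> float:
    trials = run_drop_experiment(geom, cfg, fe, population, seed=seed)
    sizes = trials["size_mm"].to_numpy()
    det = trials["detected"].to_numpy().astype(int)
    if det.min() == det.max():
        # degenerate experiment: everything (or nothing) detected
        return size_lo if det.min() == 1 else size_hi * 2.0
    model = DetectabilityGLM()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        model.fit(sizes, det)
    if model.separation_:
        return float(model.d95_)
    try:
        return float(d95(model))
    except NonIdentifiableError:
        return size_hi * 2.0


def calibrate_noise(
    geom: RingGeometry,
    cfg: DetectorConfig = ST100,
    target_d95: float = 0.9,
    material: ObjectDescriptor = GRAIN,
    seed: int = 0,
    fe: FrontEndConfig | None = None,
    n_per_bin: int = 60,
    sigma_bounds: tuple[float, float] = (0.0, 120.0),
    tol_mm: float = 0.04,
    max_iter: int = 18,
) -> NoiseCalibration:
    """Bisect the front-end noise level until the simulated grain
    experiment reproduces ``target_d95``.

    Uses common random numbers (the same master seed for every noise
    evaluation) so the fitted D95 is a monotone function of the noise
    level; with additive noise and a fixed threshold, more noise helps
    small dips across the threshold, so D95 *decreases* with sigma and the
    zero-noise D95 must sit above the target for the bracket to close.
    """
    fe = fe or FrontEndConfig()
    pop = binned_population(material, np.arange(0.2, 1.8001, 0.2), n_per_bin,
                            seed=seed)
    size_lo, size_hi = 0.2, 1.8

    def evaluate(sigma: float) -> float:
        return _experiment_d95(geom, cfg, replace(fe, noise_sigma=sigma), pop,
                               seed, size_lo, size_hi)

    lo, hi = sigma_bounds
    d_lo, d_hi = evaluate(lo), evaluate(hi)
    n_eval = 2
    increasing = d_hi > d_lo
    if not (min(d_lo, d_hi) <= target_d95 <= max(d_lo, d_hi)):
        raise CalibrationError(
            f"target D95 {target_d95} mm not bracketed: D95({lo})={d_lo:.3f}, "
            f"D95({hi})={d_hi:.3f}")
    best = (lo, d_lo) if abs(d_lo - target_d95) < abs(d_hi - target_d95) else (hi, d_hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        d_mid = evaluate(mid)
        n_eval += 1
        if abs(d_mid - target_d95) < abs(best[1] - target_d95):
            best = (mid, d_mid)
        if abs(d_mid - target_d95) <= tol_mm:
            break
        if (d_mid > target_d95) == (not increasing):
            lo = mid
        else:
            hi = mid
    return NoiseCalibration(noise_sigma=best[0], achieved_d95=best[1],
                            n_evaluations=n_eval)
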