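"""Second-order system identification of pursuit-tracking behavior.

A tracking trial pairs a target trajectory ``u`` (the desired force profile,
in %MVC) with the subject's response ``y``.  Performance is summarized two
ways: the raw RMS tracking error, and the parameters of a discrete
second-order linear dynamical system (LDS)

    x_t = A x_{t-1} + B u_{t-1},    y_t = C x_t + D u_t

fitted to the trial.  The eigenvalues of ``A`` are mapped to continuous-time
poles ``s = log(lambda)/dt`` and then to the damping ratio ``zeta`` and
natural frequency ``omega_n`` via the pole formula

    s_{1,2} = -zeta*omega_n +/- omega_n*sqrt(zeta**2 - 1),

plus the classic step-response metrics (rise, peak and settling time).
Underdamped systems (zeta < 1) overshoot the target; overdamped ones
(zeta > 1) respond sluggishly.
"""

from __future__ import annotations

import cmath
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal, stats


def _tf2ss_quiet(num, den):
    # tf2ss warns about a stripped leading zero in strictly proper numerators
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", signal.BadCoefficients)
        return signal.tf2ss(num, den)


class InvalidTrialError(ValueError):
    """The trial arrays violate the tracking-trial contract."""


class UnidentifiableInputError(ValueError):
    """The input trajectory does not excite the system (e.g. constant u)."""


class RankDeficientDataError(ValueError):
    """The regression problem built from the trial is rank deficient."""


class DegeneratePolesError(ValueError):
    """Discrete eigenvalues admit no real-valued second-order interpretation."""


@dataclass(frozen=True)
class TrackingTrial:
    """Paired target/response trajectories sampled on a uniform grid.

    Attributes
    ----------
    time : array, seconds, strictly increasing and approximately uniform.
    u : target trajectory (%MVC).
    y : response trajectory (%MVC).
    dt : nominal sampling interval in seconds.
    """

    time: np.ndarray
    u: np.ndarray
    y: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        u = np.asarray(self.u, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "y", y)
        n = len(time)
        if not (len(u) == len(y) == n):
            raise InvalidTrialError(
                f"length mismatch: time={n}, u={len(u)}, y={len(y)}"
            )
        if n < 20:
            raise InvalidTrialError(f"need at least 20 samples, got {n}")
        if not (np.isfinite(time).all() and np.isfinite(u).all() and np.isfinite(y).all()):
            raise InvalidTrialError("non-finite values in trial")
        diffs = np.diff(time)
        if np.any(diffs <= 0):
            raise InvalidTrialError("time must be strictly increasing")
        if self.dt <= 0:
            raise InvalidTrialError("dt must be positive")
        if np.max(np.abs(diffs - self.dt)) >= 0.2 * self.dt:
            raise InvalidTrialError("sampling grid deviates from dt by >= 20%")

    @property
    def n_samples(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class LDSModel:
    """Discrete state-space model x_t = A x_{t-1} + B u_{t-1}, y_t = C x_t + D u_t."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        B = np.asarray(self.B, dtype=float).reshape(A.shape[0], -1)
        C = np.asarray(self.C, dtype=float).reshape(-1, A.shape[0])
        D = np.atleast_2d(np.asarray(self.D, dtype=float))
        if A.shape != (2, 2):
            raise ValueError(f"A must be 2x2, got {A.shape}")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "D", D)
        if not np.isfinite(np.linalg.eigvals(A)).all():
            raise ValueError("eigenvalues of A must be finite")

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.A)

    @property
    def is_stable(self) -> bool:
        return bool(np.all(np.abs(self.eigenvalues) < 1.0))

    def dc_gain(self) -> float:
        """Steady-state gain C (I - A)^-1 B + D."""
        return float(
            (self.C @ np.linalg.solve(np.eye(2) - self.A, self.B) + self.D).squeeze()
        )

    def simulate(self, u: np.ndarray, x0: np.ndarray | None = None) -> np.ndarray:
        """Response of the model to input ``u`` from initial state ``x0``."""
        u = np.asarray(u, dtype=float)
        x = np.zeros(2) if x0 is None else np.asarray(x0, dtype=float)
        b = self.B.reshape(2)
        d = float(self.D.reshape(-1)[0])
        y = np.empty_like(u)
        y[0] = float((self.C @ x)[0]) + d * u[0]
        for t in range(1, len(u)):
            x = self.A @ x + b * u[t - 1]
            y[t] = float((self.C @ x)[0]) + d * u[t]
        return y


Classification = Literal["underdamped", "critically_damped", "overdamped", "degenerate"]

#: |zeta - 1| below this counts as critically damped.
CRITICAL_TOL = 1e-9


@dataclass(frozen=True)
class ResponseMetrics:
    """Damping ratio, natural frequency and step-response timing of one fit.

    ``peak_time`` is defined only for underdamped systems (zeta < 1).
    ``settling_time`` uses the 2% band approximation 4/(zeta*omega_n);
    ``settling_time_simulated`` is the last exit of the simulated step
    response from the 2% band.  ``rise_time`` is the 10%->90% rise of the
    simulated unit-step response.
    """

    zeta: float
    omega_n: float
    rise_time: float
    peak_time: float | None
    settling_time: float
    classification: Classification
    stable: bool = True
    settling_time_simulated: float = field(default=math.nan)


def rms_error(trial: TrackingTrial) -> float:
    """Root-mean-square tracking error sqrt(mean((y - u)^2))."""
    return float(np.sqrt(np.mean((trial.y - trial.u) ** 2)))


def _arx2_coefficients(trial: TrackingTrial) -> np.ndarray:
    """Least-squares ARX(2) fit: y_t on [y_{t-1}, y_{t-2}, u_t, u_{t-1}, u_{t-2}]."""
    y, u = trial.y, trial.u
    target = y[2:]
    X = np.column_stack([y[1:-1], y[:-2], u[2:], u[1:-1], u[:-2]])
    coef, _, rank, sv = np.linalg.lstsq(X, target, rcond=None)
    if rank < X.shape[1]:
        # Constant input is the common culprit; diagnose before the generic error.
        if np.var(u) == 0:
            raise UnidentifiableInputError(
                "target trajectory u is constant: the input does not excite the system"
            )
        raise RankDeficientDataError(
            f"ARX regression rank {rank} < {X.shape[1]}; singular values {sv}"
        )
    if np.var(u) == 0:
        raise UnidentifiableInputError(
            "target trajectory u is constant: the input does not excite the system"
        )
    return coef


def _fit_arx(trial: TrackingTrial) -> LDSModel:
    a1, a2, b0, b1, b2 = _arx2_coefficients(trial)
    # y_t = a1 y_{t-1} + a2 y_{t-2} + b0 u_t + b1 u_{t-1} + b2 u_{t-2}
    # <=> H(z) = (b0 z^2 + b1 z + b2) / (z^2 - a1 z - a2)
    A, B, C, D = _tf2ss_quiet([b0, b1, b2], [1.0, -a1, -a2])
    return LDSModel(A=A, B=B, C=C, D=D, dt=trial.dt)


def _zoh_response(zeta: float, omega_n: float, gain: float, u: np.ndarray, dt: float) -> np.ndarray:
    """Simulated ZOH response of gain * omega_n^2/(s^2 + 2 zeta omega_n s + omega_n^2)."""
    numd, dend, _ = signal.cont2discrete(
        ([gain * omega_n**2], [1.0, 2.0 * zeta * omega_n, omega_n**2]), dt, method="zoh"
    )
    return signal.lfilter(np.atleast_1d(numd.squeeze()), dend, u)


def _oe_refine(trial: TrackingTrial, zeta0: float, omega0: float) -> LDSModel:
    """Output-error fit of (zeta, omega_n, gain) by simulation-error least squares.

    The gain is profiled out at the initial point and then co-optimized.
    Consistent under white measurement noise, where the one-step ARX
    regression is not.
    """
    from scipy.optimize import least_squares

    u, y, dt = trial.u, trial.y, trial.dt

    def best_gain(z: float, w: float) -> float:
        yhat1 = _zoh_response(z, w, 1.0, u, dt)
        denom = float(yhat1 @ yhat1)
        return float(yhat1 @ y) / denom if denom > 0 else 0.0

    def residual(theta: np.ndarray) -> np.ndarray:
        z, w = np.exp(theta[0]), np.exp(theta[1])
        return _zoh_response(z, w, theta[2], u, dt) - y

    x0 = np.array([math.log(zeta0), math.log(omega0), best_gain(zeta0, omega0)])
    sol = least_squares(residual, x0, method="lm", xtol=1e-12, ftol=1e-12)
    z, w, g = math.exp(sol.x[0]), math.exp(sol.x[1]), sol.x[2]
    numd, dend, _ = signal.cont2discrete(
        ([g * w**2], [1.0, 2.0 * z * w, w**2]), dt, method="zoh"
    )
    A, B, C, D = _tf2ss_quiet(np.atleast_1d(numd.squeeze()), dend)
    return LDSModel(A=A, B=B, C=C, D=D, dt=dt)


#: coarse initialization grid for the output-error fit when the ARX poles
#: admit no (zeta, omega_n) interpretation
_OE_INIT_GRID = [(z, w) for z in (0.2, 0.5, 0.8, 1.2, 2.0) for w in (0.5, 1.5, 3.0, 6.0)]


def fit_lds(trial: TrackingTrial, order: int = 2, method: str = "oe") -> LDSModel:
    """Fit the discrete second-order LDS relating target to response.

    ``method="arx"`` is the plain one-step least-squares ARX(2) fit converted
    to state space; it is exact on noise-free second-order data (fitted poles
    match the generator's discrete poles to near machine precision) but
    biased under measurement noise.  The default ``method="oe"`` refines the
    ARX initialization by minimizing the *simulation* error over the
    second-order (zeta, omega_n, gain) family, which is consistent under
    white output noise; it reduces to the exact solution on noise-free data.
    """
    if order != 2:
        raise NotImplementedError("only second-order models are supported")
    if trial.n_samples < 10 * order:
        raise InvalidTrialError(
            f"need at least {10 * order} samples to fit order {order}, got {trial.n_samples}"
        )
    if np.max(np.abs(trial.y)) <= 1e-12 * max(1.0, np.max(np.abs(trial.u))):
        # null response: the zero-gain model is exact and the ARX regression
        # would be rank deficient
        if np.var(trial.u) == 0:
            raise UnidentifiableInputError(
                "target trajectory u is constant: the input does not excite the system"
            )
        return LDSModel(
            A=np.zeros((2, 2)), B=[[1.0], [0.0]], C=[[0.0, 0.0]], D=0.0, dt=trial.dt
        )
    arx = _fit_arx(trial)
    if method == "arx":
        return arx
    if method != "oe":
        raise ValueError(f"unknown method {method!r}")
    inits: list[tuple[float, float]] = []
    try:
        s = discrete_to_continuous_poles(arx.eigenvalues, trial.dt)
        m = poles_to_metrics(s)
        if math.isfinite(m.zeta) and m.zeta > 0 and math.isfinite(m.omega_n):
            inits.append((min(max(m.zeta, 1e-3), 50.0), min(max(m.omega_n, 1e-3), 1e3)))
    except (DegeneratePolesError, ValueError):
        pass
    if not inits:
        u, y, dt = trial.u, trial.y, trial.dt

        def sse(z: float, w: float) -> float:
            yhat = _zoh_response(z, w, 1.0, u, dt)
            d = float(yhat @ yhat)
            g = float(yhat @ y) / d if d > 0 else 0.0
            return float(np.sum((g * yhat - y) ** 2))

        inits.append(min(_OE_INIT_GRID, key=lambda p: sse(*p)))
    return _oe_refine(trial, *inits[0])


def discrete_to_continuous_poles(
    eigs: Sequence[complex] | np.ndarray, dt: float
) -> np.ndarray:
    """Map discrete eigenvalues to continuous poles via the principal log.

    ``s = log(lambda)/dt``; the round trip ``exp(s*dt)`` reproduces ``lambda``
    to 1e-12.  Eigenvalues on the non-positive real axis have no real-valued
    second-order continuous counterpart at this sampling rate and raise
    :class:`DegeneratePolesError`.
    """
    eigs = np.asarray(eigs, dtype=complex)
    if dt <= 0:
        raise ValueError("dt must be positive")
    for lam in eigs:
        if lam == 0:
            raise DegeneratePolesError("zero eigenvalue has no continuous pole")
        if lam.imag == 0 and lam.real < 0:
            raise DegeneratePolesError(
                f"negative real eigenvalue {lam.real:g} has no real-valued "
                "second-order interpretation"
            )
    return np.array([cmath.log(lam) / dt for lam in eigs])


def _simulated_step_metrics(zeta: float, omega_n: float) -> tuple[float, float]:
    """(rise_time, settling_time_simulated) from a brute-force unit-step response."""
    # Horizon: several settling times, or many periods for tiny damping.
    if zeta > 0:
        horizon = max(8.0 / (zeta * omega_n), 4.0 * 2.0 * math.pi / omega_n)
    else:
        horizon = 50.0 * 2.0 * math.pi / omega_n
    n = 20000
    t = np.linspace(0.0, horizon, n)
    sys = signal.TransferFunction([omega_n**2], [1.0, 2.0 * zeta * omega_n, omega_n**2])
    _, y = signal.step(sys, T=t)
    final = 1.0  # unity DC gain by construction

    def first_crossing(level: float) -> float:
        idx = np.nonzero(y >= level)[0]
        if len(idx) == 0:
            return math.nan
        i = idx[0]
        if i == 0:
            return t[0]
        # linear interpolation between samples
        return float(np.interp(level, [y[i - 1], y[i]], [t[i - 1], t[i]]))

    t10 = first_crossing(0.1 * final)
    t90 = first_crossing(0.9 * final)
    rise = t90 - t10 if math.isfinite(t90) and math.isfinite(t10) else math.nan

    if zeta <= 0:
        return rise, math.inf
    outside = np.abs(y - final) > 0.02 * final
    if not outside.any():
        settle_sim = t[0]
    else:
        last_out = np.nonzero(outside)[0][-1]
        settle_sim = float(t[last_out + 1]) if last_out + 1 < n else math.inf
    return rise, settle_sim


def poles_to_metrics(s_poles: Sequence[complex] | np.ndarray) -> ResponseMetrics:
    """Convert a continuous pole pair into (zeta, omega_n) and timing metrics.

    For a conjugate pair, ``omega_n = |s|`` and ``zeta = -Re(s)/|s|``; for a
    real pair, ``omega_n = sqrt(s1*s2)`` and ``zeta = -(s1+s2)/(2*omega_n)``.
    Poles with positive real part are flagged unstable but metrics are still
    reported.
    """
    s = np.asarray(s_poles, dtype=complex)
    if len(s) != 2:
        raise ValueError("expected a pole pair")
    s1, s2 = s
    is_complex = abs(s1.imag) > 1e-12 * max(1.0, abs(s1))
    if is_complex:
        if abs(s1 - s2.conjugate()) > 1e-6 * max(1.0, abs(s1)):
            raise ValueError("complex poles must form a conjugate pair")
        omega_n = abs(s1)
        zeta = -s1.real / omega_n
    else:
        r1, r2 = s1.real, s2.real
        prod = r1 * r2
        if prod <= 0:
            raise DegeneratePolesError(
                "real pole pair with non-positive product has no (zeta, omega_n) form"
            )
        omega_n = math.sqrt(prod)
        zeta = -(r1 + r2) / (2.0 * omega_n)

    stable = bool(s1.real < 0 and s2.real < 0)
    if abs(zeta - 1.0) <= CRITICAL_TOL:
        classification: Classification = "critically_damped"
    elif zeta < 1.0:
        classification = "underdamped"
    else:
        classification = "overdamped"

    peak_time = (
        math.pi / (omega_n * math.sqrt(1.0 - zeta**2)) if zeta < 1.0 else None
    )
    settling = 4.0 / (zeta * omega_n) if zeta > 0 else math.inf
    rise, settle_sim = _simulated_step_metrics(max(zeta, 0.0), omega_n)
    return ResponseMetrics(
        zeta=float(zeta),
        omega_n=float(omega_n),
        rise_time=rise,
        peak_time=peak_time,
        settling_time=settling,
        classification=classification,
        stable=stable,
        settling_time_simulated=settle_sim,
    )


def trial_metrics(trial: TrackingTrial) -> ResponseMetrics:
    """Fit the trial and return its response metrics.

    Fits that yield discrete eigenvalues without a continuous second-order
    interpretation are reported with ``classification='degenerate'`` and NaN
    parameters instead of raising.
    """
    model = fit_lds(trial)
    try:
        s = discrete_to_continuous_poles(model.eigenvalues, model.dt)
        return poles_to_metrics(s)
    except DegeneratePolesError:
        return ResponseMetrics(
            zeta=math.nan,
            omega_n=math.nan,
            rise_time=math.nan,
            peak_time=None,
            settling_time=math.nan,
            classification="degenerate",
            stable=False,
        )


def aggregate_subject_metrics(
    run_metrics: Sequence[ResponseMetrics], aggregator: str = "mean"
) -> ResponseMetrics:
    """Aggregate per-run metrics into one per-subject summary.

    ``zeta`` and ``omega_n`` are aggregated over non-degenerate runs (mean by
    default, median selectable); the timing metrics are recomputed from the
    aggregated parameters so the summary is internally consistent.
    """
    valid = [m for m in run_metrics if m.classification != "degenerate"]
    if not valid:
        raise ValueError("all runs are degenerate; nothing to aggregate")
    agg = {"mean": np.mean, "median": np.median}.get(aggregator)
    if agg is None:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    zeta = float(agg([m.zeta for m in valid]))
    omega_n = float(agg([m.omega_n for m in valid]))
    wd = omega_n * math.sqrt(max(1.0 - zeta**2, 0.0))
    if zeta < 1.0 and wd > 0:
        s = np.array([complex(-zeta * omega_n, wd), complex(-zeta * omega_n, -wd)])
    else:
        root = omega_n * math.sqrt(max(zeta**2 - 1.0, 0.0))
        s = np.array([-zeta * omega_n + root, -zeta * omega_n - root], dtype=complex)
    return poles_to_metrics(s)


def compare_rms_groups(
    rms_values: Sequence[float], labels: Sequence
) -> tuple[float, float]:
    """One-way ANOVA of RMS errors across labelled groups; returns (F, p)."""
    rms_values = np.asarray(rms_values, dtype=float)
    labels = np.asarray(labels)
    groups = [rms_values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least two observations")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
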