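"""Seeded generators for tracking trials, ROI time series and cohorts.

Every generator is a pure function of its spec (same spec, same output) and
carries its generating parameters alongside the data, so downstream recovery
tests compare estimates against stored truth rather than re-deriving it.

The study conditions emulated here: a 0.5 Hz sinusoidal force target kept
between 5 and 15 %MVC over 90 s runs sampled at 50 Hz, tracked by a noisy
second-order system; stationary sparse lag-1 vector-autoregressive ROI
series at TR = 1.985 s; and rigidity scores generated as a sparse linear
function of connection strengths plus noise, Y = X beta + eps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import signal

from rigidnet.tracking import LDSModel, TrackingTrial


class InvalidSpecError(ValueError):
    """A simulation spec violates its invariants."""


class NonStationarySpecError(InvalidSpecError):
    """The requested VAR coefficient matrix has spectral radius >= 1."""


#: samples discarded before returning a VAR series (stationarity warm-up)
VAR_BURN_IN = 200


@dataclass(frozen=True)
class TrackingSimSpec:
    """Parameters of one simulated pursuit-tracking run.

    zeta / omega_n define the second-order tracker; the target is a
    ``target_freq`` Hz sinusoid spanning [amp_low, amp_high] %MVC for
    ``duration`` seconds at ``sample_rate`` Hz; ``noise_sd`` is the sd of
    i.i.d. Gaussian response noise in %MVC.
    """

    zeta: float
    omega_n: float
    target_freq: float = 0.5
    amp_low: float = 5.0
    amp_high: float = 15.0
    duration: float = 90.0
    sample_rate: float = 50.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0:
            raise InvalidSpecError("duration and sample_rate must be positive")
        n = self.duration * self.sample_rate
        if abs(n - round(n)) > 1e-9 or round(n) <= 0:
            raise InvalidSpecError(
                "duration * sample_rate must be a positive integer sample count"
            )
        if self.amp_low > self.amp_high:
            raise InvalidSpecError("amp_low must not exceed amp_high")
        if self.zeta < 0 or self.omega_n <= 0 or self.noise_sd < 0:
            raise InvalidSpecError("zeta, noise_sd must be >= 0 and omega_n > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate


def generate_target_trajectory(spec: TrackingSimSpec) -> np.ndarray:
    """Sinusoidal target u(t) = midpoint + half-range * sin(2 pi f t)."""
    t = np.arange(spec.n_samples) * spec.dt
    mid = 0.5 * (spec.amp_low + spec.amp_high)
    half = 0.5 * (spec.amp_high - spec.amp_low)
    return mid + half * np.sin(2.0 * np.pi * spec.target_freq * t)


def second_order_discrete(zeta: float, omega_n: float, dt: float) -> LDSModel:
    """Zero-order-hold discretization of the unity-gain second-order system.

    Continuous transfer function omega_n^2 / (s^2 + 2 zeta omega_n s +
    omega_n^2), whose poles are s = -zeta*omega_n +/- omega_n*sqrt(zeta^2-1).
    """
    num = [omega_n**2]
    den = [1.0, 2.0 * zeta * omega_n, omega_n**2]
    A, B, C, D, _ = signal.cont2discrete(signal.tf2ss(num, den), dt, method="zoh")
    return LDSModel(A=A, B=B, C=C, D=D, dt=dt)


def simulate_tracking_trial(spec: TrackingSimSpec) -> TrackingTrial:
    """Simulate the tracker's response to the sinusoidal target.

    The response is the ZOH discretization of the unity-DC-gain second-order
    system driven by the target, plus i.i.d. Gaussian noise of sd
    ``noise_sd``.  Deterministic given the spec (seed included).
    """
    u = generate_target_trajectory(spec)
    t = np.arange(spec.n_samples) * spec.dt
    model = second_order_discrete(spec.zeta, spec.omega_n, spec.dt)
    y = model.simulate(u)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=len(y))
    return TrackingTrial(time=t, u=u, y=y, dt=spec.dt)


@dataclass(frozen=True)
class NetworkSimSpec:
    """Parameters of a stationary lag-1 vector-autoregressive ROI network.

    ``coeff_matrix[j, i]`` is the influence of ROI i at time t-1 on ROI j at
    time t.  The spectral radius must be < 1 for stationarity.  Diagonal
    self-loops are permitted in simulation but are excluded from the edge
    universe reported by the network-inference stage.
    """

    n_rois: int
    coeff_matrix: np.ndarray
    innovation_sd: float = 1.0
    n_timepoints: int = 270
    tr: float = 1.985
    seed: int = 0

    def __post_init__(self) -> None:
        W = np.asarray(self.coeff_matrix, dtype=float)
        object.__setattr__(self, "coeff_matrix", W)
        if W.shape != (self.n_rois, self.n_rois):
            raise InvalidSpecError(
                f"coeff_matrix shape {W.shape} != ({self.n_rois}, {self.n_rois})"
            )
        if self.innovation_sd <= 0 or self.n_timepoints < 2 or self.tr <= 0:
            raise InvalidSpecError("innovation_sd, n_timepoints, tr must be positive")

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.coeff_matrix))))


def simulate_roi_timeseries(spec: NetworkSimSpec) -> np.ndarray:
    """Simulate x_t = W x_{t-1} + e_t, e_t ~ N(0, innovation_sd^2 I).

    A burn-in of ``VAR_BURN_IN`` samples is discarded so the returned
    ``n_timepoints x n_rois`` series is approximately stationary.
    """
    if spec.spectral_radius >= 1.0:
        raise NonStationarySpecError(
            f"spectral radius {spec.spectral_radius:.3f} >= 1: series would diverge"
        )
    rng = np.random.default_rng(spec.seed)
    W = spec.coeff_matrix
    total = spec.n_timepoints + VAR_BURN_IN
    e = rng.normal(0.0, spec.innovation_sd, size=(total, spec.n_rois))
    x = np.empty((total, spec.n_rois))
    x[0] = e[0]
    for t in range(1, total):
        x[t] = W @ x[t - 1] + e[t]
    return x[VAR_BURN_IN:]


def stationary_covariance(W: np.ndarray, innovation_sd: float) -> np.ndarray:
    """Stationary covariance Sigma solving Sigma = W Sigma W' + sd^2 I."""
    from scipy.linalg import solve_discrete_lyapunov

    return solve_discrete_lyapunov(np.asarray(W, float), innovation_sd**2 * np.eye(len(W)))


def edge_slots(n_rois: int, n_connections: int) -> list[tuple[int, int]]:
    """First ``n_connections`` directed (source, target) pairs, source != target,
    in lexicographic order — the cohort's fixed edge universe."""
    slots = [(i, j) for i in range(n_rois) for j in range(n_rois) if i != j]
    if n_connections > len(slots):
        raise InvalidSpecError(
            f"n_connections={n_connections} exceeds {n_rois}*{n_rois - 1} possible edges"
        )
    return slots[:n_connections]


@dataclass(frozen=True)
class CohortSimSpec:
    """Parameters of a simulated cohort linking connectivity to rigidity.

    Rigidity scores follow Y = X beta + eps where X holds per-subject
    connection strengths over ``n_connections`` edge slots and beta is
    nonzero only on ``true_support``.  ``strength_jitter_sd`` is the
    multiplicative between-subject variation of nonzero base coefficients;
    ``strength_noise_sd`` is a small additive strength variability applied to
    every edge slot (it keeps X full rank, emulating estimation-level spread
    of connection strengths).
    """

    n_subjects: int
    n_connections: int
    true_support: tuple[int, ...]
    beta_values: tuple[float, ...]
    score_noise_sd: float = 1.0
    clip_range: tuple[float, float] | None = None
    strength_jitter_sd: float = 0.2
    strength_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_support", tuple(self.true_support))
        object.__setattr__(self, "beta_values", tuple(self.beta_values))
        if self.n_subjects < 2:
            raise InvalidSpecError("need at least 2 subjects")
        if len(self.true_support) != len(self.beta_values):
            raise InvalidSpecError("true_support and beta_values must align")
        if len(self.true_support) > self.n_connections:
            raise InvalidSpecError("more true effects than connections")
        if any(k < 0 or k >= self.n_connections for k in self.true_support):
            raise InvalidSpecError("true_support index out of range")
        if self.score_noise_sd < 0:
            raise InvalidSpecError("score_noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters carried alongside every simulated dataset."""

    tracking: dict = field(default_factory=dict)
    coeff_matrices: dict = field(default_factory=dict)
    true_support: tuple[int, ...] = ()
    beta: tuple[float, ...] = ()

    def to_json(self) -> str:
        payload = asdict(self)
        payload["coeff_matrices"] = {
            k: np.asarray(v).tolist() for k, v in payload["coeff_matrices"].items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass(frozen=True)
class CohortData:
    """One simulated cohort: per-subject ROI series, strengths and scores."""

    subject_ids: tuple[str, ...]
    roi_series: dict[str, np.ndarray]
    X: np.ndarray
    Y: np.ndarray
    edge_slots: tuple[tuple[int, int], ...]
    truth: GroundTruth


def simulate_cohort(
    cohort: CohortSimSpec, net: NetworkSimSpec, slot_rule: str = "lex"
) -> CohortData:
    """Simulate a cohort: per-subject networks, ROI series and scores.

    Each subject receives a perturbed copy of the base coefficient matrix
    (multiplicative Gaussian jitter on nonzero entries plus small additive
    strength noise on every edge slot), an ROI series simulated from it, and
    a score Y = X beta + eps, optionally clipped and rounded to the ordinal
    clinical range.

    ``slot_rule`` fixes the edge universe X is indexed by: ``"lex"`` takes
    the first ``n_connections`` off-diagonal (source, target) pairs in
    lexicographic order; ``"support"`` takes the nonzero off-diagonal
    entries of the base coefficient matrix (whose count must then equal
    ``n_connections``), so the cohort's columns are exactly the true
    network's connections.
    """
    if slot_rule == "lex":
        slots = edge_slots(net.n_rois, cohort.n_connections)
    elif slot_rule == "support":
        slots = [
            (i, j)
            for i in range(net.n_rois)
            for j in range(net.n_rois)
            if i != j and net.coeff_matrix[j, i] != 0
        ]
        if len(slots) != cohort.n_connections:
            raise InvalidSpecError(
                f"base network has {len(slots)} off-diagonal connections, "
                f"but n_connections={cohort.n_connections}"
            )
    else:
        raise InvalidSpecError(f"unknown slot_rule {slot_rule!r}")
    rng = np.random.default_rng(cohort.seed)
    n = cohort.n_subjects
    X = np.empty((n, cohort.n_connections))
    roi_series: dict[str, np.ndarray] = {}
    coeff_matrices: dict[str, np.ndarray] = {}
    subject_ids = tuple(f"sub-{k + 1:03d}" for k in range(n))
    for row, sid in enumerate(subject_ids):
        for attempt in range(50):
            W = net.coeff_matrix.copy()
            strengths = np.empty(cohort.n_connections)
            for k, (src, tgt) in enumerate(slots):
                base = W[tgt, src]
                val = base * (1.0 + rng.normal(0.0, cohort.strength_jitter_sd)) if base != 0 else 0.0
                val += rng.normal(0.0, cohort.strength_noise_sd)
                W[tgt, src] = val
                strengths[k] = val
            if np.max(np.abs(np.linalg.eigvals(W))) < 1.0:
                break
        else:
            raise NonStationarySpecError(
                "could not draw a stationary subject network in 50 attempts"
            )
        X[row] = strengths
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_net = NetworkSimSpec(
            n_rois=net.n_rois,
            coeff_matrix=W,
            innovation_sd=net.innovation_sd,
            n_timepoints=net.n_timepoints,
            tr=net.tr,
            seed=sub_seed,
        )
        roi_series[sid] = simulate_roi_timeseries(sub_net)
        coeff_matrices[sid] = W

    beta = np.zeros(cohort.n_connections)
    beta[list(cohort.true_support)] = cohort.beta_values
    Y = X @ beta
    if cohort.score_noise_sd > 0:
        Y = Y + rng.normal(0.0, cohort.score_noise_sd, size=n)
    if cohort.clip_range is not None:
        lo, hi = cohort.clip_range
        Y = np.clip(np.round(Y), lo, hi)
    truth = GroundTruth(
        coeff_matrices=coeff_matrices,
        true_support=cohort.true_support,
        beta=cohort.beta_values,
    )
    return CohortData(
        subject_ids=subject_ids,
        roi_series=roi_series,
        X=X,
        Y=Y,
        edge_slots=tuple(slots),
        truth=truth,
    )


def mvc_calibration(pressure_trace: Sequence[float] | np.ndarray) -> float:
    """Maximum voluntary contraction: the median of a 15 s pressure trace."""
    trace = np.asarray(pressure_trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty pressure trace")
    return float(np.median(trace))


def sparse_var_matrix(
    n_rois: int,
    density: float,
    coeff: float,
    seed: int,
    max_radius: float = 0.95,
    signed: bool = True,
) -> np.ndarray:
    """Random sparse off-diagonal VAR coefficient matrix with radius < 1.

    Draws round(density * R * (R-1)) off-diagonal entries of magnitude
    ``coeff`` (random sign when ``signed``); redraws until the spectral
    radius is below ``max_radius``.
    """
    rng = np.random.default_rng(seed)
    offdiag = [(i, j) for i in range(n_rois) for j in range(n_rois) if i != j]
    n_edges = int(round(density * len(offdiag)))
    for _ in range(200):
        W = np.zeros((n_rois, n_rois))
        picks = rng.choice(len(offdiag), size=n_edges, replace=False)
        for p in picks:
            i, j = offdiag[p]
            sign = rng.choice([-1.0, 1.0]) if signed else 1.0
            W[j, i] = sign * coeff
        if np.max(np.abs(np.linalg.eigvals(W))) < max_radius:
            return W
    raise NonStationarySpecError(
        f"could not draw a stationary matrix at density {density}, coeff {coeff}"
    )
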