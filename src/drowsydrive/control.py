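"""Car-following deceleration model, safety distance, and the speed-control state machine.

The coordinated-deceleration scenario: the instrumented (drowsy) driver's car
is the *front* car; a follower travels behind it at gap La.  When drowsiness
is confirmed the front car is commanded to shed dV = 20 km/h.  The follower
reacts after a perception/brake-coordination time t1, ramps its deceleration
linearly to the maximum a_m over t2, then holds a_m until it too has shed dV.
The front car decelerates at the constant rate a_f that spreads its speed
drop over exactly the follower's total deceleration time t_following, so both
cars reach their final speeds together.  The maneuver is safe when the
initial gap exceeds

    L = D_min + s_following - s_front ,

the distance by which the follower out-travels the front car plus a minimum
residual gap.  All internal kinematics are SI (m, s, m/s); public speeds are
km/h at the API boundary, matching how the scenario constants are quoted.

The per-second state machine turns a vigilance label stream into commands:
DECELERATE after n consecutive drowsy seconds (Situation 1, with a horn
event), RELEASE_LIMIT after m consecutive alert seconds while limited
(Situation 3), and a terminal BRAKE when at least k seconds have elapsed
since DECELERATE without the driver ever staying alert for m seconds and the
current sample is still drowsy (Situation 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "KMH",
    "DecelParams",
    "ControlConfig",
    "Command",
    "FollowingScenario",
    "KinematicTrace",
    "following_kinematics",
    "front_deceleration",
    "required_distance",
    "make_scenario",
    "estimate_following_speed",
    "simulate_pair",
    "SpeedController",
    "run_controller",
    "RangeSensor",
]

KMH = 1.0 / 3.6  # km/h -> m/s


@dataclass
class DecelParams:
    """Deceleration-model constants.

    t1 : driver reaction + brake coordination time of the follower (s)
    t2 : deceleration ramp-up time of the follower (s)
    am : maximum deceleration magnitude of the follower (m/s^2, positive)
    Dmin : minimum residual safety gap after the maneuver (m)
    dV : commanded speed drop (km/h)
    """

    t1: float = 1.2
    t2: float = 0.2
    am: float = 4.5
    Dmin: float = 5.0
    dV: float = 20.0

    def __post_init__(self):
        for name in ("t1", "t2", "am", "Dmin", "dV"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ControlConfig:
    """State-machine thresholds (all in whole seconds).

    n : consecutive drowsy seconds that confirm drowsiness (Situation 1)
    k : wake-up window after DECELERATE before braking becomes possible
    m : minimum continuous alert time that counts as woken up
    """

    n: int = 3
    k: int = 10
    m: int = 10

    def __post_init__(self):
        if min(self.n, self.k, self.m) <= 0:
            raise ValueError("n, k, m must be positive")


@dataclass
class Command:
    name: str  # DECELERATE | BRAKE | RELEASE_LIMIT
    t: int     # second at which the command is emitted


@dataclass
class Kinematics:
    """Closed-form follower deceleration profile summary (SI units)."""

    t3: float
    t_following: float
    s1: float
    s2: float
    s3: float
    s_following: float


@dataclass
class FollowingScenario:
    """Two-car scenario: initial speeds (km/h), actual gap (m), derived quantities."""

    v11: float
    v21: float
    La: float
    params: DecelParams = field(default_factory=DecelParams)
    # derived, filled by make_scenario
    v12: float = 0.0
    v22: float = 0.0
    t_following: float = 0.0
    s_following: float = 0.0
    af: float = 0.0
    s_front: float = 0.0
    L: float = 0.0

    @property
    def safe(self) -> bool:
        return self.La > self.L


@dataclass
class KinematicTrace:
    """Fixed-step two-car simulation output (SI units, speeds also in km/h helpers)."""

    t: np.ndarray
    a_front: np.ndarray
    v_front: np.ndarray
    x_front: np.ndarray
    a_follow: np.ndarray
    v_follow: np.ndarray
    x_follow: np.ndarray
    gap: np.ndarray

    @property
    def terminal_speeds_kmh(self) -> tuple[float, float]:
        return (self.v_front[-1] / KMH, self.v_follow[-1] / KMH)

    @property
    def terminal_gap(self) -> float:
        return float(self.gap[-1])

    @property
    def min_gap(self) -> float:
        return float(self.gap.min())


def following_kinematics(params: DecelParams, v21_kmh: float, v22_kmh: float) -> Kinematics:
    """Three-stage follower deceleration from v21 to v22 (speeds in km/h).

    Stage distances: s1 = t1 v21 (reaction), s2 over the linear ramp, s3 at
    constant a_m; the total uses the standard simplification that drops the
    O(am t2^2) ramp correction:

        t3 = (v21 - v22)/am - t2/2
        s_following = v21 (t1 + t2/2) + (v21^2 - v22^2) / (2 am)
    """
    if v22_kmh < 0 or v21_kmh <= v22_kmh:
        raise ValueError(f"need v21 > v22 >= 0, got v21={v21_kmh}, v22={v22_kmh} km/h")
    v21, v22 = v21_kmh * KMH, v22_kmh * KMH
    t1, t2, am = params.t1, params.t2, params.am
    t3 = (v21 - v22) / am - t2 / 2.0
    if t3 <= 0:
        raise ValueError("speed drop too small for the ramp time: t3 <= 0")
    s1 = t1 * v21
    s2 = v21 * t2 - am * t2**2 / 6.0
    v_ramp_end = v21 - am * t2 / 2.0
    s3 = (v_ramp_end**2 - v22**2) / (2.0 * am)
    s_following = v21 * (t1 + t2 / 2.0) + (v21**2 - v22**2) / (2.0 * am)
    return Kinematics(t3, t1 + t2 + t3, s1, s2, s3, s_following)


def front_deceleration(params: DecelParams, v11_kmh: float, v12_kmh: float,
                       t_following: float) -> tuple[float, float]:
    """Constant front-car deceleration spreading v11 -> v12 over t_following.

    Returns ``(af, s_front)`` in SI: af = (v12 - v11)/t_following (signed,
    negative when decelerating) and the distance s_front covered while the
    speed changes; a degenerate v12 == v11 gives af = 0 and constant-speed
    travel.
    """
    if t_following <= 0:
        raise ValueError("t_following must be positive")
    v11, v12 = v11_kmh * KMH, v12_kmh * KMH
    af = (v12 - v11) / t_following
    if af == 0.0:
        return 0.0, v11 * t_following
    s_front = (v12**2 - v11**2) / (2.0 * af)
    return af, s_front


def make_scenario(v11_kmh: float, v21_kmh: float, La: float,
                  params: DecelParams | None = None) -> FollowingScenario:
    """Build a scenario with all derived quantities filled in.

    Both cars target the same final speed v21 - dV (the commanded drop is
    defined against the follower's initial speed).
    """
    params = params or DecelParams()
    v22 = v21_kmh - params.dV
    v12 = v22
    kin = following_kinematics(params, v21_kmh, v22)
    af, s_front = front_deceleration(params, v11_kmh, v12, kin.t_following)
    L = params.Dmin + kin.s_following - s_front
    return FollowingScenario(
        v11=v11_kmh, v21=v21_kmh, La=La, params=params,
        v12=v12, v22=v22, t_following=kin.t_following,
        s_following=kin.s_following, af=af, s_front=s_front, L=L,
    )


def required_distance(params: DecelParams, v11_kmh: float, v21_kmh: float) -> float:
    """Safety distance L = Dmin + s_following - s_front (m); safe iff La > L."""
    return make_scenario(v11_kmh, v21_kmh, La=np.inf, params=params).L


def estimate_following_speed(v11: float, L1: float, L2: float, dt: float = 0.5) -> float:
    """Follower speed from two ranged gaps dt apart (SI: m/s and m).

    The gap to the follower closes at the relative speed v21 - v11, so
    v21 = v11 + (L1 - L2)/dt; at the default 0.5 s ranging interval the
    factor 1/dt is 2.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    return v11 + (L1 - L2) / dt


def simulate_pair(scenario: FollowingScenario, params: DecelParams | None = None,
                  dt: float = 0.01, settle: float = 1.0) -> KinematicTrace:
    """Fixed-step two-car point-mass simulation of the deceleration maneuver.

    Front car: constant af from v11 down to v12, then constant speed.
    Follower: v21 for t1, deceleration ramping linearly to am over t2, then
    constant am down to v22, then constant speed.  Piecewise-constant/linear
    accelerations make the trapezoidal update exact to O(dt).
    """
    params = params or scenario.params
    if dt > 0.01:
        raise ValueError("dt must be <= 0.01 s")
    v11, v12 = scenario.v11 * KMH, scenario.v12 * KMH
    v21, v22 = scenario.v21 * KMH, scenario.v22 * KMH
    T = scenario.t_following + settle
    t = np.arange(0.0, T + dt / 2, dt)
    n = t.size
    af_arr = np.zeros(n)
    vf = np.full(n, v11)
    afo = np.zeros(n)
    vfo = np.full(n, v21)
    t1, t2, am = params.t1, params.t2, params.am

    def follower_accel(ti):
        if ti <= t1:
            return 0.0
        if ti <= t1 + t2:
            return -am * (ti - t1) / t2
        return -am

    for i in range(1, n):
        ti = t[i]
        # front car: constant af until v12, then cruise
        a = scenario.af if vf[i - 1] > v12 + 1e-12 else 0.0
        af_arr[i] = a
        vf[i] = max(vf[i - 1] + a * dt, v12)
        # follower: trapezoid on the piecewise-linear acceleration profile
        a2 = follower_accel(ti)
        afo[i] = a2
        if vfo[i - 1] <= v22 + 1e-12:
            afo[i] = 0.0
            vfo[i] = vfo[i - 1]
        else:
            vfo[i] = max(vfo[i - 1] + (follower_accel(t[i - 1]) + a2) / 2.0 * dt, v22)
    if (vf < -1e-9).any() or (vfo < -1e-9).any():
        raise ValueError("invalid scenario: negative speed encountered")
    xf = np.concatenate([[0.0], np.cumsum((vf[1:] + vf[:-1]) / 2.0 * dt)])
    xfo = np.concatenate([[0.0], np.cumsum((vfo[1:] + vfo[:-1]) / 2.0 * dt)])
    gap = scenario.La + xf - xfo
    return KinematicTrace(t, af_arr, vf, xf, afo, vfo, xfo, gap)


class RangeSensor:
    """Simulated range sensor standing in for the binocular camera.

    Reports the current gap La (m) and the follower speed v21 (km/h),
    optionally with additive Gaussian noise on the range.
    """

    def __init__(self, La: float, v21_kmh: float, noise_std: float = 0.0,
                 seed: int | None = None):
        self.La = La
        self.v21_kmh = v21_kmh
        self.noise_std = noise_std
        self._rng = np.random.default_rng(seed)

    def __call__(self) -> tuple[float, float]:
        La = self.La
        if self.noise_std > 0:
            La += self._rng.normal(0.0, self.noise_std)
        return La, self.v21_kmh


class SpeedController:
    """Per-second vigilance -> command state machine (Situations 1-3).

    Call :meth:`step` once per second with that second's vigilance label.
    Commands returned are those emitted at that second.  BRAKE is absorbing:
    further steps warn and do nothing.

    Parameters
    ----------
    config : ControlConfig
        Thresholds n (drowsy trigger), k (wake-up window), m (minimum alert).
    params : DecelParams, optional
        Used to evaluate the safety distance when a range sensor is attached.
    own_speed_kmh : float
        The instrumented (front) car's speed v11, needed for L.
    range_sensor : callable -> (La, v21_kmh), optional
        Queried at DECELERATE; if the reported gap La <= L the speed change
        is withheld, an ``unsafe_gap`` event is logged, and the check is
        retried every following second until it passes.
    """

    def __init__(self, config: ControlConfig | None = None,
                 params: DecelParams | None = None,
                 own_speed_kmh: float = 95.0,
                 range_sensor: Callable[[], tuple[float, float]] | None = None):
        self.config = config or ControlConfig()
        self.params = params or DecelParams()
        self.own_speed_kmh = own_speed_kmh
        self.range_sensor = range_sensor
        self.t = 0
        self.drowsy_run = 0
        self.alert_run = 0
        self.drowsy_flag = False
        self.braked = False
        self.decel_t: int | None = None
        self.alert_reached_m = False
        self.pending_gap_check = False
        self.commands: list[Command] = []
        self.events: list[tuple[str, int]] = []

    def _gap_is_safe(self) -> bool:
        if self.range_sensor is None:
            return True
        La, v21 = self.range_sensor()
        L = required_distance(self.params, self.own_speed_kmh, v21)
        if La > L:
            return True
        self.events.append(("unsafe_gap", self.t))
        return False

    def step(self, sample: str) -> list[Command]:
        """Advance one second; returns the commands emitted at this second."""
        if self.braked:
            warnings.warn("controller already braked; ignoring further samples")
            return []
        if sample not in ("alert", "drowsy"):
            raise ValueError(f"sample must be 'alert' or 'drowsy', got {sample!r}")
        self.t += 1
        drowsy = sample == "drowsy"
        self.drowsy_run = self.drowsy_run + 1 if drowsy else 0
        self.alert_run = 0 if drowsy else self.alert_run + 1
        emitted: list[Command] = []

        if self.pending_gap_check and self.drowsy_flag and self._gap_is_safe():
            self.pending_gap_check = False
            self.events.append(("speed_change_applied", self.t))

        # Situation 1: confirmed drowsiness -> decelerate, horn, speed limit
        if not self.drowsy_flag and self.drowsy_run >= self.config.n:
            cmd = Command("DECELERATE", self.t)
            emitted.append(cmd)
            self.commands.append(cmd)
            self.events.append(("horn", self.t))
            self.drowsy_flag = True
            self.decel_t = self.t
            self.alert_reached_m = False
            self.pending_gap_check = not self._gap_is_safe()
            if not self.pending_gap_check:
                self.events.append(("speed_change_applied", self.t))

        elif self.drowsy_flag:
            if self.alert_run >= self.config.m:
                # Situation 3: driver woke up and stayed alert for m seconds
                self.alert_reached_m = True
                cmd = Command("RELEASE_LIMIT", self.t)
                emitted.append(cmd)
                self.commands.append(cmd)
                self.drowsy_flag = False
                self.decel_t = None
                self.pending_gap_check = False
            elif (drowsy and not self.alert_reached_m
                  and self.decel_t is not None
                  and self.t - self.decel_t >= self.config.k):
                # Situation 2: horn failed to wake the driver within k seconds
                cmd = Command("BRAKE", self.t)
                emitted.append(cmd)
                self.commands.append(cmd)
                self.braked = True
        return emitted


def run_controller(labels, config: ControlConfig | None = None,
                   params: DecelParams | None = None,
                   own_speed_kmh: float = 95.0,
                   range_sensor=None) -> tuple[list[Command], SpeedController]:
    """Replay a per-second label sequence through a fresh controller."""
    ctrl = SpeedController(config, params, own_speed_kmh, range_sensor)
    for sample in labels:
        ctrl.step(sample)
        if ctrl.braked:
            break
    return ctrl.commands, ctrl
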