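"""Synthetic tennis-session generator.

Emulates the data a wearable study produces: a 10 Hz, 12-channel IMU
stream per player (acceleration, gravity, orientation, rotation rate —
three axes each), a latent binary "in the zone" state trace, and sparse
coach label events.  The generator gives every downstream stage of the
pipeline (cleaning, windowing, splitting, training) a fully testable
input with known ground truth.

Structure of a session
----------------------
* The latent zone state is a two-state semi-Markov process: alternating
  in-zone / out-of-zone dwells with gamma-distributed durations
  (minute-scale means, shape 2 by default).  Sessions start out of the
  zone by convention.
* The IMU base signal is stroke bursts (short damped oscillations on the
  acceleration and rotation-rate channels, Poisson-timed) riding on a
  rally/rest intensity oscillation, a slowly wandering gravity vector,
  bounded Euler-like orientation drift, and white sensor noise.
* While the player is in the zone the channels are additively modulated
  by a *personal* pattern (direction drawn per player from the player's
  signature matrix — independent across players) plus a *weak shared*
  pattern common to the whole cohort, scaled by ``shared_signature_gain``.
  The personal component carries per-channel mean offsets (strongly
  separable within a player, uninformative across players); the shared
  component is a small zero-mean oscillation (transfers weakly).
* Coaches observe transitions with a reaction latency and may miss some;
  a *verbose* coach additionally re-emits the current state periodically,
  a *sparse* coach labels transitions only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

SAMPLE_RATE_HZ = 10.0
N_CHANNELS = 12
CHANNEL_NAMES = (
    "ax", "ay", "az",          # acceleration
    "gx", "gy", "gz",          # gravity vector
    "ox", "oy", "oz",          # orientation (Euler-like, bounded)
    "rx", "ry", "rz",          # rotation rate
)
# per-channel sensor noise scale (white noise standard deviation at
# noise_scale = 1), in sensor-native units
CHANNEL_NOISE_SD = np.array(
    [0.40, 0.40, 0.40, 0.02, 0.02, 0.02, 0.05, 0.05, 0.05, 0.30, 0.30, 0.30]
)

# calibrated in-zone modulation amplitudes (units of the per-channel noise
# sd); chosen so that a discriminant oracle on window summary statistics
# exceeds 90% within-player accuracy while cross-player transfer stays
# near chance (see docs/methods.md)
PERSONAL_OFFSET_AMP = 1.4
PERSONAL_OSC_AMP = 0.15
SHARED_AMP = 0.6
SHARED_OSC_HZ = 0.8
# the shared pattern lives on a fixed subset of channels (vertical
# acceleration and two rotation-rate axes)
_SHARED_DIRECTION = np.zeros(N_CHANNELS)
_SHARED_DIRECTION[[2, 9, 10]] = [0.5, 0.62, 0.60]
_SHARED_DIRECTION /= np.linalg.norm(_SHARED_DIRECTION)

ZONE_RAMP_S = 2.0  # smoothing of the modulation at zone transitions

# channels that respond to movement (acceleration + rotation rate); the
# personal zone offset lives in this subspace — coaches read the zone off
# movement and behaviour, and gravity/orientation baselines drift too much
# to carry a mean offset
DYNAMIC_CHANNELS = np.array([0, 1, 2, 9, 10, 11])


class ParameterError(ValueError):
    """Raised when a generator parameter is out of its valid range."""


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------
@dataclass
class PlayerProfile:
    """Generative parameters of one player.

    ``personal_signature`` is a 12x12 matrix of mixing weights drawn
    independently per player; the in-zone personal modulation direction
    and oscillation are derived from it, so two players agree only by
    chance.  ``shared_signature_gain`` scales the cohort-wide zone
    pattern and is identical across players of one cohort.
    """

    player_id: str
    stroke_rate: float = 30.0          # stroke events per minute at peak rally
    rally_rest_period: float = 40.0    # s, full rally+rest cycle
    personal_signature: np.ndarray = None  # (12, 12) mixing weights
    shared_signature_gain: float = 0.25
    zone_dwell_in_mean: float = 8.0    # min
    zone_dwell_out_mean: float = 10.0  # min
    dwell_shape: float = 2.0           # gamma shape of dwell durations
    noise_scale: float = 1.0
    # explicit in-zone offset direction (12,); set by cohort assembly
    # (orthogonalized across players), otherwise derived from the signature
    zone_offset_direction: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.personal_signature is None:
            raise ParameterError("personal_signature is required (use random_profile)")
        self.personal_signature = np.asarray(self.personal_signature, dtype=float)
        if self.personal_signature.shape != (N_CHANNELS, N_CHANNELS):
            raise ParameterError("personal_signature must be 12x12")
        if min(self.stroke_rate, self.dwell_shape, self.noise_scale) < 0:
            raise ParameterError("rates, shape and noise_scale must be >= 0")
        if not (0.0 <= self.shared_signature_gain <= 1.0):
            raise ParameterError("shared_signature_gain must be in [0, 1]")

    # derived, deterministic functions of the signature --------------------
    def personal_offset_direction(self) -> np.ndarray:
        if self.zone_offset_direction is not None:
            return np.asarray(self.zone_offset_direction, dtype=float)
        return project_to_dynamic(self.personal_signature[:, 0])

    def personal_osc_direction(self) -> np.ndarray:
        # dividing a standard-normal column by sqrt(12) gives expected unit
        # norm while preserving deliberate scaling (zero-signal ablations)
        return self.personal_signature[:, 1] / np.sqrt(N_CHANNELS)

    def personal_osc_freq(self) -> float:
        # slow, player-specific oscillation in 0.04..0.08 Hz
        u = 0.5 * (1.0 + np.tanh(self.personal_signature[0, 2]))
        return 0.04 + 0.04 * float(u)

    def personal_osc_phase(self) -> float:
        return float(np.pi * np.tanh(self.personal_signature[1, 2]))


def project_to_dynamic(v: np.ndarray) -> np.ndarray:
    """Restrict a 12-channel direction to the dynamic subspace, unit norm.

    A direction with (near-)zero dynamic mass stays a zero vector, which
    encodes a zero-signal player.
    """
    d = np.zeros(N_CHANNELS)
    d[DYNAMIC_CHANNELS] = np.asarray(v, dtype=float)[DYNAMIC_CHANNELS]
    n = np.linalg.norm(d)
    return d / n if n > 1e-9 else d


def orthogonalize_zone_directions(profiles: list["PlayerProfile"]) -> None:
    """Make the cohort's personal zone-offset directions mutually orthogonal.

    Player behaviour signatures are independent; within a small cohort we
    realise that independence exactly by Gram-Schmidt orthogonalisation of
    the offset directions inside the dynamic-channel subspace, so that one
    player's in-zone mean shift carries no linear information about
    another's.  Directions are written to ``zone_offset_direction`` in
    place; zero (no-signal) directions are left untouched.
    """
    if len(profiles) > len(DYNAMIC_CHANNELS):
        raise ParameterError("cannot orthogonalize more players than dynamic channels")
    basis: list[np.ndarray] = []
    for p in profiles:
        d = project_to_dynamic(p.personal_signature[:, 0])
        for b in basis:
            d = d - (d @ b) * b
        n = np.linalg.norm(d)
        if n > 1e-9:
            d = d / n
            basis.append(d)
        else:
            d = np.zeros(N_CHANNELS)
        p.zone_offset_direction = d


def random_profile(
    player_id: str,
    seed: int,
    *,
    zone_dwell_in_mean: float = 8.0,
    zone_dwell_out_mean: float = 10.0,
    shared_signature_gain: float = 0.25,
    noise_scale: float = 1.0,
    signal_scale: float = 1.0,
    time_scale: float = 1.0,
) -> PlayerProfile:
    """Draw a player profile with an independent random signature.

    ``signal_scale`` multiplies the whole in-zone modulation (0 gives a
    zero-signal player for ablations); it is stored by scaling the
    signature columns used for the modulation.  ``time_scale`` compresses
    the rally/rest cycle for scaled-down sessions, preserving the ratio
    between zone-dwell and rally time scales.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51F0]))
    sig = rng.standard_normal((N_CHANNELS, N_CHANNELS))
    sig[:, 0] *= signal_scale
    sig[:, 1] *= signal_scale
    return PlayerProfile(
        player_id=player_id,
        stroke_rate=float(rng.uniform(25.0, 35.0)),
        rally_rest_period=float(rng.uniform(35.0, 45.0)) * time_scale,
        personal_signature=sig,
        shared_signature_gain=shared_signature_gain,
        zone_dwell_in_mean=zone_dwell_in_mean,
        zone_dwell_out_mean=zone_dwell_out_mean,
        noise_scale=noise_scale,
    )


@dataclass
class ZoneTrace:
    """Latent alternating zone-state trace of one session.

    ``transition_times[0]`` is 0.0 with the initial state (out of zone by
    convention); subsequent entries are the state-change times.  States
    alternate and the last transition lies strictly before the session
    end.
    """

    transition_times: np.ndarray  # s, strictly increasing, starts at 0
    states: np.ndarray            # int8, alternating, states[k] entered at time k
    session_duration: float       # s

    def __post_init__(self):
        self.transition_times = np.asarray(self.transition_times, dtype=float)
        self.states = np.asarray(self.states, dtype=np.int8)
        if len(self.transition_times) != len(self.states):
            raise ParameterError("times/states length mismatch")
        if len(self.transition_times) == 0 or self.transition_times[0] < 0:
            raise ParameterError("trace must start at a time >= 0")
        d = np.diff(self.transition_times)
        if np.any(d <= 0):
            raise ParameterError("transition times must be strictly increasing")
        if np.any(self.states[1:] == self.states[:-1]):
            raise ParameterError("states must alternate")
        if self.transition_times[-1] >= self.session_duration:
            raise ParameterError("last transition must precede session end")

    @property
    def n_transitions(self) -> int:
        """Number of state changes (the initial state does not count)."""
        return len(self.transition_times) - 1

    def in_fraction(self) -> float:
        """Time-weighted fraction of the session spent in the zone."""
        edges = np.append(self.transition_times, self.session_duration)
        dur = np.diff(edges)
        return float(dur[self.states == 1].sum() / self.session_duration)

    def state_at(self, times) -> np.ndarray:
        """Latent state at each query time (scalar or array)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.transition_times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.states) - 1)
        out = self.states[idx]
        return out if np.ndim(times) else out[0]


@dataclass
class CoachModel:
    """Observer model that converts a latent trace into label events."""

    coach_id: str = "C"
    style: str = "sparse"              # "verbose" or "sparse"
    detection_latency_mean: float = 5.0  # s
    detection_latency_sd: float = 2.0    # s
    miss_prob: float = 0.0
    verbose_reemit_period: float = 2.5   # min (verbose style only)

    def __post_init__(self):
        if self.style not in ("verbose", "sparse"):
            raise ParameterError("style must be 'verbose' or 'sparse'")
        if not (0.0 <= self.miss_prob < 1.0):
            raise ParameterError("miss_prob must be in [0, 1)")
        if self.detection_latency_sd < 0:
            raise ParameterError("latency sd must be >= 0")


@dataclass
class ImuSeries:
    """Timestamped 12-channel sensor matrix for one player-session."""

    player_id: str
    timestamps: np.ndarray  # s, nominal 0.1 s grid
    channels: np.ndarray    # (n, 12)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[1] != N_CHANNELS:
            raise ParameterError("channels must be an (n, 12) matrix")
        if len(self.timestamps) != len(self.channels):
            raise ParameterError("timestamps/channels length mismatch")
        if np.any(np.diff(self.timestamps) < 0):
            raise ParameterError("timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class LabelEvent:
    """One coach observation: timestamp, binary zone state, optional note."""

    timestamp: float
    state: int
    note: Optional[str] = None

    def __post_init__(self):
        if int(self.state) not in (0, 1):
            raise ParameterError("state must be 0 or 1")
        self.state = int(self.state)
        self.timestamp = float(self.timestamp)


@dataclass
class CorruptionRecord:
    """Ground truth of an injected corruption, for tests."""

    duplicated_indices: np.ndarray  # indices (into the clean input) that were doubled
    dropped_indices: np.ndarray     # indices (into the clean input) that were removed


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------
def sample_zone_trace(profile: PlayerProfile, duration: float, seed: int) -> ZoneTrace:
    """Draw the latent two-state semi-Markov zone trace of one session.

    Dwell durations are gamma distributed with the profile's per-state
    means (minutes) and common shape.  Deterministic for a given seed.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    if profile.zone_dwell_in_mean <= 0 or profile.zone_dwell_out_mean <= 0:
        raise ParameterError("dwell means must be positive")
    if profile.dwell_shape <= 0:
        raise ParameterError("dwell_shape must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x2042]))
    k = profile.dwell_shape
    means_s = {0: profile.zone_dwell_out_mean * 60.0, 1: profile.zone_dwell_in_mean * 60.0}
    times = [0.0]
    states = [0]  # sessions start out of the zone by convention
    t = 0.0
    state = 0
    while True:
        t += rng.gamma(k, means_s[state] / k)
        if t >= duration:
            break
        state = 1 - state
        times.append(t)
        states.append(state)
    return ZoneTrace(np.array(times), np.array(states, np.int8), float(duration))


def _ou_process(rng, n, dt, tau, sd):
    """Ornstein-Uhlenbeck path: stationary sd ``sd``, time constant ``tau``."""
    from scipy.signal import lfilter

    a = 1.0 - dt / tau
    noise = rng.standard_normal(n) * (sd * np.sqrt(2.0 * dt / tau))
    noise[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -a], noise)


def _zone_indicator(t: np.ndarray, trace: ZoneTrace) -> np.ndarray:
    """Smoothed 0/1 zone indicator with a raised-cosine transition ramp."""
    z = trace.state_at(t).astype(float)
    if ZONE_RAMP_S <= 0:
        return z
    # smooth each transition with a half-cosine ramp
    for tt, s in zip(trace.transition_times[1:], trace.states[1:]):
        in_ramp = (t >= tt) & (t < tt + ZONE_RAMP_S)
        frac = (t[in_ramp] - tt) / ZONE_RAMP_S
        ramp = 0.5 * (1.0 - np.cos(np.pi * frac))
        z[in_ramp] = (1.0 - ramp) * (1 - s) + ramp * s
    return z


def synthesize_imu(profile: PlayerProfile, trace: ZoneTrace, seed: int) -> ImuSeries:
    """Render the 10 Hz, 12-channel IMU stream for one session.

    The returned series is clean (complete 0.1 s grid); use
    :func:`corrupt_timestamps` to inject duplicates and gaps.
    """
    duration = trace.session_duration
    n = int(round(duration * SAMPLE_RATE_HZ))
    if n < 2:
        raise ParameterError("session too short to synthesize")
    dt = 1.0 / SAMPLE_RATE_HZ
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1111]))
    t = np.arange(n) * dt
    X = np.zeros((n, N_CHANNELS))

    # rally/rest intensity envelope in [0.1, 1]
    env = 0.55 - 0.45 * np.cos(2.0 * np.pi * t / profile.rally_rest_period)

    # stroke bursts: Poisson-timed damped oscillations on acceleration and
    # rotation-rate channels, thinned by the rally envelope
    peak_rate = profile.stroke_rate / 60.0
    n_cand = rng.poisson(peak_rate * duration * 1.2)
    cand_times = np.sort(rng.uniform(0.0, duration, n_cand))
    cand_env = 0.55 - 0.45 * np.cos(2.0 * np.pi * cand_times / profile.rally_rest_period)
    keep = rng.random(n_cand) < cand_env / 1.2
    stroke_times = cand_times[keep]
    burst_len = int(round(0.5 * SAMPLE_RATE_HZ))
    tau_burst = 0.15
    burst_t = np.arange(burst_len) * dt
    burst_shape = np.exp(-burst_t / tau_burst) * np.sin(2.0 * np.pi * 4.0 * burst_t)
    for st in stroke_times:
        i0 = int(st * SAMPLE_RATE_HZ)
        i1 = min(i0 + burst_len, n)
        if i1 <= i0:
            continue
        amp_a = rng.uniform(2.0, 4.0)
        dir_a = rng.standard_normal(3)
        dir_a /= np.linalg.norm(dir_a)
        amp_r = rng.uniform(1.5, 3.0)
        dir_r = rng.standard_normal(3)
        dir_r /= np.linalg.norm(dir_r)
        seg = burst_shape[: i1 - i0]
        X[i0:i1, 0:3] += amp_a * seg[:, None] * dir_a
        X[i0:i1, 9:12] += amp_r * seg[:, None] * dir_r

    # gravity: unit-norm vector wandering around (0, 0, -1); same
    # correlation-time constraint as the orientation channels
    tilt_x = 0.15 * np.sin(2.0 * np.pi * t / profile.rally_rest_period)
    tilt_y = _ou_process(rng, n, dt, 2.0, 0.12)
    gz = -np.sqrt(np.maximum(1.0 - tilt_x**2 - tilt_y**2, 0.05))
    X[:, 3] += tilt_x
    X[:, 4] += tilt_y
    X[:, 5] += gz

    # orientation: bounded Euler-like wander.  Correlation times are kept
    # below the minimum test-segment length (5 s): slower drift would let a
    # classifier interpolate labels through held-out segments via the
    # drift state alone, an artefact no contiguous-block split can remove.
    for j, tau in zip((6, 7, 8), (2.0, 1.5, 2.5)):
        X[:, j] += np.pi * np.tanh(_ou_process(rng, n, dt, tau, 0.6))

    # white sensor noise
    X += rng.standard_normal((n, N_CHANNELS)) * (CHANNEL_NOISE_SD * profile.noise_scale)

    # in-zone modulation: personal offset + slow personal oscillation +
    # weak shared zero-mean oscillation
    z = _zone_indicator(t, trace)
    sd = CHANNEL_NOISE_SD * profile.noise_scale
    v_off = profile.personal_offset_direction()
    v_osc = profile.personal_osc_direction()
    f_p = profile.personal_osc_freq()
    phase = profile.personal_osc_phase()
    personal = (
        PERSONAL_OFFSET_AMP * np.outer(np.ones(n), sd * v_off)
        + PERSONAL_OSC_AMP
        * np.outer(np.sin(2.0 * np.pi * f_p * t + phase), sd * v_osc)
    )
    shared = (
        profile.shared_signature_gain
        * SHARED_AMP
        * np.outer(np.sin(2.0 * np.pi * SHARED_OSC_HZ * t), sd * _SHARED_DIRECTION)
    )
    X += z[:, None] * (personal + shared)

    return ImuSeries(player_id=profile.player_id, timestamps=t, channels=X)


_VERBOSE_NOTES = (
    "doing his rituals",
    "gaze sharpened, controlling breath",
    "footwork loose, shaking head",
    "locked in between points",
    "rushing, bouncing ball impatiently",
)


def emit_coach_labels(trace: ZoneTrace, coach: CoachModel, seed: int) -> list[LabelEvent]:
    """Convert a latent trace into the coach's sparse label events.

    Every detected transition produces one event after a Gaussian reaction
    latency (clipped at zero); each transition is missed independently
    with ``miss_prob``.  A verbose coach additionally re-emits the current
    state every ``verbose_reemit_period`` minutes.  Events are sorted by
    time and their state always equals the latent state at the labeled
    moment.  An initial event at t=0 records the starting state.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0AC]))
    events: list[LabelEvent] = [LabelEvent(0.0, int(trace.states[0]))]
    for tt in trace.transition_times[1:]:
        if rng.random() < coach.miss_prob:
            continue
        latency = max(0.0, rng.normal(coach.detection_latency_mean, coach.detection_latency_sd))
        te = tt + latency
        if te >= trace.session_duration:
            continue
        note = None
        if coach.style == "verbose":
            note = _VERBOSE_NOTES[rng.integers(len(_VERBOSE_NOTES))]
        events.append(LabelEvent(float(te), int(trace.state_at(te)), note))
    if coach.style == "verbose" and coach.verbose_reemit_period > 0:
        period = coach.verbose_reemit_period * 60.0
        te = period
        while te < trace.session_duration:
            events.append(LabelEvent(float(te), int(trace.state_at(te))))
            te += period
    events.sort(key=lambda e: e.timestamp)
    return events


def corrupt_timestamps(
    series: ImuSeries, dup_rate: float, gap_rate: float, seed: int
) -> tuple[ImuSeries, CorruptionRecord]:
    """Inject duplicated timestamps and dropped samples into a clean series.

    Each input sample is independently duplicated with ``dup_rate`` and
    dropped with ``gap_rate`` (the first and last samples are never
    dropped, so the observed span is preserved).  Returns the corrupted
    series together with the ground-truth corruption record.
    """
    for name, r in (("dup_rate", dup_rate), ("gap_rate", gap_rate)):
        if not (0.0 <= r <= 0.2):
            raise ParameterError(f"{name} must be in [0, 0.2]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0DE]))
    n = len(series)
    dup_mask = rng.random(n) < dup_rate
    drop_mask = rng.random(n) < gap_rate
    drop_mask[0] = drop_mask[-1] = False
    drop_mask &= ~dup_mask  # a sample is either doubled or dropped, not both
    out_t: list[np.ndarray] = []
    out_x: list[np.ndarray] = []
    keep = ~drop_mask
    idx = np.arange(n)[keep]
    reps = np.where(dup_mask[keep], 2, 1)
    rows = np.repeat(idx, reps)
    out_t = series.timestamps[rows]
    out_x = series.channels[rows]
    corrupted = ImuSeries(series.player_id, out_t, out_x)
    record = CorruptionRecord(
        duplicated_indices=np.flatnonzero(dup_mask),
        dropped_indices=np.flatnonzero(drop_mask),
    )
    return corrupted, record
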