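"""Ground-truthed synthetic sensor and behavior logs.

Real hen data of this kind are not publicly deposited, so every downstream
stage is exercised against a generator that reproduces the statistical
structure the analysis assumes: a smooth bounded trajectory with
velocity autocorrelation (the CTCRW / integrated-OU process, reflected at
the walls), 8-s sensor polling with dropouts and Gaussian position noise,
and a semi-Markov behavior process with exponential dwell times whose
resource-directed states (e.g. feeding) fire only near the matching room
feature.  Behavior is emitted as 1-s instantaneous samples inside the
observation windows; bout segmentation is downstream's job.

Defaults are placeholders chosen to be realistic for a laying hen, not
estimates from data: beta = 0.2 /s (velocity decorrelation over ~5 s),
sigma = 0.05 m s^-3/2 (stationary RMS speed ~0.08 m/s per axis -- a slow
amble, since standing/resting dominates a hen's day), tau = 0.25 m sensor
noise, 20% dropout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ctcrw import CTCRWParams, transition
from .io import ETHOGRAM, BehaviorAnnotation, SensorFix
from .room import RoomGeometry
from .schedule import ObservationSchedule


@dataclass(frozen=True)
class BehaviorState:
    """One semi-Markov behavior state.

    mean_dwell : mean of the exponential dwell time, seconds (> 0)
    weight     : relative transition weight into this state
    near       : optional (feature kind, radius m) spatial gate — the state
                 can only be occupied while the animal is within ``radius``
                 of a feature of that kind
    """

    mean_dwell: float
    weight: float = 1.0
    near: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if self.mean_dwell <= 0:
            raise ValueError("mean_dwell must be > 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


def default_behavior_model() -> dict[str, BehaviorState]:
    """A hen-like behavior repertoire over the ethogram's behavior labels."""
    return {
        "feed": BehaviorState(60.0, 1.5, near=("feeder", 0.3)),
        "drink": BehaviorState(20.0, 0.8, near=("water_line", 0.3)),
        "preen": BehaviorState(90.0, 1.0),
        "dust_bathe": BehaviorState(120.0, 0.2),
        "forage": BehaviorState(80.0, 1.5),
        "rest": BehaviorState(180.0, 1.0),
    }


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to simulate one animal's study data."""

    ctcrw_params: CTCRWParams = field(
        default_factory=lambda: CTCRWParams(beta=0.2, sigma=0.05, tau=0.25)
    )
    duration: float = 2 * 86_400.0  # seconds (48-h recording)
    fine_step: float = 1.0
    poll_interval: float = 8.0
    dropout_prob: float = 0.2
    behavior_model: Mapping[str, BehaviorState] = field(
        default_factory=default_behavior_model
    )
    schedule: ObservationSchedule = field(default_factory=ObservationSchedule)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.fine_step <= 0:
            raise ValueError("fine_step must be > 0")
        if self.fine_step > self.poll_interval:
            raise ValueError("fine_step must not exceed the poll interval")
        for name in self.behavior_model:
            if name not in ETHOGRAM["behavior"]:
                raise ValueError(f"unknown behavior state {name!r}")


@dataclass
class TrueTrack:
    """Dense ground-truth trajectory: positions and velocities on a fine grid."""

    t: np.ndarray  # (n,)
    xy: np.ndarray  # (n, 2) meters, always inside the room
    v: np.ndarray  # (n, 2) m/s
    seed: int

    def position_at(self, times: np.ndarray) -> np.ndarray:
        """Linear interpolation of the dense track at arbitrary times."""
        times = np.asarray(times, float)
        x = np.interp(times, self.t, self.xy[:, 0])
        y = np.interp(times, self.t, self.xy[:, 1])
        return np.column_stack([x, y])


def simulate_track(spec: SimulationSpec, room: RoomGeometry) -> TrueTrack:
    """Simulate the dense true trajectory: integrated-OU velocity, reflected walls.

    Each fine step samples the exact Gaussian transition of the CTCRW per
    axis; a position crossing a wall is reflected back inside and the
    corresponding velocity component negated, which keeps the track inside
    the room while preserving the free-space dynamics in the interior.
    """
    if spec.fine_step <= 0:
        raise ValueError("fine_step must be > 0")
    rng = np.random.default_rng(spec.seed)
    p = spec.ctcrw_params
    n = int(round(spec.duration / spec.fine_step)) + 1
    t = spec.fine_step * np.arange(n)
    phi, q = transition(p, spec.fine_step)
    # Cholesky of the 2x2 step covariance (degenerate when sigma == 0)
    if p.sigma > 0:
        chol = np.linalg.cholesky(q + 1e-300 * np.eye(2))
    else:
        chol = np.zeros((2, 2))
    xy = np.empty((n, 2))
    v = np.empty((n, 2))
    start = np.array([room.width / 2.0, room.depth / 2.0])
    xy[0] = start
    v[0] = 0.0
    shocks = rng.standard_normal((n - 1, 2, 2))  # (step, axis, state-dim)
    f01, e1 = float(phi[0, 1]), float(phi[1, 1])
    c00, c10, c11 = float(chol[0, 0]), float(chol[1, 0]), float(chol[1, 1])
    width, depth = room.width, room.depth
    px, py = float(xy[0, 0]), float(xy[0, 1])
    vx, vy = 0.0, 0.0
    for i in range(1, n):
        n0, n1 = shocks[i - 1, 0]
        px, vx = _reflect(px + f01 * vx + c00 * n0,
                          e1 * vx + c10 * n0 + c11 * n1, width)
        n0, n1 = shocks[i - 1, 1]
        py, vy = _reflect(py + f01 * vy + c00 * n0,
                          e1 * vy + c10 * n0 + c11 * n1, depth)
        xy[i, 0], xy[i, 1] = px, py
        v[i, 0], v[i, 1] = vx, vy
    return TrueTrack(t=t, xy=xy, v=v, seed=spec.seed)


def _reflect(pos: float, vel: float, lim: float) -> tuple[float, float]:
    """Fold a coordinate into [0, lim], negating velocity per reflection."""
    period = 2.0 * lim
    pos = pos % period
    if pos > lim:
        pos = period - pos
        vel = -vel
    return pos, vel


def simulate_sensor_log(
    track: TrueTrack,
    poll_interval: float = 8.0,
    dropout_prob: float = 0.2,
    tau: float = 0.25,
    seed: int = 0,
    animal_id: str = "A01",
) -> list[SensorFix]:
    """Sample the true track at the polling grid with dropouts and noise.

    Fix = true position + independent N(0, tau^2) per axis; each scheduled
    poll is independently lost with probability ``dropout_prob``.
    """
    if poll_interval <= 0:
        raise ValueError("poll_interval must be > 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    rng = np.random.default_rng(seed)
    t0, t1 = float(track.t[0]), float(track.t[-1])
    n_polls = int(math.floor((t1 - t0) / poll_interval + 1e-9)) + 1
    poll_t = t0 + poll_interval * np.arange(n_polls)
    truth = track.position_at(poll_t)
    kept = rng.random(n_polls) >= dropout_prob
    noise = rng.normal(0.0, tau, size=(n_polls, 2)) if tau > 0 else np.zeros((n_polls, 2))
    fixes = [
        SensorFix(animal_id, float(poll_t[i]), float(truth[i, 0] + noise[i, 0]),
                  float(truth[i, 1] + noise[i, 1]))
        for i in range(n_polls)
        if kept[i]
    ]
    return fixes


def simulate_behavior_log(
    track: TrueTrack,
    behavior_model: Mapping[str, BehaviorState],
    schedule: ObservationSchedule,
    seed: int = 0,
    animal_id: str = "A01",
    room: RoomGeometry | None = None,
) -> tuple[list[BehaviorAnnotation], list[tuple[float, str]]]:
    """Simulate the ethogram state path and the decoded annotation log.

    The state path is a semi-Markov chain at 1-s resolution over the whole
    track: dwell times are exponential with the state's mean, transitions
    draw the next state with probability proportional to its weight among
    the states whose spatial gate is satisfied at that instant, and a gated
    state is vacated immediately if the animal leaves the gate region.

    Returns (annotations inside observation windows, full ground-truth
    (t, state) path at 1-s steps).
    """
    for name in behavior_model:
        if name not in ETHOGRAM["behavior"]:
            raise ValueError(f"unknown behavior state {name!r}")
    if not behavior_model:
        raise ValueError("behavior model has no states")
    rng = np.random.default_rng(seed)
    t0, t1 = float(track.t[0]), float(track.t[-1])
    times = np.arange(t0, t1 + 0.5, 1.0)
    pos = track.position_at(times)
    names = list(behavior_model)
    weights = np.array([behavior_model[s].weight for s in names], float)
    # precompute spatial-gate masks over the whole 1-s time base (vectorized)
    ok_mask = np.ones((len(times), len(names)), bool)
    if room is not None:
        import shapely

        pts = shapely.points(pos)
        for j, s in enumerate(names):
            gate = behavior_model[s].near
            if gate is None:
                continue
            kind, radius = gate
            feats = room.features_of_kind(kind)
            if not feats:
                ok_mask[:, j] = False
                continue
            d = np.min(
                np.stack([shapely.distance(f.geometry, pts) for f in feats]), axis=0
            )
            ok_mask[:, j] = d <= radius

    def draw_state(i: int, exclude: str | None) -> str:
        w = weights * ok_mask[i]
        if exclude is not None and w.sum() > 0:
            w2 = w.copy()
            w2[names.index(exclude)] = 0.0
            if w2.sum() > 0:
                w = w2
        if w.sum() <= 0:  # no gated state reachable: fall back to ungated states
            w = np.array(
                [behavior_model[s].weight if behavior_model[s].near is None else 0.0
                 for s in names]
            )
            if w.sum() <= 0:
                raise ValueError("no eligible behavior state (all states gated)")
        return names[rng.choice(len(names), p=w / w.sum())]

    path: list[tuple[float, str]] = []
    state = draw_state(0, exclude=None)
    dwell_left = rng.exponential(behavior_model[state].mean_dwell)
    for i, t in enumerate(times):
        gated_out = (
            behavior_model[state].near is not None
            and not ok_mask[i, names.index(state)]
        )
        if dwell_left <= 0 or gated_out:
            state = draw_state(i, exclude=state)
            dwell_left = rng.exponential(behavior_model[state].mean_dwell)
        path.append((float(t), state))
        dwell_left -= 1.0
    annotations = [
        BehaviorAnnotation(animal_id, t, "behavior", s)
        for t, s in path
        if schedule.contains(t)
    ]
    return annotations, path


def simulate_animal(
    spec: SimulationSpec, room: RoomGeometry, animal_id: str = "A01"
) -> tuple[TrueTrack, list[SensorFix], list[BehaviorAnnotation], list[tuple[float, str]]]:
    """Convenience: one animal's true track, sensor log and behavior log.

    Sub-seeds for the three stochastic stages are derived from the spec
    seed so the whole dataset is reproducible from (spec, animal_id).
    """
    import zlib

    ss = np.random.SeedSequence([spec.seed, zlib.crc32(animal_id.encode()) % (2**31)])
    s_track, s_sensor, s_beh = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
    track = simulate_track(
        SimulationSpec(
            ctcrw_params=spec.ctcrw_params,
            duration=spec.duration,
            fine_step=spec.fine_step,
            poll_interval=spec.poll_interval,
            dropout_prob=spec.dropout_prob,
            behavior_model=spec.behavior_model,
            schedule=spec.schedule,
            seed=s_track,
        ),
        room,
    )
    fixes = simulate_sensor_log(
        track,
        poll_interval=spec.poll_interval,
        dropout_prob=spec.dropout_prob,
        tau=spec.ctcrw_params.tau,
        seed=s_sensor,
        animal_id=animal_id,
    )
    annotations, path = simulate_behavior_log(
        track, spec.behavior_model, spec.schedule, seed=s_beh,
        animal_id=animal_id, room=room,
    )
    return track, fixes, annotations, path
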