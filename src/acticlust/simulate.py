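"""Synthetic labelled wrist-accelerometer recordings.

The generator emulates the statistical structure the pipeline relies on,
without pretending to biomechanical realism:

* static postures hold a fixed gravity orientation in the device frame
  (distinct for lying, sitting and standing) plus a slow orientation wobble
  and white sensor noise — SMV stays near 1 g, ENMO near 0;
* ambulatory activities superpose a sinusoidal arm swing at the step cadence
  on the device's anterior-posterior (x) axis together with an orientation
  oscillation at the same cadence, so both the magnitude/angle variability
  features and the ENMO dominant frequency carry the cadence;
* the left-wrist option mirrors the x and z axes, matching how the device
  frame flips between wrists.

Every bout draws its phases and noise from a seeded generator: a config is
bit-reproducible.  Amplitudes rise monotonically from household movement
through walking speeds to running, so intensity ordering of clusters is
recoverable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import LabelBout, RawRecording

__all__ = [
    "ActivityArchetype",
    "ARCHETYPES",
    "SimConfig",
    "simulate_recording",
    "default_protocol",
]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class ActivityArchetype:
    """Generative parameters of one activity type.

    orientation : unit gravity direction in the device frame (right wrist).
    swing_amplitude : arm-swing sinusoid amplitude in g (0 for postures).
    cadence : step frequency in Hz (0 for postures).
    wobble_deg : amplitude of the circular orientation wobble, degrees.
    noise_sd : white sensor-noise SD per axis, g.
    sway_amplitude : radial (along-gravity) sway tone amplitude in g; gives
        static postures a defined low-frequency ENMO spectrum (postural
        sway/breathing) instead of a pure rectified noise floor.
    vigor_jitter : relative depth of a two-level vigor envelope modulating
        swing amplitude and wobble in alternating 30-s blocks; nonzero for
        heterogeneous activities (household chores), which switch between a
        gentler and a more vigorous movement mode.
    typical_duration : default bout length in seconds.
    """

    name: str
    orientation: tuple[float, float, float]
    swing_amplitude: float = 0.0
    cadence: float = 0.0
    wobble_deg: float = 2.0
    noise_sd: float = 0.02
    sway_amplitude: float = 0.0
    vigor_jitter: float = 0.0
    typical_duration: float = 300.0

    def __post_init__(self) -> None:
        if self.swing_amplitude < 0 or self.cadence < 0:
            raise ValueError("amplitude and cadence must be >= 0")
        if self.wobble_deg < 0 or self.noise_sd < 0:
            raise ValueError("wobble and noise SDs must be >= 0")
        n = np.linalg.norm(self.orientation)
        if abs(n - 1.0) > 1e-6:
            object.__setattr__(self, "orientation",
                               tuple(_unit(self.orientation)))


def _arch(name, orient, amp=0.0, cad=0.0, wob=2.0, noise=0.02, sway=0.0,
          jitter=0.0, dur=300.0):
    return ActivityArchetype(name, tuple(_unit(orient)), amp, cad, wob, noise,
                             sway, jitter, dur)


#: Laboratory activity repertoire: three static postures with distinct wrist
#: orientations, irregular household movement, three walking intensities,
#: stair climbing and a run.  Intensity (swing amplitude) is strictly
#: increasing from postures to running.
ARCHETYPES: dict[str, ActivityArchetype] = {a.name: a for a in [
    _arch("lying", (0.10, -0.10, 0.99), wob=1.5, noise=0.012, sway=0.025,
          dur=600.0),
    _arch("seated", (0.45, -0.45, 0.77), wob=2.0, noise=0.02, sway=0.025,
          dur=300.0),
    _arch("standing", (0.12, -0.99, 0.05), wob=2.0, noise=0.018, sway=0.02,
          dur=300.0),
    _arch("household", (0.35, -0.80, 0.48), amp=0.18, cad=0.9, wob=16.0,
          noise=0.05, sway=0.05, jitter=0.6, dur=300.0),
    _arch("indoor_walking", (0.35, -0.93, 0.10), amp=0.25, cad=1.8, wob=6.0,
          noise=0.03, dur=300.0),
    _arch("treadmill_walking", (0.38, -0.92, 0.08), amp=0.35, cad=2.0, wob=7.0,
          noise=0.03, dur=270.0),
    _arch("brisk_walking", (0.40, -0.91, 0.06), amp=0.5, cad=2.2, wob=8.0,
          noise=0.035, dur=270.0),
    _arch("stairs", (0.33, -0.90, 0.28), amp=0.3, cad=1.7, wob=9.0,
          noise=0.04, dur=180.0),
    _arch("running", (0.42, -0.90, 0.11), amp=0.8, cad=2.8, wob=10.0,
          noise=0.05, dur=270.0),
]}


@dataclass
class SimConfig:
    """A simulated study: sampling rate, activity schedule, wrist, seed."""

    fs: float = 100.0
    schedule: list[tuple[str, float]] = field(default_factory=list)
    wrist: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 80.0 <= self.fs <= 100.0:
            raise ValueError("fs must lie in [80, 100] Hz")
        if self.wrist not in ("left", "right"):
            raise ValueError("wrist must be 'left' or 'right'")
        for name, dur in self.schedule:
            if name not in ARCHETYPES:
                raise ValueError(f"unknown archetype {name!r}")
            if dur <= 0:
                raise ValueError("bout durations must be > 0")

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.schedule)


def _orthonormal_pair(g0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(g0 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(g0, helper))
    v = np.cross(g0, u)
    return u, v


def _simulate_bout(arch: ActivityArchetype, n: int, fs: float,
                   rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    g0 = np.asarray(arch.orientation)
    u, v = _orthonormal_pair(g0)
    wob = np.deg2rad(arch.wobble_deg)
    # slow drift for postures (one cycle per 10-s window), step cadence for
    # ambulation; the two tilt components run in quadrature so the wobble is
    # circular and its window statistics do not depend on the drawn phase
    f_tilt = arch.cadence if arch.cadence > 0 else 0.1
    phases = rng.uniform(0, 2 * np.pi, size=3)
    # two-level vigor envelope for heterogeneous activities (chore
    # mixtures): alternating 30-s blocks from the bout start, so mode
    # switches align with the 10-s analysis windows
    vigor = 1.0 + arch.vigor_jitter * np.where((t // 30.0) % 2 < 1, -1.0, 1.0)
    alpha = vigor * wob * np.sin(2 * np.pi * f_tilt * t + phases[0])
    beta = vigor * wob * np.cos(2 * np.pi * f_tilt * t + phases[0])
    gdir = (g0[None, :] + alpha[:, None] * u[None, :] + beta[:, None] * v[None, :])
    gdir /= np.linalg.norm(gdir, axis=1, keepdims=True)
    a = gdir
    if arch.sway_amplitude > 0:
        sway = arch.sway_amplitude * np.sin(2 * np.pi * 0.25 * t + phases[1])
        a = a * (1.0 + sway)[:, None]
    if arch.swing_amplitude > 0:
        # arm swing is gait-driven, hence phase-locked to the orientation
        # oscillation (quarter-cycle lead)
        swing = vigor * arch.swing_amplitude * np.sin(
            2 * np.pi * arch.cadence * t + phases[0] + np.pi / 2)
        a = a + np.outer(swing, np.array([1.0, 0.0, 0.0]))
    a = a + rng.normal(0.0, arch.noise_sd, size=(n, 3))
    return a


def simulate_recording(cfg: SimConfig) -> tuple[RawRecording, list[LabelBout]]:
    """Generate a labelled recording following the config's schedule.

    Returns the recording (uniform sampling at cfg.fs) and the exact label
    bouts matching the schedule.  Deterministic given cfg.seed.
    """
    if not cfg.schedule:
        raise ValueError("empty schedule")
    rng = np.random.default_rng(cfg.seed)
    chunks: list[np.ndarray] = []
    bouts: list[LabelBout] = []
    t0 = 0.0
    for name, dur in cfg.schedule:
        arch = ARCHETYPES[name]
        n = int(round(dur * cfg.fs))
        chunks.append(_simulate_bout(arch, n, cfg.fs, rng))
        bouts.append(LabelBout(t0, t0 + n / cfg.fs, name))
        t0 += n / cfg.fs
    xyz = np.vstack(chunks)
    if cfg.wrist == "left":
        xyz = xyz * np.array([-1.0, 1.0, -1.0])
    time = np.arange(xyz.shape[0]) / cfg.fs
    rec = RawRecording(time=time, xyz=xyz, fs=cfg.fs, wrist=cfg.wrist)
    return rec, bouts


def default_protocol(fs: float = 100.0, seed: int = 0,
                     wrist: str = "right") -> SimConfig:
    """Laboratory-style schedule covering the full activity repertoire.

    Lying is held for 10 min, other activities for 3-5 min, mirroring a
    semi-structured laboratory visit; suitable for end-to-end tests.
    """
    schedule = [(a.name, a.typical_duration) for a in ARCHETYPES.values()]
    return SimConfig(fs=fs, schedule=schedule, wrist=wrist, seed=seed)
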