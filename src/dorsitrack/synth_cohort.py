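"""Synthetic speckle phantoms and simulated cohorts with exact ground truth.

The study's raw ultrasound recordings are not publicly deposited, so every
downstream stage is exercised on synthetic B-mode-like videos instead: a
random scatterer field blurred by a Gaussian point spread (no acoustic
physics), warped frame-to-frame by a prescribed per-layer stretch along the
fiber (lateral) axis. Because the warp is the bookkeeping, the ground-truth
deformation of any ROI inside a layer is known exactly.

The emulated acquisition follows the study protocol: 50 frames/s video of
five stacked dorsal neck muscles in longitudinal view (TR, SP, Scap, Scerv,
MF from superficial to deep), ten 2-s rotation cycles paced at 30
beats/min (reach on one beat, return on the next), a contact-switch sync
channel marking start / 20-degree reach / stop of every cycle, and a 15 mm
ROI per muscle.

Per-muscle strain magnitudes are free parameters (the study reports none);
defaults are a few percent peak deformation, graded superficial to deep,
with the whiplash group's deep layers reduced in rotation to the painful
(right) side — the qualitative effect structure of the study's results.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import MUSCLES, ConfigError, FrameSequence, SyncEvent

# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerSpec:
    """One muscle layer: depth extent and its cyclic strain behaviour.

    ``strain_amplitude`` is the signed peak deformation in percent per
    cycle (positive = elongation). ``phase_offset`` shifts the cycle as a
    fraction of the period. ``noise_sd`` is an optional per-subject
    amplitude jitter in percentage points.
    """

    label: str
    depth_range: tuple[float, float]  # mm from top of image
    strain_amplitude: float = 0.0  # percent, signed
    phase_offset: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        d0, d1 = self.depth_range
        if not d1 > d0 >= 0:
            raise ConfigError(f"bad depth range for {self.label}: {self.depth_range}")
        if not np.isfinite(self.strain_amplitude):
            raise ConfigError("strain_amplitude must be finite")


@dataclass(frozen=True)
class MotionModel:
    """Timing and waveform of the repeated rotation task.

    Defaults: ten cycles at 2 s per full reach-and-return rotation (the
    30 beats/min metronome gives one beat out, one beat back), a smooth
    raised-cosine strain waveform that starts and ends each cycle at zero
    and peaks mid-cycle, and a small rigid sinusoidal sway to stress the
    tracker. ``rest_frames`` motionless frames are prepended.
    """

    n_cycles: int = 10
    cycle_period_s: float = 2.0
    rest_frames: int = 10
    waveform: str = "raised_cosine"  # or "biphasic"
    sway_mm: tuple[float, float] = (0.1, 0.0)  # rigid (axial, lateral) amplitude

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        if self.cycle_period_s <= 0:
            raise ConfigError("cycle_period_s must be positive")
        if self.rest_frames < 0:
            raise ConfigError("rest_frames must be >= 0")
        if self.waveform not in ("raised_cosine", "biphasic"):
            raise ConfigError(f"unknown waveform {self.waveform!r}")


@dataclass(frozen=True)
class SceneConfig:
    """Imaging parameters of the emulated scanner (not a physics model)."""

    image_size: tuple[int, int] = (200, 190)  # rows (axial) x cols (lateral)
    pixel_spacing_mm: tuple[float, float] = (0.2, 0.2)
    frame_rate_hz: float = 50.0
    speckle_density: float = 8.0  # scatterers per mm^2
    point_spread: float = 0.3  # Gaussian PSF sigma, mm
    additive_noise_sd: float = 0.02  # intensity units on [0, 1]
    background: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_size) <= 0:
            raise ConfigError("image size must be positive")
        if self.frame_rate_hz <= 0:
            raise ConfigError("frame rate must be positive")
        if min(self.pixel_spacing_mm) <= 0:
            raise ConfigError("pixel spacing must be positive")
        if self.speckle_density < 0 or self.additive_noise_sd < 0:
            raise ConfigError("density and noise must be >= 0")

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (self.image_size[0] * self.pixel_spacing_mm[0],
                self.image_size[1] * self.pixel_spacing_mm[1])


@dataclass(frozen=True)
class CohortConfig:
    """Effect structure of a simulated case-control cohort.

    ``group_effects`` maps (group, muscle, direction) to the mean peak
    strain amplitude in percent; per-subject amplitudes are that mean plus
    Gaussian between-subject noise, drawn independently per muscle and
    direction. ``followup_effects`` shifts the WAD group's amplitudes at
    the follow-up timepoint (per muscle, applied in the right direction
    and the left direction alike unless a (muscle, direction) key is used).
    """

    n_per_group: int = 34
    group_effects: dict = field(default_factory=lambda: default_group_effects())
    between_subject_sd: float = 1.5  # percent
    timepoints: tuple[str, ...] = ("baseline",)
    followup_effects: dict = field(default_factory=dict)
    directions: tuple[str, ...] = ("right", "left")
    groups: tuple[str, ...] = ("WAD", "control")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if self.between_subject_sd < 0:
            raise ConfigError("between_subject_sd must be >= 0")

    def mean_amplitude(self, group: str, muscle: str, direction: str,
                       timepoint: str = "baseline") -> float:
        amp = self.group_effects[(group, muscle, direction)]
        if timepoint != "baseline" and group == "WAD":
            amp += self.followup_effects.get((muscle, direction),
                                             self.followup_effects.get(muscle, 0.0))
        return amp


def default_layers(amplitudes: dict[str, float] | None = None,
                   phase_offsets: dict[str, float] | None = None) -> list[LayerSpec]:
    """Five stacked layers, superficial TR at the top through deep MF."""
    depth_ranges = {
        "TR": (2.0, 8.0),
        "SP": (9.0, 15.0),
        "Scap": (16.0, 22.0),
        "Scerv": (23.0, 29.0),
        "MF": (30.0, 36.0),
    }
    amplitudes = amplitudes or {}
    phase_offsets = phase_offsets or {}
    return [LayerSpec(m, depth_ranges[m],
                      strain_amplitude=amplitudes.get(m, 0.0),
                      phase_offset=phase_offsets.get(m, 0.0))
            for m in MUSCLES]


def null_group_effects() -> dict:
    """Group effects with no group difference anywhere (both groups get
    the control amplitudes); the null world for type-I-error checks."""
    effects = default_group_effects()
    return {(g, m, d): effects[("control", m, d)] for (g, m, d) in effects}


def default_group_effects() -> dict:
    """Mean peak strain (%) per (group, muscle, direction).

    Controls deform a few percent, graded superficial to deep; the WAD
    group's middle and deep layers (Scap, Scerv, MF) are reduced in
    rotation to the right (most painful side) by at least one
    between-subject SD. The left direction is unaffected.
    """
    control = {"TR": 4.0, "SP": 5.0, "Scap": 6.0, "Scerv": 7.0, "MF": 8.0}
    wad_right_deficit = {"TR": 0.0, "SP": 0.0, "Scap": 1.5, "Scerv": 2.0, "MF": 2.0}
    effects = {}
    for m in MUSCLES:
        for d in ("right", "left"):
            effects[("control", m, d)] = control[m]
            effects[("WAD", m, d)] = control[m] - (wad_right_deficit[m] if d == "right" else 0.0)
    return effects


# --------------------------------------------------------------------------
# waveform and ground truth
# --------------------------------------------------------------------------

def waveform_value(name: str, tau: np.ndarray | float) -> np.ndarray:
    """Normalized cyclic strain waveform w(tau), tau in cycle fractions.

    ``raised_cosine``: 0.5 (1 - cos 2 pi tau) — one-signed, peaks at 1 at
    mid-cycle, zero at cycle boundaries. ``biphasic``: sin(2 pi tau) —
    elongation then shortening within one cycle.
    """
    tau = np.asarray(tau, dtype=np.float64)
    if name == "raised_cosine":
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * tau))
    if name == "biphasic":
        return np.sin(2.0 * np.pi * tau)
    raise ConfigError(f"unknown waveform {name!r}")


@dataclass
class GroundTruth:
    """Exact bookkeeping of the warp used to render a sequence.

    ``deformation_percent`` holds the true per-layer deformation curve in
    percent, one column per layer in ``labels`` order; ``strain_fraction``
    the same quantity as a fraction; ``sway_mm`` the rigid translation per
    frame. ``advect`` applies the exact forward map used for rendering, so
    measuring the distance between two advected points inside a layer
    reproduces the curve with no estimation error.
    """

    times_s: np.ndarray
    labels: tuple[str, ...]
    deformation_percent: np.ndarray  # (n_frames, n_layers)
    strain_fraction: np.ndarray  # (n_frames, n_layers)
    sway_mm: np.ndarray  # (n_frames, 2) rigid (axial, lateral) translation
    depth_knots_mm: np.ndarray
    layer_of_knot: np.ndarray  # index into labels per knot
    center_lateral_mm: float

    def curve(self, label: str) -> np.ndarray:
        return self.deformation_percent[:, self.labels.index(label)]

    def strain_profile(self, depth_mm: np.ndarray, frame: int) -> np.ndarray:
        """Strain fraction as a function of material depth at ``frame``."""
        knot_values = self.strain_fraction[frame, self.layer_of_knot]
        return np.interp(np.asarray(depth_mm, dtype=float),
                         self.depth_knots_mm, knot_values)

    def advect(self, points_mm: np.ndarray, frame: int) -> np.ndarray:
        """Map material points (frame-0 coordinates, mm, (row, col)) to
        their position at ``frame``."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        s = self.strain_profile(pts[:, 0], frame)
        out = np.empty_like(pts)
        out[:, 0] = pts[:, 0] + self.sway_mm[frame, 0]
        out[:, 1] = (self.center_lateral_mm
                     + (1.0 + s) * (pts[:, 1] - self.center_lateral_mm)
                     + self.sway_mm[frame, 1])
        return out


# --------------------------------------------------------------------------
# image formation
# --------------------------------------------------------------------------

def _scatterer_sites(scene: SceneConfig, rng: np.random.Generator | None = None):
    """Random scatterer positions (mm) and echo amplitudes."""
    rng = rng or np.random.default_rng(scene.seed)
    h_mm, w_mm = scene.extent_mm
    n = rng.poisson(scene.speckle_density * h_mm * w_mm)
    pos = rng.uniform([0.0, 0.0], [h_mm, w_mm], size=(n, 2))
    amp = rng.exponential(1.0, size=n)
    return pos, amp


def make_speckle_frame(scene: SceneConfig,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Render the reference speckle frame, float intensities in [0, 1].

    A Poisson-random scatterer field is splatted bilinearly onto the pixel
    grid, convolved with a Gaussian point spread, scaled by a fixed gain
    (so the nominal mean brightness is density-independent), and offset by
    a uniform background. Zero density gives a uniform background frame.
    """
    rows, cols = scene.image_size
    pos, amp = _scatterer_sites(scene, rng)
    img = np.zeros((rows, cols), dtype=np.float64)
    if len(pos):
        r = pos[:, 0] / scene.pixel_spacing_mm[0]
        c = pos[:, 1] / scene.pixel_spacing_mm[1]
        r0 = np.clip(np.floor(r).astype(int), 0, rows - 1)
        c0 = np.clip(np.floor(c).astype(int), 0, cols - 1)
        r1 = np.minimum(r0 + 1, rows - 1)
        c1 = np.minimum(c0 + 1, cols - 1)
        fr, fc = r - r0, c - c0
        np.add.at(img, (r0, c0), amp * (1 - fr) * (1 - fc))
        np.add.at(img, (r0, c1), amp * (1 - fr) * fc)
        np.add.at(img, (r1, c0), amp * fr * (1 - fc))
        np.add.at(img, (r1, c1), amp * fr * fc)
        sigma = (scene.point_spread / scene.pixel_spacing_mm[0],
                 scene.point_spread / scene.pixel_spacing_mm[1])
        img = ndimage.gaussian_filter(img, sigma, mode="nearest")
        # fixed gain: expected blurred mean is density * pixel area (unit
        # mean echo amplitude), independent of the PSF
        pixel_area = scene.pixel_spacing_mm[0] * scene.pixel_spacing_mm[1]
        img = img * (0.45 / (scene.speckle_density * pixel_area))
    return np.clip(scene.background + img, 0.0, 1.0)


# --------------------------------------------------------------------------
# sequence rendering
# --------------------------------------------------------------------------

def _validate_layers(layers: list[LayerSpec], scene: SceneConfig) -> list[LayerSpec]:
    layers = sorted(layers, key=lambda l: l.depth_range[0])
    h_mm = scene.extent_mm[0]
    for a, b in itertools.pairwise(layers):
        if b.depth_range[0] < a.depth_range[1]:
            raise ConfigError(f"layers {a.label} and {b.label} overlap")
    for l in layers:
        if l.depth_range[1] > h_mm:
            raise ConfigError(f"layer {l.label} extends below the image")
    return layers


def motion_timeline(motion: MotionModel, frame_rate_hz: float):
    """Frame counts and per-frame cycle phase for a motion model.

    Returns (n_frames, frames_per_cycle, tau) where ``tau`` is the global
    phase in cycles (negative sentinel -1 during the rest segment).
    """
    fpc = int(round(motion.cycle_period_s * frame_rate_hz))
    if fpc < 4:
        raise ConfigError("cycle period too short for the frame rate")
    n_frames = motion.rest_frames + motion.n_cycles * fpc + 1
    tau = np.full(n_frames, -1.0)
    active = np.arange(motion.rest_frames, n_frames)
    tau[active] = (active - motion.rest_frames) / fpc
    return n_frames, fpc, tau


def _sync_events(motion: MotionModel, fpc: int) -> list[SyncEvent]:
    events = []
    for i in range(motion.n_cycles):
        start = motion.rest_frames + i * fpc
        events.append(SyncEvent(start, "start"))
        events.append(SyncEvent(start + fpc // 2, "reach"))
        events.append(SyncEvent(start + fpc, "stop"))
    return events


def render_sequence(scene: SceneConfig, layers: list[LayerSpec],
                    motion: MotionModel,
                    rng: np.random.Generator | None = None,
                    dtype=np.uint8) -> tuple[FrameSequence, GroundTruth]:
    """Render a full rotation-task video plus its exact ground truth.

    Every frame is the reference speckle frame warped by a per-layer
    lateral stretch about the image center (linear through-depth
    interpolation between layers) plus a rigid sway, with fresh additive
    Gaussian noise per frame.
    """
    layers = _validate_layers(layers, scene)
    rng = rng or np.random.default_rng(scene.seed)
    reference = make_speckle_frame(scene, rng)

    n_frames, fpc, tau = motion_timeline(motion, scene.frame_rate_hz)
    labels = tuple(l.label for l in layers)

    strain = np.zeros((n_frames, len(layers)))
    active = tau >= 0
    for j, layer in enumerate(layers):
        w = waveform_value(motion.waveform, (tau[active] + layer.phase_offset) % 1.0)
        # each cycle starts and ends at zero strain: the modular phase is
        # continuous for zero offset; nonzero offsets shift within-cycle
        strain[active, j] = layer.strain_amplitude / 100.0 * w

    sway = np.zeros((n_frames, 2))
    sway[active, 0] = motion.sway_mm[0] * np.sin(2 * np.pi * tau[active])
    sway[active, 1] = motion.sway_mm[1] * np.sin(2 * np.pi * tau[active])

    knots, knot_layer = [], []
    for j, layer in enumerate(layers):
        knots.extend(layer.depth_range)
        knot_layer.extend([j, j])

    spacing = scene.pixel_spacing_mm
    truth = GroundTruth(
        times_s=np.arange(n_frames) / scene.frame_rate_hz,
        labels=labels,
        deformation_percent=strain * 100.0,
        strain_fraction=strain,
        sway_mm=sway,
        depth_knots_mm=np.asarray(knots, dtype=float),
        layer_of_knot=np.asarray(knot_layer, dtype=int),
        center_lateral_mm=(scene.image_size[1] - 1) / 2.0 * spacing[1],
    )

    rows, cols = scene.image_size
    cc = (cols - 1) / 2.0
    row_idx = np.arange(rows, dtype=np.float64)
    col_idx = np.arange(cols, dtype=np.float64)

    frames = np.empty((n_frames,) + scene.image_size,
                      dtype=np.uint8 if dtype == np.uint8 else np.float64)
    for f in range(n_frames):
        moving = active[f] and (np.any(strain[f]) or np.any(sway[f]))
        if not moving:
            # rest / zero-phase frames share geometry; only noise differs
            warped = reference
        else:
            src_row = row_idx - sway[f, 0] / spacing[0]
            s_row = truth.strain_profile(src_row * spacing[0], f)
            src_col = cc + (col_idx[None, :] - cc - sway[f, 1] / spacing[1]) \
                / (1.0 + s_row[:, None])
            coords = np.broadcast_arrays(src_row[:, None], src_col)
            warped = ndimage.map_coordinates(reference, coords, order=1,
                                             mode="nearest")
        noisy = warped if scene.additive_noise_sd == 0 else \
            warped + rng.normal(0.0, scene.additive_noise_sd, warped.shape)
        if dtype == np.uint8:
            frames[f] = np.clip(np.round(noisy * 255.0), 0, 255).astype(np.uint8)
        else:
            frames[f] = noisy

    seq = FrameSequence(frames, 1.0 / scene.frame_rate_hz, spacing,
                        _sync_events(motion, fpc))
    return seq, truth


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """Provenance of one simulated subject at one timepoint."""

    subject: str
    group: str
    sex: str
    age: float
    wad_grade: int | None
    timepoint: str
    seed: int
    amplitudes: dict  # (direction, muscle) -> drawn peak strain %


def draw_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw subject metadata and per-muscle amplitudes for a whole cohort.

    Deterministic for a fixed config seed; each subject gets an
    independent child seed recorded for rendering reproducibility.
    """
    ss = np.random.SeedSequence(config.seed)
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    records = []
    for group in config.groups:
        for i in range(config.n_per_group):
            subject = f"{group}{i:03d}"
            sex = "F" if meta_rng.random() < 0.7 else "M"
            age = float(np.clip(meta_rng.normal(40.0, 10.0), 18, 63))
            grade = int(2 + (meta_rng.random() < 0.25)) if group == "WAD" else None
            child = np.random.SeedSequence(entropy=config.seed,
                                           spawn_key=(zlib.crc32(subject.encode()),))
            subj_rng = np.random.default_rng(child)
            for tp in config.timepoints:
                amps = {}
                for d in config.directions:
                    for m in MUSCLES:
                        mean = config.mean_amplitude(group, m, d, tp)
                        amps[(d, m)] = mean + subj_rng.normal(
                            0.0, config.between_subject_sd)
                records.append(SubjectRecord(
                    subject=subject, group=group, sex=sex, age=age,
                    wad_grade=grade, timepoint=tp,
                    seed=int(child.generate_state(1)[0] % (2**31)),
                    amplitudes=amps))
    return records


@dataclass
class SubjectSim:
    """One rendered subject: record plus per-direction video and truth."""

    record: SubjectRecord
    sequences: dict  # direction -> (FrameSequence, GroundTruth)


def simulate_cohort(config: CohortConfig, scene: SceneConfig,
                    motion: MotionModel) -> list[SubjectSim]:
    """Render full videos for every subject/timepoint/direction.

    Intended for small demonstration cohorts; statistics-scale cohorts
    should use :func:`simulate_feature_curves` instead of rendering.
    """
    sims = []
    for rec in draw_cohort(config):
        rng = np.random.default_rng(rec.seed)
        seqs = {}
        for d in config.directions:
            amps = {m: rec.amplitudes[(d, m)] for m in MUSCLES}
            layers = default_layers(amplitudes=amps)
            seq, truth = render_sequence(
                replace(scene, seed=rec.seed), layers, motion, rng=rng)
            seqs[d] = (seq, truth)
        sims.append(SubjectSim(rec, seqs))
    return sims


def true_cycle_curve(amplitude_percent: float, motion: MotionModel,
                     frame_rate_hz: float = 50.0):
    """Exact single-cycle deformation curve (times_s, values_percent)."""
    fpc = int(round(motion.cycle_period_s * frame_rate_hz))
    tau = np.arange(fpc + 1) / fpc
    values = amplitude_percent * waveform_value(motion.waveform, tau % 1.0)
    return tau * motion.cycle_period_s, values


def simulate_feature_table(config: CohortConfig,
                           motion: MotionModel | None = None,
                           frame_rate_hz: float = 50.0):
    """Statistics-level cohort: the 25-variable feature table computed
    from exact ground-truth curves, skipping rendering and tracking.

    Per-subject amplitudes are drawn exactly as in the rendered pathway;
    each muscle's analytic single-cycle deformation curve then runs
    through the real curve/area code (:mod:`deformation_curves`,
    :mod:`curve_areas`), so the feature table is the one a perfect tracker
    would produce. Used for cohort-scale statistical validation where
    rendering 68 videos is pointless.
    """
    from .curve_areas import build_feature_table, decompose
    from .deformation_curves import DeformationCurve, to_rate

    motion = motion or MotionModel()
    records = []
    for rec in draw_cohort(config):
        for d in config.directions:
            muscles = {}
            for m in MUSCLES:
                t, v = true_cycle_curve(rec.amplitudes[(d, m)], motion,
                                        frame_rate_hz)
                curve = DeformationCurve(t, v, 15.0, np.ones(len(t), bool),
                                         muscle=m, direction=d)
                muscles[m] = decompose(curve, to_rate(curve))
            records.append({
                "subject": rec.subject, "group": rec.group, "sex": rec.sex,
                "age": rec.age, "wad_grade": rec.wad_grade,
                "timepoint": rec.timepoint, "direction": d,
                "muscles": muscles,
            })
    return build_feature_table(records)
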