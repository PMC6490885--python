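"""Stimuli and trial schedules for hierarchical frequency tagging (HFT).

HFT superimposes two periodic modulations on one image stream:

* **SWIFT** — cyclic wavelet-domain scrambling of an image.  Each cycle
  starts from a fully scrambled frame, passes once through the intact
  image (the *peak*) and returns to scramble, tagging object-recognition
  activity at the cycle frequency while holding local low-level image
  statistics constant.
* **SSVEP** — a global sinusoidal contrast modulation at a higher
  frequency, tagging early visual activity.

This module builds SWIFT frame sequences, the noise sequences paired with
them, the trial schedules of the expectation (pattern-violation vs
image-repetition) and attention (dual-frequency counting) paradigms, and
the stimulus phase references that the stimulus-referenced coherence
variant consumes.

Phase conventions (fixed so results are reproducible; the coherence
statistic is invariant to any constant offset): the SSVEP contrast cosine
has its maximum at t = 0 of the trial, and the SWIFT phase is 0 (mod 2*pi)
at every peak-frame time, with the peak at the middle of each cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pywt

from ._meyer import meyer_wavelet

__all__ = [
    "ImageGrid",
    "SwiftSequence",
    "Cycle",
    "TrialSchedule",
    "CrossEvent",
    "PhaseReference",
    "DimensionError",
    "swift_scramble",
    "make_noise_sequence",
    "alpha_blend",
    "contrast_modulate",
    "build_exp1_schedule",
    "build_exp2_schedule",
    "build_cross_schedule",
    "stimulus_phase",
    "assign_variants",
]

#: fraction of a SWIFT cycle at which the intact image appears
PEAK_FRACTION = 0.5


class DimensionError(ValueError):
    """Image dimensions incompatible with the requested wavelet depth."""


@dataclass(frozen=True)
class ImageGrid:
    """A grayscale image with intensities in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise DimensionError(f"expected a 2-D image, got shape {px.shape}")
        if px.size == 0:
            raise DimensionError("empty image")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class SwiftSequence:
    """One cyclic SWIFT scramble of a source image.

    ``frames`` has shape ``(n_frames, height, width)``; frame values may
    slightly exceed [0, 1] away from the peak because wavelet-domain
    rotation does not respect pixel-range bounds.  ``frames[peak_index]``
    reconstructs the source image; ``anchor_index`` is the frame at path
    angle pi from the peak — the geometrically most distant scramble,
    used to seed noise sequences and as the swap point between sequence
    variants.
    """

    frames: np.ndarray
    peak_index: int
    anchor_index: int
    variant_id: int = 0
    source: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class Cycle:
    """One SWIFT cycle in a trial: what is shown, at which rate, and when."""

    category: str  # face | house | noise_face | noise_house
    swift_freq: float
    onset: float
    variant_id: int = 0
    swap_at: str = "peak"  # peak | anchor


@dataclass(frozen=True)
class TrialSchedule:
    """The full stimulus timeline of one trial."""

    cycles: tuple[Cycle, ...]
    ssvep_freq: float
    duration: float
    task: str
    target_index: int | None = None
    contrast_bounds: tuple[float, float] = (0.30, 1.00)
    frame_rate: float = 120.0

    def __post_init__(self) -> None:
        onsets = [c.onset for c in self.cycles]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("cycle onsets must be strictly increasing")

    @property
    def swift_freqs(self) -> tuple[float, ...]:
        return tuple(sorted({c.swift_freq for c in self.cycles}))

    @property
    def categories(self) -> list[str]:
        return [c.category for c in self.cycles]

    def stream(self, swift_freq: float) -> list[Cycle]:
        """Cycles belonging to one SWIFT frequency stream."""
        return [c for c in self.cycles if abs(c.swift_freq - swift_freq) < 1e-9]

    def image_count(self, category: str) -> int:
        """Number of non-noise cycles showing ``category``."""
        return sum(1 for c in self.cycles if c.category == category)


@dataclass(frozen=True)
class CrossEvent:
    time: float
    height: str  # up | down
    colour: str  # red | green | blue

    @property
    def is_target(self) -> bool:
        return (self.height, self.colour) in {("up", "red"), ("down", "green")}


@dataclass(frozen=True)
class PhaseReference:
    """Analytic stimulus phase: advances by 2*pi per cycle of ``freq``.

    ``kind`` is ``"ssvep_contrast"`` (phase 0 at trial start, where the
    contrast cosine peaks) or ``"swift_cycle"`` (phase 0 at every
    peak-frame time).
    """

    freq: float
    kind: str
    t_zero: float = 0.0  # a time at which the phase is 0 (mod 2*pi)

    def phase_at(self, t):
        return 2.0 * np.pi * self.freq * (np.asarray(t, dtype=float) - self.t_zero)


# ---------------------------------------------------------------------------
# SWIFT scrambling
# ---------------------------------------------------------------------------

def _pad_to_multiple(arr: np.ndarray, block: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = arr.shape
    ph = (-h) % block
    pw = (-w) % block
    if ph or pw:
        arr = np.pad(arr, ((0, ph), (0, pw)), mode="symmetric")
    return arr, (h, w)


def _circle_paths(details: list[np.ndarray], rng: np.random.Generator):
    """For every 3-vector of detail coefficients, build the circular path
    through two random vectors of the same norm.

    Returns per level the tuple (center, rho, u1, u2, frozen) such that the
    rotated vector at angle theta is ``center + rho*(cos(theta)*u1 +
    sin(theta)*u2)``; at theta = 0 this reproduces the original vector, and
    every point on the path has the original vector's norm exactly.
    ``frozen`` marks degenerate locations (zero or collinear vectors) that
    stay fixed.
    """
    paths = []
    for V in details:  # V: (3, a, b)
        r = np.linalg.norm(V, axis=0)
        # two random directions on the sphere of radius r
        def rand_on_sphere():
            d = rng.standard_normal(V.shape)
            n = np.linalg.norm(d, axis=0)
            n[n == 0] = 1.0
            return d / n * r

        A, B = rand_on_sphere(), rand_on_sphere()
        # plane through V, A, B; its intersection with the radius-r sphere
        # is the circle.  normal = (A - V) x (B - V)
        normal = np.cross(A - V, B - V, axis=0)
        nn = np.linalg.norm(normal, axis=0)
        frozen = (r <= 0.0) | (nn <= 1e-12 * np.maximum(r, 1.0) ** 2)
        nn_safe = np.where(nn > 0, nn, 1.0)
        nhat = normal / nn_safe
        center = (V * nhat).sum(axis=0) * nhat
        w1 = V - center
        rho = np.linalg.norm(w1, axis=0)
        frozen |= rho <= 1e-12 * np.maximum(r, 1.0)
        rho_safe = np.where(rho > 0, rho, 1.0)
        u1 = w1 / rho_safe
        u2 = np.cross(nhat, u1, axis=0)
        paths.append((center, rho, u1, u2, frozen, V))
    return paths


def swift_scramble(
    image: ImageGrid | np.ndarray,
    n_frames: int,
    levels: int = 6,
    rng_seed: int | np.random.Generator = 0,
    peak_index: int | None = None,
    filter_length: int = 256,
) -> SwiftSequence:
    """Create a cyclic SWIFT sequence by wavelet-coefficient rotation.

    The image is decomposed with a discrete Meyer wavelet at ``levels``
    depths; at each detail location/scale the 3-vector of (horizontal,
    vertical, diagonal) coefficients is rotated along a circular path
    through two random vectors of identical norm, and each frame is the
    inverse transform at one path angle.  The approximation band is left
    untouched, which preserves the frame mean exactly.  Frame ``peak_index``
    (default ``n_frames // 2``) is at angle 0 and reconstructs the image.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if n_frames < 3:
        raise ValueError("n_frames must be >= 3")
    px = image.pixels if isinstance(image, ImageGrid) else np.asarray(image, dtype=float)
    if px.ndim != 2:
        raise DimensionError(f"expected a 2-D image, got shape {px.shape}")
    if min(px.shape) < 2**levels:
        raise DimensionError(
            f"image of shape {px.shape} is too small for {levels} decomposition levels"
        )
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    if peak_index is None:
        peak_index = n_frames // 2

    padded, orig_shape = _pad_to_multiple(px, 2**levels)
    wav = meyer_wavelet(filter_length)
    with warnings.catch_warnings():
        # pywt warns when the filter is longer than the deepest band; with
        # periodized convolution the transform stays exactly invertible
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(padded, wav, mode="periodization", level=levels)
    approx = coeffs[0]
    details = [np.stack(lvl) for lvl in coeffs[1:]]
    paths = _circle_paths(details, rng)

    h, w = orig_shape
    frames = np.empty((n_frames, h, w))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for k in range(n_frames):
            theta = 2.0 * np.pi * ((k - peak_index) % n_frames) / n_frames
            rotated = []
            for center, rho, u1, u2, frozen, V in paths:
                P = center + rho * (np.cos(theta) * u1 + np.sin(theta) * u2)
                P = np.where(frozen, V, P)
                rotated.append(tuple(P))
            frame = pywt.waverec2([approx, *rotated], wav, mode="periodization")
            frames[k] = frame[:h, :w]

    anchor_index = (peak_index + n_frames // 2) % n_frames
    return SwiftSequence(
        frames=frames,
        peak_index=peak_index,
        anchor_index=anchor_index,
        source=px,
    )


def make_noise_sequence(
    seq: SwiftSequence,
    n_frames: int | None = None,
    rng_seed: int | np.random.Generator = 0,
    levels: int = 6,
) -> SwiftSequence:
    """Scramble the most distant frame of ``seq`` into a matching noise sequence.

    The anchor frame (path angle pi from the peak) is used as the source of
    a fresh SWIFT scramble, so the noise sequence shares the image
    sequence's local low-level statistics but never reconstructs the
    original image.
    """
    if n_frames is None:
        n_frames = seq.n_frames
    source = seq.frames[seq.anchor_index]
    return swift_scramble(source, n_frames=n_frames, levels=levels, rng_seed=rng_seed)


def alpha_blend(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Equal-weight alpha blend of two frame stacks."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return 0.5 * a + 0.5 * b


def contrast_modulate(
    frames: np.ndarray,
    ssvep_freq: float,
    frame_rate: float,
    bounds: tuple[float, float] = (0.30, 1.00),
) -> np.ndarray:
    """Apply the sinusoidal SSVEP contrast modulation to a frame stack.

    Each frame's contrast about its own mean is scaled by
    ``c(t) = lo + (hi - lo) * (1 + cos(2*pi*f*t)) / 2`` with t the frame
    time; the modulation peaks (full contrast) at t = 0 and bottoms out at
    ``lo`` half a period later.  Defaults span 30%-100% of the original
    contrast.
    """
    lo, hi = bounds
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("bounds must satisfy 0 <= lo <= hi <= 1")
    if frame_rate <= 2.0 * ssvep_freq:
        raise ValueError(
            f"frame rate {frame_rate} Hz cannot represent a {ssvep_freq} Hz "
            "contrast modulation (aliasing)"
        )
    frames = np.asarray(frames, dtype=float)
    t = np.arange(frames.shape[0]) / frame_rate
    c = lo + (hi - lo) * (1.0 + np.cos(2.0 * np.pi * ssvep_freq * t)) / 2.0
    means = frames.mean(axis=(1, 2), keepdims=True)
    return means + c[:, None, None] * (frames - means)


# ---------------------------------------------------------------------------
# Trial schedules
# ---------------------------------------------------------------------------

_CAT = {"F": "face", "H": "house"}
_FLIP = {"face": "house", "house": "face"}


def assign_variants(categories: list[str], n_variants: int = 3) -> list[tuple[int, str]]:
    """Assign a SWIFT variant id and swap point to each cycle.

    Three sequence variants per image are alternated to avoid low-level
    tagging by the repeated scrambled frames.  When the next cycle shows
    the same image, the variant is swapped at the peak frame; otherwise the
    image hands over to its noise sequence at the anchor frame.
    """
    out = []
    variant = 0
    for i, cat in enumerate(categories):
        nxt = categories[i + 1] if i + 1 < len(categories) else None
        swap_at = "peak" if nxt == cat else "anchor"
        out.append((variant, swap_at))
        variant = (variant + 1) % n_variants
    return out


def build_exp1_schedule(
    pattern: str,
    task: str,
    n_cycles: int,
    violation_index: int,
    swift_freq: float = 1.2,
    ssvep_freq: float = 15.0,
    frame_rate: float = 120.0,
) -> TrialSchedule:
    """Build an expectation-paradigm trial schedule.

    The face/house ``pattern`` (e.g. ``"FHHFFH"``) repeats until
    ``violation_index`` (0-based), where the category is flipped; the flip
    is simultaneously the pattern violation of the PV task and the
    three-in-a-row repetition of the IR task, so a PV schedule and its
    paired IR schedule carry identical category series.
    """
    if task not in {"PV", "IR"}:
        raise ValueError(f"task must be 'PV' or 'IR', got {task!r}")
    pattern = pattern.upper()
    if any(ch not in _CAT for ch in pattern):
        raise ValueError("pattern may contain only 'F' and 'H'")
    if task == "PV" and not 5 <= len(pattern) <= 6:
        raise ValueError("PV patterns must describe 5-6 images")
    if len(pattern) < 2:
        raise ValueError("pattern must describe at least 2 images")
    if violation_index <= len(pattern):
        raise ValueError("violation must come after at least one full pattern")
    if violation_index < 2 * len(pattern):
        raise ValueError("violation must come after two full pattern repetitions")
    if violation_index >= n_cycles:
        raise ValueError("violation_index beyond the trial")

    cats = [_CAT[pattern[k % len(pattern)]] for k in range(n_cycles)]
    cats[violation_index] = _FLIP[cats[violation_index]]
    variants = assign_variants(cats)
    cycles = tuple(
        Cycle(cat, swift_freq, k / swift_freq, variant_id=v, swap_at=s)
        for k, (cat, (v, s)) in enumerate(zip(cats, variants))
    )
    return TrialSchedule(
        cycles=cycles,
        ssvep_freq=ssvep_freq,
        duration=n_cycles / swift_freq,
        task=task,
        target_index=violation_index,
        frame_rate=frame_rate,
    )


def build_exp2_schedule(
    f_a: float = 0.8,
    f_b: float = 1.0,
    duration: float = 31.5,
    presence: float = 0.775,
    ssvep_freq: float = 12.0,
    rng_seed: int | np.random.Generator = 0,
    task: str = "count_face",
    frame_rate: float = 120.0,
) -> TrialSchedule:
    """Build an attention-paradigm trial with two independent image streams.

    The face stream cycles at ``f_a`` and the house stream at ``f_b``
    (counterbalance by swapping the arguments).  Each stream has
    ``floor(duration * f)`` cycles, of which a fraction ``presence`` show
    the image; the rest are randomly substituted with the matching noise
    sequence, which is what makes the counting task attentionally
    demanding.
    """
    if not 0.0 <= presence <= 1.0:
        raise ValueError("presence must lie in [0, 1]")
    if task not in {"count_face", "count_house", "count_cross"}:
        raise ValueError(f"unknown task {task!r}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)

    cycles: list[Cycle] = []
    for freq, cat in ((f_a, "face"), (f_b, "house")):
        n = int(np.floor(duration * freq))
        n_image = int(np.floor(n * presence))
        noise_idx = set(rng.choice(n, size=n - n_image, replace=False).tolist())
        stream_cats = [f"noise_{cat}" if k in noise_idx else cat for k in range(n)]
        variants = assign_variants(stream_cats)
        cycles.extend(
            Cycle(c, freq, k / freq, variant_id=v, swap_at=s)
            for k, (c, (v, s)) in enumerate(zip(stream_cats, variants))
        )
    # merge the two grids; nudge exact onset ties apart so ordering is defined
    cycles.sort(key=lambda c: (c.onset, c.swift_freq))
    merged = []
    last = -np.inf
    for c in cycles:
        onset = c.onset if c.onset > last else last + 1e-9
        merged.append(replace(c, onset=onset))
        last = onset
    return TrialSchedule(
        cycles=tuple(merged),
        ssvep_freq=ssvep_freq,
        duration=duration,
        task=task,
        frame_rate=frame_rate,
    )


def build_cross_schedule(
    duration: float,
    jitter_bounds: tuple[float, float] = (0.850, 1.000),
    rng_seed: int | np.random.Generator = 0,
) -> list[CrossEvent]:
    """Events of the central-cross task, jittered to defeat frequency tagging.

    Inter-event intervals are uniform in ``jitter_bounds``; each event has
    a random height (up/down) and colour (red/green/blue); the conjunction
    targets are up+red and down+green.
    """
    lo, hi = jitter_bounds
    if lo <= 0 or hi < lo:
        raise ValueError("jitter bounds must satisfy 0 < lo <= hi")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    events: list[CrossEvent] = []
    t = 0.0
    while True:
        t += rng.uniform(lo, hi)
        if t >= duration:
            break
        events.append(
            CrossEvent(
                time=t,
                height=("up", "down")[rng.integers(2)],
                colour=("red", "green", "blue")[rng.integers(3)],
            )
        )
    return events


# ---------------------------------------------------------------------------
# Stimulus phase
# ---------------------------------------------------------------------------

def phase_reference(schedule: TrialSchedule, freq: float) -> PhaseReference:
    """The analytic phase reference for one of the schedule's frequencies."""
    if abs(freq - schedule.ssvep_freq) < 1e-9:
        return PhaseReference(freq=schedule.ssvep_freq, kind="ssvep_contrast", t_zero=0.0)
    for f in schedule.swift_freqs:
        if abs(freq - f) < 1e-9:
            stream = schedule.stream(f)
            t_peak0 = stream[0].onset + PEAK_FRACTION / f
            return PhaseReference(freq=f, kind="swift_cycle", t_zero=t_peak0)
    raise ValueError(
        f"{freq} Hz is neither the SSVEP frequency ({schedule.ssvep_freq} Hz) "
        f"nor a SWIFT frequency ({schedule.swift_freqs})"
    )


def stimulus_phase(schedule: TrialSchedule, freq: float, times) -> np.ndarray:
    """Stimulus phase (radians) of one tagged frequency at the given times.

    For the SSVEP this is the phase of the contrast cosine; for a SWIFT
    frequency it is the phase of a cosine whose maxima coincide with the
    peak-frame times.  With this convention, the phase at an epoch's start
    equals the FFT phase (referenced to the epoch start) that an entrained,
    zero-latency response would show — the property the stimulus-referenced
    coherence variant relies on.
    """
    return phase_reference(schedule, freq).phase_at(times)
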