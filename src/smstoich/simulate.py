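"""Synthetic two-channel TIRF data with known ground truth.

Emulates the acquisition used for colocalization stoichiometry: per field,
50 frames of 50 ms in the red channel (Cy5-labelled RNA, 633 nm) followed
by 250 frames in the green channel (mEGFP-labelled protein, 488 nm),
recorded continuously until the fluorophores bleach.  Emitters are
diffraction-limited 2-D Gaussian spots; each fluorophore bleaches
irreversibly with an exponential lifetime and may visit a reversible dark
state (mEGFP blinking, dwell ~1-2 s); the camera contributes Gaussian read
noise plus an optional signal-dependent (shot) term; and the green channel
is displaced from the red by a small configurable chromatic map.

True bound-protein counts per RNA are drawn from a configurable
stoichiometry distribution and thinned through the labeling/dimerization
model, so the observable green spot carries Binomial-labelled fluorophores
exactly as in the physical assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import ImageStack
from .register import ChromaticMap
from .steps import BleachTrace
from .stoichiometry import per_event_label_pmf

__all__ = ["SimulationConfig", "ComplexPopulationSpec", "TraceGroundTruth",
           "MovieGroundTruth", "simulate_trace", "simulate_movie",
           "simulate_fiducials"]


def _default_chromatic_map() -> ChromaticMap:
    # small offset plus a sub-percent magnification difference, typical of
    # a two-colour TIRF path
    return ChromaticMap(matrix=np.array([[1.002, 0.0], [0.0, 0.998]]),
                        translation=np.array([1.2, -0.8]))


@dataclass
class SimulationConfig:
    """Acquisition and photophysics parameters for synthetic data.

    Defaults reproduce the reference acquisition: 50 red frames then 250
    green frames of 50 ms each; bleach lifetimes default to one third of
    the channel's irradiation window so >95% of fluorophores bleach within
    the record; the dark state has a 1.5 s mean dwell and an entry rate
    giving roughly one excursion per trace.
    """

    image_size: tuple[int, int] = (256, 256)          # (height, width) px
    psf_sigma: float = 1.2                            # px
    frame_exposure_ms: float = 50.0
    n_frames_red: int = 50
    n_frames_green: int = 250
    unit_intensity: float = 100.0                     # green PSF peak / fluor
    red_intensity: float = 300.0                      # Cy5 PSF peak
    background_mean: float = 100.0
    background_sd: float = 10.0
    bleach_mean_lifetime_s: float | None = None       # default: green window/3
    red_bleach_lifetime_s: float | None = None        # default: red window/3
    dark_lifetime_mean_s: float = 1.5
    dark_entry_rate_per_s: float = 0.08               # per s while emitting
    shot_noise_factor: float = 1.0                    # variance per signal unit
    chromatic_map: ChromaticMap = field(default_factory=_default_chromatic_map)
    green_position_jitter_sd: float = 0.1             # px, localization jitter
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_frames_red <= 0 or self.n_frames_green <= 0:
            raise ValueError("frame counts must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.frame_exposure_ms <= 0:
            raise ValueError("frame_exposure_ms must be positive")
        if self.dark_entry_rate_per_s < 0:
            raise ValueError("dark_entry_rate_per_s must be >= 0")
        if min(self.image_size) <= 0:
            raise ValueError("image_size must be positive")
        if self.bleach_mean_lifetime_s is None:
            self.bleach_mean_lifetime_s = self.green_irradiation_s / 3.0
        if self.red_bleach_lifetime_s is None:
            self.red_bleach_lifetime_s = self.red_irradiation_s / 3.0

    @property
    def frame_dt_s(self) -> float:
        return self.frame_exposure_ms / 1000.0

    @property
    def green_irradiation_s(self) -> float:
        return self.n_frames_green * self.frame_dt_s

    @property
    def red_irradiation_s(self) -> float:
        return self.n_frames_red * self.frame_dt_s

    def rng(self, rng: np.random.Generator | None = None) -> np.random.Generator:
        if rng is not None:
            return rng
        return np.random.default_rng(self.rng_seed)


@dataclass
class ComplexPopulationSpec:
    """Population of RNA-protein complexes with known true stoichiometry.

    ``stoichiometry_weights`` maps the true bound-molecule count k to its
    population weight (must sum to 1).  ``p_label`` and ``dimer_fraction``
    parameterize the thinning from bound molecules to labelled
    fluorophores; ``free_protein_density`` adds uncolocalized green spots
    (protein stuck to the surface away from any RNA), per px^2.
    """

    n_complexes: int
    stoichiometry_weights: Mapping[int, float]
    p_label: float = 1.0
    dimer_fraction: float = 0.0
    free_protein_density: float = 0.0

    def __post_init__(self) -> None:
        if self.n_complexes < 0:
            raise ValueError("n_complexes must be >= 0")
        w = {int(k): float(v) for k, v in dict(self.stoichiometry_weights).items()}
        if any(k < 0 for k in w) or any(v < 0 for v in w.values()):
            raise ValueError("stoichiometry weights must have k >= 0, w >= 0")
        total = sum(w.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"stoichiometry weights sum to {total}, not 1")
        self.stoichiometry_weights = w
        for name in ("p_label", "dimer_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.free_protein_density < 0:
            raise ValueError("free_protein_density must be >= 0")


@dataclass
class TraceGroundTruth:
    """Truth for a single simulated trace."""

    n_fluors: int
    bleach_frames: list[int]          # frame at which each bleach step lands
    dark_intervals: list[tuple[int, int]]  # [start, stop) frames, per excursion


@dataclass
class MovieGroundTruth:
    """Truth for a simulated two-channel field.

    ``complexes`` has one row per RNA (red emitter) with its true bound
    count, labelled-fluorophore count and both channel positions;
    ``free_green`` lists uncolocalized protein spots.  Bleach-step times
    for complex i's green fluorophores are in ``green_bleach_frames[i]``.
    """

    complexes: pd.DataFrame
    free_green: pd.DataFrame
    green_bleach_frames: list[list[int]]
    free_green_bleach_frames: list[list[int]]

    def to_dict(self) -> dict:
        return {
            "complexes": self.complexes.to_dict(orient="list"),
            "free_green": self.free_green.to_dict(orient="list"),
            "green_bleach_frames": self.green_bleach_frames,
            "free_green_bleach_frames": self.free_green_bleach_frames,
        }


# ---------------------------------------------------------------------------
# single-fluorophore photophysics
# ---------------------------------------------------------------------------

def _geometric_frames(rng: np.random.Generator, p: float) -> int:
    """Number of frames survived before a per-frame-probability event."""
    if p <= 0.0:
        return np.iinfo(np.int64).max
    return int(rng.geometric(p))


def _simulate_fluor(n_frames: int, dt_s: float, bleach_lifetime_s: float,
                    dark_entry_rate_per_s: float, dark_lifetime_s: float,
                    rng: np.random.Generator
                    ) -> tuple[np.ndarray, int | None, list[tuple[int, int]]]:
    """Per-frame emitting state of one fluorophore.

    Discrete-frame two-state (emitting/dark) kinetics with an irreversible
    bleach clock that runs only while emitting.  Returns the boolean
    emitting array, the bleach frame (None if it outlives the record) and
    the dark intervals.
    """
    p_bleach = 1.0 - np.exp(-dt_s / bleach_lifetime_s)
    p_dark = 1.0 - np.exp(-dark_entry_rate_per_s * dt_s)
    p_return = 1.0 - np.exp(-dt_s / dark_lifetime_s)

    emitting = np.zeros(n_frames, dtype=bool)
    dark_intervals: list[tuple[int, int]] = []
    on_remaining = _geometric_frames(rng, p_bleach)
    frame = 0
    bleach_frame: int | None = None
    while frame < n_frames:
        on_dwell = _geometric_frames(rng, p_dark)
        dur = min(on_dwell, on_remaining, n_frames - frame)
        emitting[frame: frame + dur] = True
        frame += dur
        on_remaining -= dur
        if on_remaining == 0:
            if frame < n_frames:
                bleach_frame = frame
            break
        if frame >= n_frames:
            break
        dark_dwell = _geometric_frames(rng, p_return)
        dark_intervals.append((frame, min(frame + dark_dwell, n_frames)))
        frame += dark_dwell
    return emitting, bleach_frame, dark_intervals


def simulate_trace(n_fluors: int, config: SimulationConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[BleachTrace, TraceGroundTruth]:
    """Simulate one green-channel intensity trace with ``n_fluors`` fluorophores.

    Intensity per frame is background + unit_intensity x (currently
    emitting fluorophores) + noise; each fluorophore bleaches at most once
    and may blink reversibly.
    """
    if n_fluors < 0:
        raise ValueError("n_fluors must be >= 0")
    rng = config.rng(rng)
    n = config.n_frames_green
    counts = np.zeros(n)
    bleach_frames: list[int] = []
    dark_intervals: list[tuple[int, int]] = []
    for _ in range(n_fluors):
        emitting, bleach, dark = _simulate_fluor(
            n, config.frame_dt_s, config.bleach_mean_lifetime_s,
            config.dark_entry_rate_per_s, config.dark_lifetime_mean_s, rng)
        counts += emitting
        if bleach is not None:
            bleach_frames.append(bleach)
        dark_intervals.extend(dark)

    signal = config.unit_intensity * counts
    noise_var = config.background_sd ** 2 + config.shot_noise_factor * signal
    intensity = config.background_mean + signal
    if np.any(noise_var > 0):
        intensity = intensity + rng.standard_normal(n) * np.sqrt(noise_var)
    trace = BleachTrace(intensities=intensity,
                        exposure_ms=config.frame_exposure_ms, channel="green")
    truth = TraceGroundTruth(n_fluors=n_fluors,
                             bleach_frames=sorted(bleach_frames),
                             dark_intervals=dark_intervals)
    return trace, truth


# ---------------------------------------------------------------------------
# field rendering
# ---------------------------------------------------------------------------

def _render_stack(shape: tuple[int, int], n_frames: int,
                  spots: list[tuple[float, float, np.ndarray]],
                  psf_sigma: float, background_mean: float,
                  background_sd: float, shot_noise_factor: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Render frames from (x, y, per-frame peak amplitude) emitters."""
    h, w = shape
    frames = np.empty((n_frames, h, w), dtype=np.float32)
    if background_sd > 0:
        frames[:] = rng.standard_normal((n_frames, h, w), dtype=np.float32)
        frames *= background_sd
        frames += background_mean
    else:
        frames[:] = background_mean

    r = int(np.ceil(4 * psf_sigma))
    for x, y, amps in spots:
        ix, iy = int(round(x)), int(round(y))
        x0, x1 = max(ix - r, 0), min(ix + r + 1, w)
        y0, y1 = max(iy - r, 0), min(iy + r + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - x
        ys = np.arange(y0, y1) - y
        psf = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * psf_sigma ** 2))
        patch = amps[:, None, None].astype(np.float32) * psf[None].astype(np.float32)
        if shot_noise_factor > 0:
            patch = patch + (rng.standard_normal(patch.shape, dtype=np.float32)
                             * np.sqrt(shot_noise_factor * patch))
        frames[:, y0:y1, x0:x1] += patch
    return frames


def _draw_labeled_count(rng: np.random.Generator, p_label: float,
                        dimer_fraction: float) -> int:
    """Labelled fluorophores contributed by one binding event."""
    protomers = 2 if rng.random() < dimer_fraction else 1
    return int(rng.binomial(protomers, p_label))


def _fluor_amplitudes(n_fluors: int, n_frames: int, config: SimulationConfig,
                      rng: np.random.Generator,
                      lifetime_s: float, blinking: bool
                      ) -> tuple[np.ndarray, list[int]]:
    counts = np.zeros(n_frames)
    bleaches: list[int] = []
    for _ in range(n_fluors):
        emitting, bleach, _ = _simulate_fluor(
            n_frames, config.frame_dt_s, lifetime_s,
            config.dark_entry_rate_per_s if blinking else 0.0,
            config.dark_lifetime_mean_s, rng)
        counts += emitting
        if bleach is not None:
            bleaches.append(bleach)
    return counts, sorted(bleaches)


def simulate_movie(population: ComplexPopulationSpec, config: SimulationConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[ImageStack, ImageStack, MovieGroundTruth]:
    """Simulate one two-channel field.

    Each complex contributes one Cy5 emitter to the red channel; its green
    emitter carries the labelled fluorophores drawn through the
    monomer/dimer labeling model and sits at the chromatic image of the
    red position plus localization jitter.  Complexes with zero labelled
    molecules produce no green emitter — exactly the invisibility the
    labeling correction accounts for.
    """
    rng = config.rng(rng)
    h, w = config.image_size
    margin = 8.0
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError("image too small for the placement margin")

    # warn when crowding makes overlapping PSFs likely
    n = population.n_complexes
    area = (h - 2 * margin) * (w - 2 * margin)
    if n > 1:
        r_overlap = 4 * config.psf_sigma
        p_overlap = 1.0 - np.exp(-(n - 1) / area * np.pi * r_overlap ** 2)
        if p_overlap > 0.05:
            warnings.warn(f"expected overlap fraction {p_overlap:.2f} exceeds 5%; "
                          "detection recall will suffer", stacklevel=2)
    if n / max(area, 1.0) > 0.05:
        raise ValueError("spot density too high for placement")

    ks = sorted(population.stoichiometry_weights)
    weights = np.array([population.stoichiometry_weights[k] for k in ks])
    k_true = rng.choice(ks, size=n, p=weights) if n else np.zeros(0, int)

    xs = rng.uniform(margin, w - margin, size=n)
    ys = rng.uniform(margin, h - margin, size=n)
    red_xy = np.stack([xs, ys], axis=1) if n else np.zeros((0, 2))
    green_xy = config.chromatic_map.apply(red_xy) if n else np.zeros((0, 2))
    if config.green_position_jitter_sd > 0 and n:
        green_xy = green_xy + rng.normal(0.0, config.green_position_jitter_sd,
                                         size=green_xy.shape)

    n_labeled = np.array([
        sum(_draw_labeled_count(rng, population.p_label, population.dimer_fraction)
            for _ in range(int(k)))
        for k in k_true], dtype=int) if n else np.zeros(0, int)

    # red channel: one Cy5 per complex, no blinking
    red_spots = []
    for i in range(n):
        amps, _ = _fluor_amplitudes(1, config.n_frames_red, config, rng,
                                    config.red_bleach_lifetime_s, blinking=False)
        red_spots.append((red_xy[i, 0], red_xy[i, 1], config.red_intensity * amps))

    # green channel: labelled fluorophores per complex
    green_spots = []
    green_bleach_frames: list[list[int]] = []
    for i in range(n):
        if n_labeled[i] == 0:
            green_bleach_frames.append([])
            continue
        amps, bleaches = _fluor_amplitudes(
            int(n_labeled[i]), config.n_frames_green, config, rng,
            config.bleach_mean_lifetime_s, blinking=True)
        green_bleach_frames.append(bleaches)
        green_spots.append((green_xy[i, 0], green_xy[i, 1],
                            config.unit_intensity * amps))

    # free protein: visible spots only (>=1 labelled fluorophore)
    q = per_event_label_pmf(population.p_label, population.dimer_fraction)
    free_rows = []
    free_bleach_frames: list[list[int]] = []
    if population.free_protein_density > 0 and q[1:].sum() > 0:
        n_free = rng.poisson(population.free_protein_density * area)
        cond = q[1:] / q[1:].sum()
        for _ in range(n_free):
            m = 1 + int(rng.choice(2, p=cond))
            fx = rng.uniform(margin, w - margin)
            fy = rng.uniform(margin, h - margin)
            amps, bleaches = _fluor_amplitudes(
                m, config.n_frames_green, config, rng,
                config.bleach_mean_lifetime_s, blinking=True)
            green_spots.append((fx, fy, config.unit_intensity * amps))
            free_rows.append({"x_green": fx, "y_green": fy, "n_labeled": m})
            free_bleach_frames.append(bleaches)

    red_frames = _render_stack((h, w), config.n_frames_red, red_spots,
                               config.psf_sigma, config.background_mean,
                               config.background_sd, config.shot_noise_factor, rng)
    green_frames = _render_stack((h, w), config.n_frames_green, green_spots,
                                 config.psf_sigma, config.background_mean,
                                 config.background_sd, config.shot_noise_factor, rng)

    complexes = pd.DataFrame({
        "x_red": red_xy[:, 0], "y_red": red_xy[:, 1],
        "x_green": green_xy[:, 0], "y_green": green_xy[:, 1],
        "k_true": k_true, "n_labeled": n_labeled,
    })
    free_green = pd.DataFrame(free_rows, columns=["x_green", "y_green", "n_labeled"])
    truth = MovieGroundTruth(complexes=complexes, free_green=free_green,
                             green_bleach_frames=green_bleach_frames,
                             free_green_bleach_frames=free_bleach_frames)
    red_stack = ImageStack(frames=red_frames, exposure_ms=config.frame_exposure_ms,
                           channel="red", excitation_nm=633.0)
    green_stack = ImageStack(frames=green_frames, exposure_ms=config.frame_exposure_ms,
                             channel="green", excitation_nm=488.0)
    return red_stack, green_stack, truth


def simulate_fiducials(chromatic_map: ChromaticMap, n: int,
                       jitter_sd: float = 0.0,
                       rng: np.random.Generator | None = None,
                       image_size: tuple[int, int] = (256, 256)) -> pd.DataFrame:
    """Fiducial coordinate pairs from a dual-labelled test molecule.

    Red positions are scattered over the field; green positions are their
    chromatic images plus Gaussian localization jitter.  At least three
    non-collinear pairs are needed downstream for a full affine fit.
    """
    if n < 1:
        raise ValueError("need at least one fiducial")
    rng = rng or np.random.default_rng()
    h, w = image_size
    red = np.stack([rng.uniform(5, w - 5, size=n),
                    rng.uniform(5, h - 5, size=n)], axis=1)
    green = chromatic_map.apply(red)
    if jitter_sd > 0:
        green = green + rng.normal(0.0, jitter_sd, size=green.shape)
    return pd.DataFrame({"x_red": red[:, 0], "y_red": red[:, 1],
                         "x_green": green[:, 0], "y_green": green[:, 1]})
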