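"""Seeded generators for blendshape segments and simulated rater panels.

The generator emulates the statistical structure of a smile-annotation
study: short clips at 10 fps in which smile clips carry a smooth unimodal
activation pulse on the bilateral AU12 channels (``mouthSmile_L/R``), with
the AU6 channels (``cheekSquint_L/R``) driven by the same event but
attenuated and noisier — informative yet imperfect — while neutral clips
contain only low-amplitude noise.  A panel of independent raters is
simulated by flipping the true label of each clip with a small per-rater
probability.

Two structural guarantees matter downstream and hold by construction:

* smile and neutral amplitude ranges for ``mouthSmile`` are disjoint
  (default 0.60–0.95 vs 0.00–0.30), so the peak of either mouth channel
  separates the classes perfectly and threshold recovery must succeed;
* identical seeds give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BlendshapeSegment, DEFAULT_BLENDSHAPES, ValidationError

__all__ = [
    "SimulationConfig",
    "RaterSimConfig",
    "simulate_segments",
    "simulate_raters",
]


@dataclass
class SimulationConfig:
    """Parameters of the segment generator.

    Defaults mirror the study geometry: 158 five-second segments at 10 fps
    from 9 participants, with a smile prevalence of 0.354 (the test-half
    composition, 28/79, extrapolated to the full set).

    Attributes
    ----------
    n_segments, n_participants, fps, duration_s
        Dataset geometry; participants are assigned round-robin.
    p_smile
        Per-segment probability of the positive (smile) class.
    smile_amplitude, neutral_amplitude
        (low, high) peak ranges for the mouthSmile channels in smile and
        neutral segments.  Disjoint by default, which forces perfect
        separability of the mouthSmile peak feature.
    cheek_attenuation, cheek_noise_sd
        cheekSquint = attenuation * mouthSmile + Gaussian noise, clipped to
        [0, 1]; tuned once so a cheekSquint-only classifier is clearly
        informative but imperfect (training AUC near 0.95-0.97).
    asymmetry_prob
        Probability that a smile expresses on one side of the face only.
    jitter_sd
        Frame-level Gaussian jitter on the mouth channels.
    seed
        Seed for the generator's private RNG.
    """

    n_segments: int = 158
    p_smile: float = 0.354
    n_participants: int = 9
    fps: float = 10.0
    duration_s: float = 5.0
    smile_amplitude: tuple[float, float] = (0.60, 0.95)
    neutral_amplitude: tuple[float, float] = (0.00, 0.30)
    cheek_attenuation: float = 0.42
    cheek_noise_sd: float = 0.16
    asymmetry_prob: float = 0.2
    jitter_sd: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValidationError(f"n_segments must be >= 1, got {self.n_segments}")
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if not 0.0 <= self.p_smile <= 1.0:
            raise ValidationError(f"p_smile must be in [0, 1], got {self.p_smile}")
        if not 0.0 <= self.asymmetry_prob <= 1.0:
            raise ValidationError("asymmetry_prob must be in [0, 1]")
        for name in ("smile_amplitude", "neutral_amplitude"):
            low, high = getattr(self, name)
            if not (0.0 <= low < high <= 1.0):
                raise ValidationError(
                    f"{name} must satisfy 0 <= low < high <= 1, got ({low}, {high})"
                )
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValidationError("fps and duration_s must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class RaterSimConfig:
    """Parameters of the rater-panel simulator.

    Each of ``n_raters`` raters independently copies the true label of each
    segment, flipping it with probability ``flip_prob``.  The default flip
    probability 0.016 places the panel's chance-corrected agreement
    (Fleiss' kappa) near 0.91 at the default dataset geometry.
    """

    n_raters: int = 5
    flip_prob: float = 0.016
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_raters < 2:
            raise ValidationError(f"n_raters must be >= 2, got {self.n_raters}")
        if not 0.0 <= self.flip_prob < 0.5:
            raise ValidationError(
                f"flip_prob must be in [0, 0.5), got {self.flip_prob}"
            )


def _trapezoid_pulse(
    n_frames: int, peak: float, rng: np.random.Generator, fps: float
) -> np.ndarray:
    """Unimodal activation pulse: 0.5 s rise, >=1 s plateau, 0.5 s fall.

    Onset and plateau length are drawn uniformly within the clip; outside
    the pulse the signal is zero.
    """
    rise = max(1, int(round(0.5 * fps)))
    fall = rise
    min_plateau = max(1, int(round(1.0 * fps)))
    max_plateau = n_frames - rise - fall
    if max_plateau < min_plateau:  # very short clips: shrink the plateau
        min_plateau = max_plateau = max(1, max_plateau)
    plateau = int(rng.integers(min_plateau, max_plateau + 1))
    onset = int(rng.integers(0, n_frames - rise - plateau - fall + 1))

    signal = np.zeros(n_frames)
    up = np.linspace(0.0, peak, rise + 1)[1:]
    down = np.linspace(peak, 0.0, fall + 1)[1:]
    signal[onset : onset + rise] = up
    signal[onset + rise : onset + rise + plateau] = peak
    signal[onset + rise + plateau : onset + rise + plateau + fall] = down
    return signal


def _neutral_series(
    n_frames: int, amplitude: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Low-amplitude noise: per-clip baseline plus jitter, clipped to range."""
    low, high = amplitude
    baseline = rng.uniform(low, high)
    series = baseline + rng.normal(0.0, 0.03, size=n_frames)
    return np.clip(series, low, high)


def simulate_segments(
    config: SimulationConfig | None = None,
) -> tuple[list[BlendshapeSegment], pd.Series]:
    """Generate a labelled synthetic dataset of blendshape segments.

    Returns the segments and the ground-truth labels (segment_id -> 0/1).
    Smile segments carry a trapezoidal pulse with peak drawn from
    ``smile_amplitude`` on one or both mouthSmile channels; after jitter the
    plateau is clipped back into the smile range, so the peak feature of a
    smile segment never drops below ``smile_amplitude[0]``.  Neutral
    segments stay inside ``neutral_amplitude`` on the mouth channels.
    """
    cfg = config if config is not None else SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n_frames = cfg.n_frames
    smile_low, _ = cfg.smile_amplitude

    segments: list[BlendshapeSegment] = []
    labels: dict[str, int] = {}
    width = max(3, len(str(cfg.n_segments - 1)))
    for i in range(cfg.n_segments):
        seg_id = f"S{i:0{width}d}"
        participant = f"P{i % cfg.n_participants + 1:02d}"
        is_smile = bool(rng.random() < cfg.p_smile)
        labels[seg_id] = int(is_smile)

        mouth = {}
        if is_smile:
            pulse_sides = ["L", "R"]
            if rng.random() < cfg.asymmetry_prob:
                pulse_sides = [("L", "R")[int(rng.integers(2))]]
            # one shared event, per-side peak
            base_pulse = _trapezoid_pulse(n_frames, 1.0, rng, cfg.fps)
            plateau_mask = base_pulse >= 1.0
            for side in ("L", "R"):
                if side in pulse_sides:
                    peak = rng.uniform(*cfg.smile_amplitude)
                    series = base_pulse * peak
                    series = series + rng.normal(0.0, cfg.jitter_sd, n_frames)
                    series = np.clip(series, 0.0, 1.0)
                    # jitter must not pull the event peak out of the smile
                    # range: re-clip the plateau frames from below
                    series[plateau_mask] = np.clip(
                        series[plateau_mask], smile_low, 1.0
                    )
                else:
                    series = _neutral_series(n_frames, cfg.neutral_amplitude, rng)
                mouth[side] = series
        else:
            for side in ("L", "R"):
                mouth[side] = _neutral_series(n_frames, cfg.neutral_amplitude, rng)

        frames = pd.DataFrame(index=range(n_frames), columns=DEFAULT_BLENDSHAPES,
                              dtype=float)
        frames["mouthSmile_L"] = mouth["L"]
        frames["mouthSmile_R"] = mouth["R"]
        for side in ("L", "R"):
            cheek = (
                cfg.cheek_attenuation * mouth[side]
                + rng.normal(0.0, cfg.cheek_noise_sd, n_frames)
            )
            frames[f"cheekSquint_{side}"] = np.clip(cheek, 0.0, 1.0)

        segments.append(
            BlendshapeSegment(
                segment_id=seg_id,
                participant_id=participant,
                frames=frames,
                fps=cfg.fps,
            )
        )

    truth = pd.Series(labels, name="label").rename_axis("segment_id")
    return segments, truth


def simulate_raters(
    truth: pd.Series, config: RaterSimConfig | None = None
) -> pd.DataFrame:
    """Simulate a panel of independent binary raters.

    Each rater copies the true label of each segment and flips it with
    probability ``config.flip_prob``, independently across raters and
    segments.  Returns a DataFrame indexed by segment_id with columns
    ``rater_1 .. rater_r``.
    """
    cfg = config if config is not None else RaterSimConfig()
    if len(truth) == 0:
        raise ValidationError("truth labels are empty")
    rng = np.random.default_rng(cfg.seed)
    flips = rng.random((len(truth), cfg.n_raters)) < cfg.flip_prob
    judgments = np.abs(truth.to_numpy()[:, None] - flips.astype(np.int64))
    return pd.DataFrame(
        judgments,
        index=truth.index.copy(),
        columns=[f"rater_{j + 1}" for j in range(cfg.n_raters)],
    )
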