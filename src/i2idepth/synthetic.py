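"""Synthetic depth-action sequences and sparsity-calibrated feature matrices.

The simulator emulates what a ceiling- or wall-mounted depth sensor sees
during a short medical-action clip: a body-like ellipsoidal blob (rendered as
a depth dome, nearer than the background and smoothly receding toward its
rim) moving against a flat far background. Each action class has its own
motion law — horizontal/vertical sweeps at one or two cycles, diagonal
drifts, a circular path, an accelerating fall-like drop, and an in-place
tremor — so classes are separable by trajectory, which is exactly the signal
the HoD descriptor picks up. Additive Gaussian sensor noise and per-frame
brightness/contrast jitter model sensor read-out noise and the illumination
perturbation the depth modality is meant to be robust to; both perturb
rendered intensity, not geometry. Frames are quantised to the sensor's bit
range, so written-then-read PNGs are bit-exact.

Everything is deterministic under a seed, down to PNG bytes on disk.

``generate_sparse_features`` builds feature matrices with a prescribed
per-column zero fraction (zeros placed exactly, positions randomised);
``reference_sparsity_spec`` returns the calibration for which the threshold
schemes keep 2 / 127 / 477 of 1768 features at T = 10 / 50 / 90.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .depth_io import ActionSample, DatasetIndex, DepthFrame, write_depth_frame

__all__ = [
    "SceneConfig",
    "SparsitySpec",
    "MOTION_LAW_NAMES",
    "generate_sample",
    "generate_dataset",
    "generate_sparse_features",
    "reference_sparsity_spec",
]

MOTION_LAW_NAMES = (
    "sweep_horizontal",
    "sweep_vertical",
    "drift_diagonal",
    "circle",
    "fall",
    "sweep_horizontal_fast",
    "sweep_vertical_fast",
    "drift_antidiagonal",
    "tremor_in_place",
)


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for the simulator (defaults mirror the real sensor)."""

    width: int = 512
    height: int = 424
    bit_depth: int = 16
    n_frames: int = 20
    background_depth: float = 58000.0  # far wall, in raw counts
    body_depth: float = 50000.0  # dome apex (nearest point of the body)
    body_relief: float = 3000.0  # apex-to-rim depth rise across the dome
    radii: tuple[float, float] = (55.0, 95.0)  # ellipse semi-axes (rx, ry), px
    amplitude: tuple[float, float] = (120.0, 70.0)  # trajectory amplitude, px
    noise_sd: float = 2.0  # Gaussian sensor noise, counts
    brightness_jitter: float = 200.0  # per-frame additive offset, +- counts
    contrast_jitter: float = 0.05  # per-frame scale about the mean, +- fraction
    center_jitter: float = 10.0  # per-sample start-position jitter, px
    phase_jitter: float = 0.05  # per-sample phase jitter, cycles

    def __post_init__(self) -> None:
        if not 0 < self.body_depth < self.background_depth < 2**self.bit_depth:
            raise ValueError("need 0 < body_depth < background_depth < 2^bit_depth")


@dataclass(frozen=True)
class SparsitySpec:
    """Target zero fraction per feature column plus the nonzero value model."""

    zero_fractions: np.ndarray
    n_samples: int
    value_scale: float = 1.0

    def __post_init__(self) -> None:
        zf = np.asarray(self.zero_fractions, dtype=float)
        if zf.size and (zf.min() < 0 or zf.max() > 1):
            raise ValueError("zero fractions must lie in [0, 1]")


def _trajectory(class_id: int, scene: SceneConfig, phases: np.ndarray,
                dphase: float, jitter_xy: np.ndarray):
    """Blob centre (cx, cy) and radii (rx, ry) per frame for one motion law."""
    ax, ay = scene.amplitude
    rx0, ry0 = scene.radii
    cx0 = scene.width / 2.0 + jitter_xy[0]
    cy0 = scene.height / 2.0 + jitter_xy[1]
    u = phases + dphase
    cx = np.full_like(u, cx0)
    cy = np.full_like(u, cy0)
    rx = np.full_like(u, rx0)
    ry = np.full_like(u, ry0)
    law = MOTION_LAW_NAMES[class_id]
    if law == "sweep_horizontal":
        cx = cx0 + ax * np.sin(2 * np.pi * u)
    elif law == "sweep_vertical":
        cy = cy0 + ay * np.sin(2 * np.pi * u)
    elif law == "drift_diagonal":
        cx = cx0 + ax * (2 * u - 1)
        cy = cy0 + ay * (2 * u - 1)
    elif law == "circle":
        cx = cx0 + ax * np.cos(2 * np.pi * u)
        cy = cy0 + ay * np.sin(2 * np.pi * u)
    elif law == "fall":  # accelerating drop with a slight forward drift
        cx = cx0 + 0.3 * ax * u
        cy = cy0 - ay + 2 * ay * u**2
    elif law == "sweep_horizontal_fast":
        cx = cx0 + ax * np.sin(4 * np.pi * u)
    elif law == "sweep_vertical_fast":
        cy = cy0 + ay * np.sin(4 * np.pi * u)
    elif law == "drift_antidiagonal":
        cx = cx0 + ax * (2 * u - 1)
        cy = cy0 - ay * (2 * u - 1)
    elif law == "tremor_in_place":
        rx = rx0 * (1 + 0.3 * np.sin(4 * np.pi * u))
        ry = ry0 * (1 - 0.3 * np.sin(4 * np.pi * u))
    return cx, cy, rx, ry


def generate_sample(
    class_id: int,
    scene: SceneConfig = SceneConfig(),
    seed: int = 0,
    *,
    sample_id: str = "",
    subject_id: int = 0,
    out_dir: str | Path | None = None,
) -> ActionSample:
    """Render one action clip; deterministic under (class_id, seed).

    Raises ``ValueError`` if the configured amplitude would push the blob out
    of frame. With ``out_dir`` the frames are also written as 16-bit PNGs
    named ``f0001.png`` onward.
    """
    if not 0 <= class_id < len(MOTION_LAW_NAMES):
        raise ValueError(f"class_id must be in 0..{len(MOTION_LAW_NAMES) - 1}")
    rng = np.random.default_rng([seed, class_id])
    phases = (np.arange(scene.n_frames) / max(scene.n_frames - 1, 1)
              if scene.n_frames > 1 else np.zeros(1))
    dphase = rng.uniform(-scene.phase_jitter, scene.phase_jitter)
    jitter_xy = rng.uniform(-scene.center_jitter, scene.center_jitter, size=2)
    cx, cy, rx, ry = _trajectory(class_id, scene, phases, dphase, jitter_xy)
    if (np.any(cx - rx < 0) or np.any(cx + rx >= scene.width)
            or np.any(cy - ry < 0) or np.any(cy + ry >= scene.height)):
        raise ValueError(
            f"class {class_id}: blob leaves the {scene.width}x{scene.height} frame "
            "under the configured amplitude/radii")

    Y, X = np.mgrid[0 : scene.height, 0 : scene.width].astype(float)
    vmax = float(2**scene.bit_depth - 1)
    frames = []
    for t in range(scene.n_frames):
        r2 = ((X - cx[t]) / rx[t]) ** 2 + ((Y - cy[t]) / ry[t]) ** 2
        img = np.full((scene.height, scene.width), scene.background_depth)
        inside = r2 <= 1.0
        img[inside] = scene.body_depth + scene.body_relief * r2[inside]
        gain = 1.0 + rng.uniform(-scene.contrast_jitter, scene.contrast_jitter)
        offset = rng.uniform(-scene.brightness_jitter, scene.brightness_jitter)
        img = img.mean() + gain * (img - img.mean()) + offset
        if scene.noise_sd > 0:
            img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
        px = np.clip(np.rint(img), 0, vmax).astype(
            np.uint8 if scene.bit_depth == 8 else np.uint16)
        frames.append(DepthFrame(pixels=px, bit_depth=scene.bit_depth))
    sample = ActionSample(frames=frames, label=class_id,
                          sample_id=sample_id or f"A{class_id + 1:03d}",
                          subject_id=subject_id)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for t, frame in enumerate(frames):
            write_depth_frame(frame, out_dir / f"f{t + 1:04d}.png")
    return sample


def generate_dataset(
    n_per_class: int,
    C: int,
    scene: SceneConfig = SceneConfig(),
    seed: int = 0,
    *,
    out_dir: str | Path | None = None,
    n_performers: int = 8,
) -> DatasetIndex:
    """C * n_per_class clips with NTU-style names; performer ids cycle so
    cross-subject splits are possible. With ``out_dir``, one PNG directory per
    sample plus a ``manifest.json`` are written."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    samples = []
    for c in range(C):
        for i in range(n_per_class):
            performer = i % n_performers + 1
            name = f"S001C001P{performer:03d}R{i // n_performers + 1:03d}A{c + 1:03d}"
            samples.append(generate_sample(
                c, scene, seed=seed * 100003 + c * 1009 + i,
                sample_id=name, subject_id=performer,
                out_dir=None if out_dir is None else Path(out_dir) / name,
            ))
    index = DatasetIndex(samples=samples,
                         class_names=[MOTION_LAW_NAMES[c] for c in range(C)])
    if out_dir is not None:
        index.save_manifest(Path(out_dir) / "manifest.json")
    return index


def generate_sparse_features(spec: SparsitySpec, seed: int = 0) -> np.ndarray:
    """(n_samples, n_features) matrix whose column j is zero in exactly
    round(zero_fractions[j] * n) rows (random positions); nonzeros are
    half-normal with scale ``value_scale``, mimicking non-negative histogram
    mass."""
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    zf = np.asarray(spec.zero_fractions, dtype=float)
    x = np.abs(rng.standard_normal((n, zf.size))) * spec.value_scale + 1e-6
    for j, f in enumerate(zf):
        k = int(round(f * n))
        if k:
            x[rng.choice(n, size=k, replace=False), j] = 0.0
    return x


def reference_sparsity_spec(n_samples: int = 200) -> SparsitySpec:
    """Calibration whose scheme table keeps 2 / 127 / 477 of 1768 features at
    thresholds 10 / 50 / 90 (and all 1768 at 100)."""
    zf = np.concatenate([
        np.full(2, 0.05),      # dense: survive T=10
        np.full(125, 0.30),    # survive T=50
        np.full(350, 0.70),    # survive T=90
        np.full(1291, 0.95),   # only T >= 95 keeps these
    ])
    return SparsitySpec(zero_fractions=zf, n_samples=n_samples)
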