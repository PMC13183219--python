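"""Reading, validation and persistence of depth-frame sequences and feature matrices.

Depth frames are single-channel 8- or 16-bit PNG images whose pixel values are
raw sensor depth counts; a Kinect-v2 style sensor produces 512x424 frames. An
action sample is an ordered directory of such frames plus a class label. No
scaling or re-quantisation happens at read time: downstream feature code decides
how to normalise.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "DepthFrame",
    "ActionSample",
    "DatasetIndex",
    "FormatError",
    "read_depth_frame",
    "write_depth_frame",
    "load_action_sample",
    "parse_sample_name",
    "save_features",
    "load_features",
]

#: NTU RGB+D style sample name: setup, camera, performer, replication, action.
DEFAULT_NAME_PATTERN = r"S(\d{3})C(\d{3})P(\d{3})R(\d{3})A(\d{3})"


class FormatError(ValueError):
    """Raised when an input file violates the expected depth-frame format."""


@dataclass(frozen=True)
class DepthFrame:
    """One depth image: raw integer counts plus recorded geometry and bit depth."""

    pixels: np.ndarray  # (height, width) non-negative ints
    bit_depth: int  # 8 or 16
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError(f"depth frame must be a 2-D image, got shape {px.shape}")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit depth must be 8 or 16, got {self.bit_depth}")
        if px.size and (px.min() < 0 or px.max() >= 2**self.bit_depth):
            raise FormatError(
                f"pixel values must lie in [0, 2^{self.bit_depth}), "
                f"got range [{px.min()}, {px.max()}]"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ActionSample:
    """An ordered depth-frame sequence with a class label."""

    frames: list[DepthFrame]
    label: int
    sample_id: str = ""
    subject_id: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError(f"action sample {self.sample_id!r} has no frames")
        shapes = {(f.height, f.width, f.bit_depth) for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(
                f"sample {self.sample_id!r}: frames disagree on geometry/bit depth: "
                f"{sorted(shapes)}"
            )

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class DatasetIndex:
    """A labelled collection of action samples with per-class bookkeeping."""

    samples: list[ActionSample]
    class_names: list[str]

    def __post_init__(self) -> None:
        c = len(self.class_names)
        bad = [s.sample_id for s in self.samples if not 0 <= s.label < c]
        if bad:
            raise ValueError(f"samples with label outside 0..{c - 1}: {bad}")

    @property
    def counts(self) -> list[int]:
        out = [0] * len(self.class_names)
        for s in self.samples:
            out[s.label] += 1
        return out

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    def manifest(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "counts": self.counts,
            "samples": [
                {"sample_id": s.sample_id, "label": s.label, "subject_id": s.subject_id,
                 "n_frames": len(s)}
                for s in self.samples
            ],
        }

    def save_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=1, sort_keys=True))


def read_depth_frame(path: str | Path) -> DepthFrame:
    """Read a single-channel PNG as a :class:`DepthFrame`, without rescaling.

    Raises ``FileNotFoundError`` for a missing file and :class:`FormatError`
    for multi-channel or non-integer images, naming the offending property.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected single-channel image, got {arr.ndim}-D data "
            f"with shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise FormatError(f"{path}: unsupported pixel dtype {arr.dtype} (need uint8/uint16)")
    return DepthFrame(pixels=arr, bit_depth=bit_depth, source_path=str(path))


def write_depth_frame(frame: DepthFrame, path: str | Path) -> None:
    """Write a frame as an 8- or 16-bit single-channel PNG (lossless)."""
    dtype = np.uint8 if frame.bit_depth == 8 else np.uint16
    iio.imwrite(Path(path), frame.pixels.astype(dtype), extension=".png")


def load_action_sample(
    directory: str | Path,
    label: int,
    *,
    sample_id: str | None = None,
    subject_id: int = 0,
) -> ActionSample:
    """Load a sample directory; frames ordered by lexicographic filename.

    Dimension or bit-depth mismatches across frames raise ``ValueError``
    listing the offending files.
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".png")
    if not paths:
        raise ValueError(f"{directory}: no PNG frames found")
    frames = [read_depth_frame(p) for p in paths]
    ref = (frames[0].height, frames[0].width, frames[0].bit_depth)
    bad = [str(p) for p, f in zip(paths, frames)
           if (f.height, f.width, f.bit_depth) != ref]
    if bad:
        raise ValueError(
            f"{directory}: frames disagree with {paths[0].name} "
            f"(h,w,bits)={ref}: {bad}"
        )
    return ActionSample(
        frames=frames,
        label=label,
        sample_id=sample_id if sample_id is not None else directory.name,
        subject_id=subject_id,
    )


def parse_sample_name(
    name: str, pattern: str = DEFAULT_NAME_PATTERN
) -> tuple[int, int, int, int, int]:
    """Parse an NTU-style sample name into (setup, camera, performer, replication, action).

    The pattern is configurable; unmatched names raise ``ValueError`` showing
    the expected pattern rather than guessing.
    """
    m = re.fullmatch(pattern, name)
    if m is None:
        raise ValueError(f"sample name {name!r} does not match pattern {pattern!r}")
    return tuple(int(g) for g in m.groups())  # type: ignore[return-value]


def save_features(
    matrix: np.ndarray,
    labels: Sequence[int],
    path: str | Path,
    sample_ids: Sequence[str] | None = None,
) -> None:
    """Persist a (n_samples, n_features) matrix as headered CSV.

    Columns: sample_id, label, f0001..fNNNN. Values are written with 17
    significant digits so a text round-trip reproduces float64 exactly.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.size == 0:
        raise ValueError(f"feature matrix must be non-empty 2-D, got shape {matrix.shape}")
    if len(labels) != matrix.shape[0]:
        raise ValueError(f"{len(labels)} labels for {matrix.shape[0]} rows")
    if sample_ids is None:
        sample_ids = [f"sample{i:05d}" for i in range(matrix.shape[0])]
    width = max(4, len(str(matrix.shape[1])))
    cols = [f"f{j + 1:0{width}d}" for j in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, columns=cols)
    df.insert(0, "label", list(labels))
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, index=False, float_format="%.17g")


def load_features(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Inverse of :func:`save_features`: returns (matrix, labels, sample_ids)."""
    df = pd.read_csv(path)
    expected = {"sample_id", "label"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: missing header columns {expected - set(df.columns)}")
    feat_cols = [c for c in df.columns if c not in expected]
    matrix = df[feat_cols].to_numpy(dtype=float)
    return matrix, df["label"].to_numpy(dtype=int), df["sample_id"].astype(str).tolist()
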