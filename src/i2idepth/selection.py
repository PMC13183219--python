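"""Zero-sparsity threshold feature selection ("Schematic Threshold Configuration").

HoD descriptors of depth data are dominated by zeros: a cell-bin is exactly
zero whenever no gradient in that cell points into that bin, which for static
backgrounds is most of the image. The selection rule keeps feature j under
scheme I2I@T iff the fraction of samples in which feature j is zero does not
exceed T percent; I2I@100 therefore keeps every feature, and kept sets are
nested as T grows.

The zero test is exact equality by default (empty cells produce exact zeros);
``tol`` widens it to |x| <= tol for pipelines whose sensor noise leaves a
small nonzero floor in empty cells.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SparsityProfile",
    "ThresholdScheme",
    "SelectionMask",
    "zero_fraction_profile",
    "select",
    "apply_mask",
    "scheme_table",
    "save_mask",
    "load_mask",
]


@dataclass(frozen=True)
class SparsityProfile:
    """Per-feature fraction of samples (rows) where the feature is zero."""

    zero_fraction: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        zf = np.asarray(self.zero_fraction, dtype=float)
        if zf.ndim != 1:
            raise ValueError("zero_fraction must be 1-D")
        if zf.size and (zf.min() < 0 or zf.max() > 1):
            raise ValueError("zero fractions must lie in [0, 1]")

    @property
    def n_features(self) -> int:
        return self.zero_fraction.size


@dataclass(frozen=True)
class ThresholdScheme:
    """A percent threshold T; scheme I2I@T keeps features with <= T% zeros."""

    T: int

    def __post_init__(self) -> None:
        if not 1 <= self.T <= 100:
            raise ValueError(f"threshold must be in 1..100, got {self.T}")

    @property
    def name(self) -> str:
        return f"I2I@{self.T}"


@dataclass(frozen=True)
class SelectionMask:
    kept_indices: np.ndarray  # sorted, strictly increasing
    T: int
    n_original: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.kept_indices, dtype=int)
        if idx.size and (np.any(np.diff(idx) <= 0) or idx[0] < 0 or idx[-1] >= self.n_original):
            raise ValueError("kept_indices must be strictly increasing and < n_original")

    @property
    def n_kept(self) -> int:
        return self.kept_indices.size


def zero_fraction_profile(features: np.ndarray, tol: float = 0.0) -> SparsityProfile:
    """Fraction of rows where each column is zero (|x| <= tol)."""
    x = np.asarray(features)
    if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 1:
        raise ValueError(f"need a non-empty 2-D matrix, got shape {x.shape}")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    frac = (np.abs(x) <= tol).mean(axis=0)
    return SparsityProfile(zero_fraction=frac, n_samples=x.shape[0])


def select(profile: SparsityProfile, scheme: ThresholdScheme | int) -> SelectionMask:
    """Keep features with zero_fraction <= T/100 (boundary inclusive, so
    I2I@100 keeps all features). An empty selection is legal but warned about."""
    if isinstance(scheme, int):
        scheme = ThresholdScheme(scheme)
    kept = np.flatnonzero(profile.zero_fraction <= scheme.T / 100.0)
    if kept.size == 0:
        warnings.warn(f"{scheme.name}: no features survive the threshold", stacklevel=2)
    return SelectionMask(kept_indices=kept, T=scheme.T, n_original=profile.n_features)


def apply_mask(features: np.ndarray, mask: SelectionMask) -> np.ndarray:
    """Column subset in kept order; row order preserved."""
    x = np.asarray(features)
    if x.shape[-1] != mask.n_original:
        raise ValueError(
            f"matrix has {x.shape[-1]} features but mask was fitted on {mask.n_original}"
        )
    return x[..., mask.kept_indices]


def scheme_table(
    profile: SparsityProfile, T_list: list[int] = list(range(10, 101, 10))
) -> list[tuple[str, int]]:
    """(scheme name, kept count) per threshold; counts are non-decreasing in T."""
    return [(ThresholdScheme(T).name, select(profile, T).n_kept) for T in sorted(T_list)]


def save_mask(mask: SelectionMask, path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {"T": mask.T, "n_original": mask.n_original,
         "kept_indices": mask.kept_indices.tolist()},
        sort_keys=True,
    ))


def load_mask(path: str | Path) -> SelectionMask:
    d = json.loads(Path(path).read_text())
    return SelectionMask(
        kept_indices=np.asarray(d["kept_indices"], dtype=int),
        T=d["T"], n_original=d["n_original"],
    )
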