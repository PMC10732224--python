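"""Input representations for the neural classifiers and localisers.

Each conformation maps to one of the geometric representations the
classifiers are compared on:

* ``xyz`` — centre-of-mass-corrected Cartesian coordinates (3 input
  neurons per bead);
* ``sta_signed`` / ``sta_unsigned`` — windowed segment-to-all writhe
  profile (1 neuron per bead), signed by chirality or not;
* ``sts`` — the full N x N segment-to-segment writhe map, window-
  smoothed along both contour indices;
* ``curvature`` / ``density`` — per-bead baseline features.

Standardization (z-score per input dimension) is fitted on the training
split only and applied to all splits.  Rigid rotations change ``xyz``
but leave all writhe-derived features invariant, which is the point of
the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformation import RingConformation
from .writhe import (local_curvature_profile, local_density_profile,
                     smooth_map, sta_writhe, sts_writhe)

__all__ = ["FeatureTensor", "featurize", "split_dataset", "Standardizer",
           "FEATURE_KINDS"]

FEATURE_KINDS = ("xyz", "sta_signed", "sta_unsigned", "sts", "curvature",
                 "density")


@dataclass
class FeatureTensor:
    """Per-conformation feature array with its normalization metadata."""

    kind: str
    values: np.ndarray  # (n_samples, ...) float32
    window_length: float
    standardized: bool = False
    norm_mean: np.ndarray | None = field(default=None, repr=False)
    norm_std: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def input_dim(self) -> int:
        return int(np.prod(self.values.shape[1:]))

    def flat(self) -> np.ndarray:
        return self.values.reshape(self.n_samples, -1)


def _one(conf: RingConformation, kind: str, window: float) -> np.ndarray:
    if kind == "xyz":
        return (conf.positions - conf.positions.mean(axis=0)).astype(np.float32)
    if kind == "sta_signed":
        return sta_writhe(conf, window=window, signed=True).values.astype(np.float32)
    if kind == "sta_unsigned":
        return sta_writhe(conf, window=window, signed=False).values.astype(np.float32)
    if kind == "sts":
        raw = sts_writhe(conf, window=window).values
        w_beads = max(int(round(window / conf.bead_spacing_target)), 1)
        return smooth_map(raw, w_beads, periodic=conf.closed).astype(np.float32)
    if kind == "curvature":
        return local_curvature_profile(conf).astype(np.float32)
    if kind == "density":
        return local_density_profile(conf).astype(np.float32)
    raise ValueError(f"unknown feature kind {kind!r}; choose from {FEATURE_KINDS}")


def featurize(conformations, kind: str, window: float = 10.0) -> FeatureTensor:
    """Deterministic mapping from conformations to a raw feature tensor.

    All conformations must share the same bead count.  Standardization
    is a separate, split-aware step (:class:`Standardizer`).
    """
    confs = list(conformations)
    if not confs:
        raise ValueError("no conformations")
    n = confs[0].n_beads
    if any(c.n_beads != n for c in confs):
        raise ValueError("mixed bead counts in one feature tensor")
    values = np.stack([_one(c, kind, window) for c in confs])
    return FeatureTensor(kind, values, window)


@dataclass
class Standardizer:
    """Z-score normalization with statistics from the training split only."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, tensor: FeatureTensor, train_idx: np.ndarray) -> "Standardizer":
        flat = tensor.flat()[train_idx]
        mean = flat.mean(axis=0)
        std = flat.std(axis=0)
        std[std < 1e-8] = 1.0
        return cls(mean, std)

    def apply(self, tensor: FeatureTensor) -> FeatureTensor:
        flat = (tensor.flat() - self.mean) / self.std
        return FeatureTensor(tensor.kind, flat.reshape(tensor.values.shape),
                             tensor.window_length, standardized=True,
                             norm_mean=self.mean, norm_std=self.std)


def split_dataset(labels, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Stratified train/validation/test index split.

    Per-class proportions are preserved to within one item; the three
    partitions are disjoint and cover everything.
    """
    labels = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        train.extend(idx[:n_train])
        val.extend(idx[n_train:n_train + n_val])
        test.extend(idx[n_train + n_val:])
    return (np.sort(np.array(train, dtype=int)),
            np.sort(np.array(val, dtype=int)),
            np.sort(np.array(test, dtype=int)))
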