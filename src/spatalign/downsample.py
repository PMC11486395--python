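"""Display downsampling that preserves the annotation distribution.

With annotations, each cluster i of size C_i out of T observations
contributes a quota D_i = F_i × N with F_i = C_i/T, rounded by the
largest-remainder method so that Σ D_i = N exactly.  Without
annotations a plain uniform sample is drawn.  Downsampling governs
display only — export always replays every original observation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .model import PointSet

DEFAULT_DISPLAY_N = 10_000


@dataclass(frozen=True)
class ClusterQuota:
    label: object
    size: int       # C_i
    fraction: float  # F_i = C_i / T
    quota: int      # D_i after rounding


@dataclass(frozen=True)
class DownsampleSpec:
    total: int      # T
    target: int     # N
    per_cluster: tuple[ClusterQuota, ...]
    seed: int

    def __post_init__(self) -> None:
        if sum(c.size for c in self.per_cluster) != self.total:
            raise ValidationError("cluster sizes must sum to the total")
        if sum(c.quota for c in self.per_cluster) != self.target:
            raise ValidationError("quotas must sum to the target")
        for c in self.per_cluster:
            if not 0 <= c.quota <= c.size:
                raise ValidationError("each quota must satisfy 0 ≤ D_i ≤ C_i")


def largest_remainder(sizes: np.ndarray, target: int) -> np.ndarray:
    """Integer quotas proportional to ``sizes`` summing to ``target``.

    Floors F_i×N then hands the remaining units to the largest
    fractional remainders (ties broken by cluster order, so the result
    is deterministic).  Guarantees |D_i − F_i·N| < 1.
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    total = int(sizes.sum())
    exact = sizes * target / total
    quotas = np.floor(exact).astype(np.int64)
    short = target - int(quotas.sum())
    if short > 0:
        remainders = exact - quotas
        order = np.lexsort((np.arange(len(sizes)), -remainders))
        quotas[order[:short]] += 1
    return quotas


def _check_target(n_total: int, target: int) -> None:
    if target <= 0:
        raise ValidationError("target must be positive")
    if target > n_total:
        raise ValidationError(
            f"target {target} exceeds the {n_total} available observations")


def stratified_downsample(points: PointSet, target: int,
                          seed: int) -> tuple[np.ndarray, DownsampleSpec]:
    """Per-cluster uniform sample honouring largest-remainder quotas.

    Returns the sorted indices of the displayed observations and the
    :class:`DownsampleSpec` documenting T, C_i, F_i, D_i and the seed.
    """
    if points.annotation is None:
        raise ValidationError("stratified downsampling needs an annotation; "
                              "use random_downsample instead")
    _check_target(points.n, target)
    labels, inverse = np.unique(points.annotation, return_inverse=True)
    sizes = np.bincount(inverse, minlength=len(labels))
    quotas = largest_remainder(sizes, target)
    rng = np.random.default_rng(seed)
    chosen = []
    for k in range(len(labels)):
        members = np.flatnonzero(inverse == k)
        chosen.append(rng.choice(members, size=int(quotas[k]), replace=False))
    indices = np.sort(np.concatenate(chosen))
    spec = DownsampleSpec(
        total=points.n, target=target, seed=seed,
        per_cluster=tuple(
            ClusterQuota(label=labels[k], size=int(sizes[k]),
                         fraction=float(sizes[k]) / points.n,
                         quota=int(quotas[k]))
            for k in range(len(labels))),
    )
    return indices, spec


def random_downsample(points: PointSet, target: int, seed: int) -> np.ndarray:
    """Uniform sample without replacement (no-annotation fallback)."""
    _check_target(points.n, target)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(points.n, size=target, replace=False))


def downsample(points: PointSet, target: int, seed: int) -> np.ndarray:
    """Stratified when an annotation exists, random otherwise."""
    if points.annotation is not None:
        indices, _ = stratified_downsample(points, target, seed)
        return indices
    return random_downsample(points, target, seed)
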