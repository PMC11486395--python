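"""Registration-quality metrics.

Two complementary checks of a finished registration between serial
sections and a histology image:

* **binned spatial correlation** — raw counts are summed per gene over
  100×100 μm bins; the Spearman correlation between matched (same grid
  cell) or randomly paired bins of two sections is computed per gene.
  Well-registered serial sections show matched ρ well above the
  random-pairing null.
* **tissue overlap** — the fraction of data points whose display
  coordinates fall on tissue pixels of a thresholded histology mask.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import spearmanr
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import InsufficientDataError, ValidationError
from .model import ImageRaster, PointSet

DEFAULT_BIN_SIZE = 100.0  # μm


class DegenerateMaskWarning(UserWarning):
    """The image has a single intensity; the tissue mask is empty."""


# ---------------------------------------------------------------------
# count filtering
# ---------------------------------------------------------------------

def filter_counts(points: PointSet, min_umi: int = 50,
                  min_beads: int = 5) -> PointSet:
    """Strict bead/gene count filter.

    Keeps beads with total UMI **strictly greater** than ``min_umi``
    (a bead with exactly ``min_umi`` is removed), then genes detected
    in strictly more than ``min_beads`` of the retained beads.
    """
    if points.counts is None:
        raise ValidationError("filter_counts needs a count matrix")
    totals = points.counts.sum(axis=0).to_numpy()
    keep_beads = np.flatnonzero(totals > min_umi)
    if len(keep_beads) == 0:
        raise ValidationError("no beads survive the UMI filter")
    out = points.subset(keep_beads)
    detected = (out.counts > 0).sum(axis=1).to_numpy()
    out.counts = out.counts.loc[detected > min_beads]
    return out


# ---------------------------------------------------------------------
# spatial binning
# ---------------------------------------------------------------------

@dataclass
class BinnedExpression:
    """Per-gene raw-count sums over a fixed square grid.

    ``counts`` is genes × occupied bins; columns are (i, j) bin indices
    with i = floor((x−x₀)/bin_size), half-open on the upper edge so a
    point exactly on an edge belongs to the higher-index bin.
    """

    counts: pd.DataFrame
    bin_size: float
    origin: tuple[float, float]

    @property
    def bins(self) -> list[tuple[int, int]]:
        return list(self.counts.columns)


def common_origin(*point_sets: PointSet) -> tuple[float, float]:
    """Component-wise minimum over all sections, so grids coincide."""
    return (min(float(p.x.min()) for p in point_sets),
            min(float(p.y.min()) for p in point_sets))


def bin_counts(points: PointSet, bin_size: float = DEFAULT_BIN_SIZE,
               origin: tuple[float, float] | None = None) -> BinnedExpression:
    """Sum raw counts per gene within each occupied bin.

    Coordinates are display units; ``bin_size`` is in the same units
    (μm when the display scale is 1 μm/px).  Empty bins are absent.
    """
    if points.counts is None:
        raise ValidationError("bin_counts needs a count matrix")
    if not bin_size > 0:
        raise ValidationError("bin_size must be > 0")
    if origin is None:
        origin = (float(points.x.min()), float(points.y.min()))
    i = np.floor((points.x - origin[0]) / bin_size).astype(np.int64)
    j = np.floor((points.y - origin[1]) / bin_size).astype(np.int64)
    keys = pd.MultiIndex.from_arrays([i, j], names=["i", "j"])
    sums = points.counts.T.groupby(keys).sum().T
    sums = sums[sorted(sums.columns)]
    return BinnedExpression(counts=sums, bin_size=bin_size, origin=origin)


# ---------------------------------------------------------------------
# per-gene Spearman between sections
# ---------------------------------------------------------------------

def per_gene_spearman(a: BinnedExpression, b: BinnedExpression,
                      pairing: str = "matched",
                      seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Spearman ρ per gene over matched or randomly paired bins.

    The bin universe is the intersection of bins occupied in both
    sections.  ``matched`` aligns identical (i, j) indices; ``random``
    pairs a's bins with a seeded uniform permutation of b's.  Genes
    with zero variance in either vector are reported with ρ = NaN and
    excluded from the median/mean summary.
    """
    if a.bin_size != b.bin_size or a.origin != b.origin:
        raise ValidationError("sections must be binned on the same grid")
    common = [c for c in a.counts.columns if c in set(b.counts.columns)]
    if len(common) < 3:
        raise InsufficientDataError(
            f"only {len(common)} common bins; at least 3 required")
    genes = a.counts.index.intersection(b.counts.index)
    av = a.counts.loc[genes, common].to_numpy(dtype=float)
    bv = b.counts.loc[genes, common].to_numpy(dtype=float)
    if pairing == "random":
        rng = np.random.default_rng(seed)
        bv = bv[:, rng.permutation(len(common))]
    elif pairing != "matched":
        raise ValidationError(f"unknown pairing {pairing!r}")
    rho = np.full(len(genes), np.nan)
    for g in range(len(genes)):
        if av[g].std() == 0 or bv[g].std() == 0:
            continue  # constant gene: undefined, excluded from summary
        rho[g] = spearmanr(av[g], bv[g]).statistic
    table = pd.DataFrame({"gene": genes, "rho": rho,
                          "defined": ~np.isnan(rho)})
    defined = rho[~np.isnan(rho)]
    summary = {
        "n_genes": int(len(genes)),
        "n_defined": int(len(defined)),
        "n_bins": int(len(common)),
        "pairing": pairing,
        "median_rho": float(np.median(defined)) if len(defined) else float("nan"),
        "mean_rho": float(np.mean(defined)) if len(defined) else float("nan"),
    }
    return table, summary


# ---------------------------------------------------------------------
# tissue mask and overlap
# ---------------------------------------------------------------------

@dataclass
class TissueMask:
    """Binary tissue raster aligned to the registered image grid."""

    mask: np.ndarray  # bool, (height, width)
    pixel_size: float
    threshold: float

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]


def tissue_mask(image: ImageRaster, dark_tissue: bool = True) -> TissueMask:
    """Segment tissue from background by global Otsu threshold.

    Tissue is taken as the darker side of the threshold (typical for
    H&E on a bright-field background); pass ``dark_tissue=False`` for
    inverted-polarity images.  The largest connected component is kept
    and its holes are filled.
    """
    gray = image.grayscale()
    if gray.max() == gray.min():
        warnings.warn("image has a single intensity; mask is empty",
                      DegenerateMaskWarning)
        return TissueMask(mask=np.zeros(gray.shape, dtype=bool),
                          pixel_size=image.pixel_size, threshold=float("nan"))
    thr = threshold_otsu(gray)
    raw = gray < thr if dark_tissue else gray > thr
    if raw.any():
        labels = cc_label(raw)
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        raw = ndimage.binary_fill_holes(labels == largest)
    return TissueMask(mask=raw, pixel_size=image.pixel_size,
                      threshold=float(thr))


def overlap_percent(points: PointSet,
                    mask: TissueMask) -> tuple[float, np.ndarray]:
    """Percent of points landing on tissue pixels, plus the outsiders.

    A point (x, y) in display units maps to pixel column floor(x) and
    row height−1−floor(y) (y-up frame, row 0 at the top).  Points
    outside the image bounds count as non-overlapping.
    """
    col = np.floor(points.x).astype(np.int64)
    row = mask.height - 1 - np.floor(points.y).astype(np.int64)
    inside = (col >= 0) & (col < mask.width) & (row >= 0) & (row < mask.height)
    on_tissue = np.zeros(points.n, dtype=bool)
    on_tissue[inside] = mask.mask[row[inside], col[inside]]
    percent = 100.0 * on_tissue.sum() / points.n
    return float(percent), points.ids[~on_tissue]
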