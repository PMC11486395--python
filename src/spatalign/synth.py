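"""Synthetic spatio-molecular fixtures.

Generates everything the engine consumes — clustered point clouds with
Poisson gene counts, elliptical "tissue" images, and ground-truth
transformed serial sections — fully seeded, so every module is testable
without any external download.

The model is deliberately minimal: cluster labels come from spatially
coherent Gaussian blobs inside an elliptical tissue region; per-gene
Poisson rates are log-linear in the cluster identity and a smooth
spatial gradient, which is exactly the spatial autocorrelation the
matched-vs-random bin correlation metric needs.  No attempt is made to
emulate real imaging optics or bead chemistry.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import ImageRaster, PointSet


@dataclass(frozen=True)
class RigidMap:
    """Ground-truth rigid map: rotate about ``center`` then translate."""

    theta_deg: float
    tx: float
    ty: float
    center: tuple[float, float]

    def apply(self, x: np.ndarray, y: np.ndarray):
        th = np.radians(self.theta_deg)
        c, s = np.cos(th), np.sin(th)
        dx, dy = x - self.center[0], y - self.center[1]
        return (dx * c - dy * s + self.center[0] + self.tx,
                dx * s + dy * c + self.center[1] + self.ty)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic section.

    Distances are μm; the rendered image uses ``pixel_size`` μm/px.
    Defaults give a 400×400 μm section with ~600 points in 4 clusters
    and 30 genes — small enough for fast tests, structured enough for
    the correlation metric to have signal.
    """

    n_points: int = 600
    n_clusters: int = 4
    n_genes: int = 30
    image_shape: tuple[int, int] = (400, 400)  # (height, width) px
    pixel_size: float = 1.0
    ellipse_center: tuple[float, float] | None = None
    ellipse_axes: tuple[float, float] | None = None
    cluster_weights: tuple[float, ...] | None = None
    base_rate: float = 1.0
    cluster_effect_sd: float = 1.0
    gradient_strength: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_points, self.n_clusters, self.n_genes) <= 0:
            raise ValidationError("all counts must be positive")
        if min(self.image_shape) <= 0 or self.pixel_size <= 0:
            raise ValidationError("degenerate image geometry")
        if self.ellipse_axes is not None and min(self.ellipse_axes) <= 0:
            raise ValidationError("degenerate ellipse geometry")

    @property
    def geometry(self) -> tuple[tuple[float, float], tuple[float, float]]:
        h, w = self.image_shape
        center = self.ellipse_center or (w * self.pixel_size / 2,
                                         h * self.pixel_size / 2)
        axes = self.ellipse_axes or (0.42 * w * self.pixel_size,
                                     0.34 * h * self.pixel_size)
        return center, axes

    @property
    def weights(self) -> np.ndarray:
        if self.cluster_weights is not None:
            if len(self.cluster_weights) != self.n_clusters:
                raise ValidationError("one weight per cluster required")
            w = np.asarray(self.cluster_weights, dtype=float)
        else:
            w = np.ones(self.n_clusters)
        return w / w.sum()


def _inside(x, y, center, axes, margin: float = 1.0):
    return (((x - center[0]) / (axes[0] * margin)) ** 2
            + ((y - center[1]) / (axes[1] * margin)) ** 2) <= 1.0


@dataclass
class _SectionInternals:
    """Per-point Poisson rates kept for serial-pair resampling."""

    rates: np.ndarray  # genes × points
    clusters: np.ndarray


def _sample_points(spec: FixtureSpec, rng: np.random.Generator):
    center, axes = spec.geometry
    # cluster centers inside a shrunken ellipse keep blobs in-tissue
    ccx = np.empty(spec.n_clusters)
    ccy = np.empty(spec.n_clusters)
    for k in range(spec.n_clusters):
        while True:
            cx = center[0] + (rng.uniform(-1, 1)) * axes[0] * 0.6
            cy = center[1] + (rng.uniform(-1, 1)) * axes[1] * 0.6
            if _inside(cx, cy, center, axes, margin=0.65):
                ccx[k], ccy[k] = cx, cy
                break
    labels = rng.choice(spec.n_clusters, size=spec.n_points, p=spec.weights)
    sd = 0.25 * min(axes)
    x = np.empty(spec.n_points)
    y = np.empty(spec.n_points)
    for i, k in enumerate(labels):
        while True:
            px = ccx[k] + rng.normal(0, sd)
            py = ccy[k] + rng.normal(0, sd)
            # 0.93 margin keeps points clear of the rendered tissue edge
            if _inside(px, py, center, axes, margin=0.93):
                x[i], y[i] = px, py
                break
    return x, y, labels


def _gene_rates(spec: FixtureSpec, x, y, labels,
                rng: np.random.Generator) -> np.ndarray:
    center, axes = spec.geometry
    xn = (x - center[0]) / axes[0]
    yn = (y - center[1]) / axes[1]
    loadings = rng.normal(0, spec.cluster_effect_sd,
                          size=(spec.n_genes, spec.n_clusters))
    grad = rng.normal(0, spec.gradient_strength, size=(spec.n_genes, 2))
    log_rate = (np.log(spec.base_rate)
                + loadings[:, labels]
                + grad[:, :1] * xn[None, :]
                + grad[:, 1:2] * yn[None, :])
    return np.exp(np.clip(log_rate, -10, 4))


def _render_image(spec: FixtureSpec, rng: np.random.Generator) -> ImageRaster:
    h, w = spec.image_shape
    center, axes = spec.geometry
    # pixel (r, c) center in the y-up physical frame
    cols = (np.arange(w) + 0.5) * spec.pixel_size
    rows = (h - 1 - np.arange(h) + 0.5) * spec.pixel_size
    xx, yy = np.meshgrid(cols, rows)
    tissue = _inside(xx, yy, center, axes)
    img = np.where(tissue, 90.0, 250.0)
    img = img + rng.normal(0, 3.0, size=img.shape)
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return ImageRaster(pixels=pixels, pixel_size=spec.pixel_size,
                       name="synthetic_tissue")


def make_section(spec: FixtureSpec) -> tuple[PointSet, ImageRaster]:
    """One synthetic section: annotated points with counts + image."""
    points, image, _ = _make_section_with_rates(spec)
    return points, image


def _make_section_with_rates(spec: FixtureSpec):
    rng = np.random.default_rng(spec.seed)
    x, y, labels = _sample_points(spec, rng)
    rates = _gene_rates(spec, x, y, labels, rng)
    counts_arr = rng.poisson(rates)
    ids = np.arange(spec.n_points)
    genes = np.array([f"gene{g:03d}" for g in range(spec.n_genes)])
    counts = pd.DataFrame(counts_arr, index=genes, columns=ids)
    points = PointSet(ids=ids, x=x, y=y,
                      annotation=np.array([f"c{k}" for k in labels]),
                      counts=counts)
    image = _render_image(spec, rng)
    return points, image, _SectionInternals(rates=rates, clusters=labels)


def make_serial_pair(spec: FixtureSpec, theta_deg: float = 25.0,
                     tx: float = 40.0, ty: float = -15.0,
                     jitter_sd: float = 5.0, count_noise: float = 0.3,
                     ) -> tuple[PointSet, PointSet, RigidMap]:
    """Two synthetic serial sections related by a known rigid map.

    Section B carries A's points through the map plus Gaussian
    positional jitter (``jitter_sd`` μm, emulating section-to-section
    tissue differences), and counts re-drawn from A's per-location
    Poisson rates, optionally perturbed by log-normal noise of scale
    ``count_noise``.  The exact map is returned for recovery tests.
    """
    a_points, _, internals = _make_section_with_rates(spec)
    center, _ = spec.geometry
    gt = RigidMap(theta_deg=theta_deg, tx=tx, ty=ty, center=center)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    bx, by = gt.apply(a_points.x, a_points.y)
    if jitter_sd > 0:
        bx = bx + rng.normal(0, jitter_sd, size=len(bx))
        by = by + rng.normal(0, jitter_sd, size=len(by))
    rates = internals.rates
    if count_noise > 0:
        rates = rates * rng.lognormal(0.0, count_noise, size=rates.shape)
    counts_b = pd.DataFrame(rng.poisson(rates),
                            index=a_points.counts.index,
                            columns=a_points.ids)
    b_points = PointSet(ids=a_points.ids.copy(), x=bx, y=by,
                        annotation=a_points.annotation.copy(),
                        counts=counts_b)
    return a_points, b_points, gt


# ---------------------------------------------------------------------
# on-disk fixture bundles (exercise every reader)
# ---------------------------------------------------------------------

def write_fixture_bundle(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Write one section in every supported input format.

    Produces coordinates.csv / coordinates.xlsx / section.h5ad plus
    tissue.png and tissue.jpeg, all derived from the same seeded
    section.
    """
    from . import io as io_formats

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    points, image = make_section(spec)
    paths: dict[str, Path] = {}

    df = pd.DataFrame({"id": points.ids, "x": points.x, "y": points.y,
                       "cluster": points.annotation})
    paths["csv"] = out_dir / "coordinates.csv"
    df.to_csv(paths["csv"], index=False)
    paths["xlsx"] = out_dir / "coordinates.xlsx"
    df.to_excel(paths["xlsx"], index=False)

    import anndata

    adata = anndata.AnnData(
        X=points.counts.T.to_numpy(dtype=np.float32),
        obs=pd.DataFrame({"cluster": points.annotation},
                         index=points.ids.astype(str)),
        var=pd.DataFrame(index=points.counts.index))
    adata.obsm["spatial"] = np.column_stack([points.x, points.y])
    paths["h5ad"] = out_dir / "section.h5ad"
    adata.write_h5ad(paths["h5ad"])

    paths["png"] = io_formats.write_image(image, out_dir / "tissue.png")
    paths["jpeg"] = io_formats.write_image(image, out_dir / "tissue.jpeg")
    return paths
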