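"""Readers and writers for every file format the engine touches.

Coordinate tables come in as CSV, XLSX or AnnData ``.h5ad`` (x-y
mandatory, categorical annotation and a gene-count matrix optional);
images as PNG or JPEG with a user-supplied pixel size.  A finished
registration is exported as a *bundle*: registered coordinates CSV,
registered image JPEG, a plain-text parameter record, the linear
manipulation log CSV and the drag record CSV.  The bundle plus the raw
inputs reproduce the registered output with no session state.
"""
from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError, SchemaError, ValidationError
from .model import (DragEvent, ImageRaster, LogEntry, PointSet, RigidState,
                    ScaleSpec, TransformLog)
from .session import Session, initial_display_scale, replay_full

REGISTERED_COORDS = "registered_coordinates.csv"
REGISTERED_IMAGE = "registered_image.jpeg"
RECORD = "registration_record.txt"
LOG = "manipulation_log.csv"
DRAGS = "drag_record.csv"

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


# ---------------------------------------------------------------------
# coordinate tables
# ---------------------------------------------------------------------

def _frame_to_points(df: pd.DataFrame, counts: Optional[pd.DataFrame] = None,
                     cluster_key: str = "cluster") -> PointSet:
    for col in ("x", "y"):
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} is missing")
    for col in ("x", "y"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(numeric.to_numpy(dtype=float)))
        if len(bad):
            raise SchemaError(
                f"column {col!r} is not a finite number at row {bad[0]}")
        df[col] = numeric
    if "id" in df.columns:
        ids = df["id"].to_numpy()
    else:
        ids = np.arange(len(df))
    annotation = None
    if cluster_key in df.columns and not df[cluster_key].isna().all():
        annotation = df[cluster_key].astype(str).to_numpy()
    return PointSet(ids=ids, x=df["x"].to_numpy(dtype=float),
                    y=df["y"].to_numpy(dtype=float),
                    annotation=annotation, counts=counts)


def read_coordinates(path, fmt: Optional[str] = None,
                     cluster_key: Optional[str] = None) -> PointSet:
    """Load a point table from ``.csv``, ``.xlsx`` or ``.h5ad``.

    ``cluster_key`` names the annotation column; it defaults to
    ``cluster`` for tabular formats and is required to pick an ``obs``
    column from an AnnData container.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        # round_trip float parsing: shortest-repr doubles read bit-exact
        return _frame_to_points(pd.read_csv(path,
                                            float_precision="round_trip"),
                                cluster_key=cluster_key or "cluster")
    if fmt == "xlsx":
        return _frame_to_points(pd.read_excel(path),
                                cluster_key=cluster_key or "cluster")
    if fmt == "h5ad":
        return _read_h5ad(path, cluster_key)
    raise FormatError(f"unsupported coordinate format {fmt!r}")


def _read_h5ad(path: Path, cluster_key: Optional[str]) -> PointSet:
    import anndata

    adata = anndata.read_h5ad(path)
    if "spatial" not in adata.obsm:
        raise SchemaError("AnnData container lacks obsm['spatial']")
    xy = np.asarray(adata.obsm["spatial"], dtype=float)
    if xy.shape[1] < 2:
        raise SchemaError("obsm['spatial'] must carry two columns")
    ids = adata.obs_names.to_numpy()
    annotation = None
    if cluster_key is not None:
        if cluster_key not in adata.obs.columns:
            raise SchemaError(f"obs column {cluster_key!r} not found")
        annotation = adata.obs[cluster_key].astype(str).to_numpy()
    counts = None
    if adata.X is not None:
        X = adata.X
        try:
            X = X.toarray()  # sparse
        except AttributeError:
            X = np.asarray(X)
        counts = pd.DataFrame(X.T, index=adata.var_names.to_numpy(),
                              columns=ids)
    return PointSet(ids=ids, x=xy[:, 0], y=xy[:, 1],
                    annotation=annotation, counts=counts)


def write_coordinates(points: PointSet, path) -> Path:
    """Write ``id,x,y,cluster`` CSV at full double precision.

    One row per observation — after a full replay this is every
    original data point, displayed or not.  The cluster column is kept
    (empty) even when no annotation exists.
    """
    path = Path(path)
    cluster = (points.annotation if points.annotation is not None
               else [""] * points.n)
    df = pd.DataFrame({"id": points.ids, "x": points.x, "y": points.y,
                       "cluster": cluster})
    # shortest-repr doubles: bit-exact on read-back (pandas' default
    # 16-significant-digit rendering can lose the last ulp)
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    return path


# ---------------------------------------------------------------------
# images
# ---------------------------------------------------------------------

def read_image(path, pixel_size: float) -> ImageRaster:
    """Load a PNG or JPEG raster; ``pixel_size`` is μm per pixel.

    The pixel size is always supplied by the user, never read from
    metadata.
    """
    path = Path(path)
    if not pixel_size > 0:
        raise ValidationError("pixel_size must be > 0")
    if path.suffix.lower() not in _IMAGE_SUFFIXES:
        raise FormatError(f"unsupported image format {path.suffix!r} "
                          "(accepted: .png, .jpeg/.jpg)")
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as pil:
        pixels = np.asarray(pil.convert("RGB"))
    return ImageRaster(pixels=pixels, pixel_size=pixel_size, name=path.name)


def write_image(image: ImageRaster, path, quality: int = 95) -> Path:
    path = Path(path)
    pil = Image.fromarray(image.pixels)
    if path.suffix.lower() in (".jpg", ".jpeg"):
        pil.convert("RGB").save(path, quality=quality)
    else:
        pil.save(path)
    return path


# ---------------------------------------------------------------------
# registration record (.txt, key=value)
# ---------------------------------------------------------------------

def write_record(state: RigidState, spec: ScaleSpec, path,
                 image_name: str = "") -> Path:
    path = Path(path)
    lines = [
        f"data_scale_um_per_px={spec.data_scale!r}",
        f"image_scale_um_per_px={spec.image_scale!r}",
        f"display_scale_um_per_px={spec.display_scale!r}",
        f"theta_deg={state.theta_deg!r}",
        f"tx={state.tx!r}",
        f"ty={state.ty!r}",
        f"flips_h={state.flips_h}",
        f"flips_v={state.flips_v}",
        f"center_x={state.center[0]!r}",
        f"center_y={state.center[1]!r}",
        f"image_name={image_name}",
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_record(path) -> tuple[RigidState, ScaleSpec, str]:
    """Reconstruct a field-equal RigidState + ScaleSpec from a record."""
    path = Path(path)
    kv: dict[str, str] = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
    try:
        spec = ScaleSpec(data_scale=float(kv["data_scale_um_per_px"]),
                         image_scale=float(kv["image_scale_um_per_px"]),
                         display_scale=float(kv["display_scale_um_per_px"]))
        state = RigidState(
            center=(float(kv["center_x"]), float(kv["center_y"])),
            theta_deg=float(kv["theta_deg"]),
            tx=float(kv["tx"]), ty=float(kv["ty"]),
            flips_h=int(kv["flips_h"]), flips_v=int(kv["flips_v"]))
    except KeyError as missing:
        raise SchemaError(f"record is missing field {missing}") from None
    return state, spec, kv.get("image_name", "")


# ---------------------------------------------------------------------
# manipulation log (.csv) and drag record (.csv)
# ---------------------------------------------------------------------

def write_log(log: TransformLog, path) -> Path:
    """Save the applied linear manipulations (redo branch is dropped)."""
    path = Path(path)
    rows = []
    for e in log.applied:
        params = list(e.params) + [""] * (3 - len(e.params))
        rows.append({"sequence": e.sequence, "op": e.op,
                     "param1": params[0], "param2": params[1],
                     "param3": params[2]})
    pd.DataFrame(rows, columns=["sequence", "op", "param1", "param2",
                                "param3"]).to_csv(path, index=False)
    return path


def read_log(path) -> TransformLog:
    df = pd.read_csv(Path(path))
    entries = []
    for _, row in df.iterrows():
        params = tuple(float(row[c]) for c in ("param1", "param2", "param3")
                       if pd.notna(row[c]) and row[c] != "")
        entries.append(LogEntry(sequence=int(row["sequence"]),
                                op=str(row["op"]), params=params))
    return TransformLog(entries=entries, cursor=len(entries))


def write_drags(events: Sequence[DragEvent], path) -> Path:
    path = Path(path)
    rows = []
    for seq, e in enumerate(events):
        rows.append({"sequence": seq, "anchor_id": e.anchor_id,
                     "anchor_x": e.anchor_xy[0], "anchor_y": e.anchor_xy[1],
                     "dx": e.dx, "dy": e.dy, "threshold": e.threshold,
                     "locked_ids": ";".join(str(i) for i in e.locked_ids)})
    pd.DataFrame(rows, columns=["sequence", "anchor_id", "anchor_x",
                                "anchor_y", "dx", "dy", "threshold",
                                "locked_ids"]).to_csv(path, index=False)
    return path


def read_drags(path) -> list[DragEvent]:
    df = pd.read_csv(Path(path))
    events = []
    for _, row in df.iterrows():
        locked: tuple = ()
        if "locked_ids" in df.columns and pd.notna(row["locked_ids"]) \
                and str(row["locked_ids"]):
            locked = tuple(str(row["locked_ids"]).split(";"))
        events.append(DragEvent(
            anchor_id=row["anchor_id"],
            anchor_xy=(float(row["anchor_x"]), float(row["anchor_y"])),
            dx=float(row["dx"]), dy=float(row["dy"]),
            threshold=float(row["threshold"]), locked_ids=locked))
    return events


# ---------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------

def write_registration_bundle(session: Session, out_dir) -> dict[str, Path]:
    """Export the finished registration; returns the written paths.

    Partial failures are reported per file.
    """
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written: dict[str, Path] = {}
    failures: list[str] = []
    jobs = {
        "coordinates": lambda: write_coordinates(
            session.replay_full(), out_dir / REGISTERED_COORDS),
        "record": lambda: write_record(
            session.state, session.spec, out_dir / RECORD,
            image_name=session.image.name if session.image else ""),
        "log": lambda: write_log(session.log, out_dir / LOG),
        "drags": lambda: write_drags(session.drag_events, out_dir / DRAGS),
    }
    if session.image is not None:
        jobs["image"] = lambda: write_image(
            session.image, out_dir / REGISTERED_IMAGE)
    for name, job in jobs.items():
        try:
            written[name] = job()
        except OSError as exc:  # pragma: no cover - depends on filesystem
            failures.append(f"{name}: {exc}")
    if failures:
        raise OSError("bundle export failed for " + "; ".join(failures))
    return written


def replay_bundle(bundle_dir, raw_points: PointSet) -> PointSet:
    """Re-register raw coordinates from a saved bundle alone.

    Reads the record, log and drag files, recovers the at-load display
    scale from the logged rescale factors, and replays everything over
    all observations.
    """
    bundle_dir = Path(bundle_dir)
    for name in (RECORD, LOG, DRAGS):
        if not (bundle_dir / name).exists():
            raise FileNotFoundError(bundle_dir / name)
    state, spec, _ = read_record(bundle_dir / RECORD)
    log = read_log(bundle_dir / LOG)
    drags = read_drags(bundle_dir / DRAGS)
    spec0 = spec.with_display(
        initial_display_scale(spec.display_scale, log.applied))
    return replay_full(raw_points, spec0, state.center, log.applied, drags)
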