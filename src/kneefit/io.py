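"""File formats and atomic writes.

Meshes are STL (binary/ASCII) or PLY; silhouette masks are 8-bit PNG with a
JSON sidecar carrying the physical metadata (mm/px spacing, view, bone,
side, origin); contours are CSV; trained models are a versioned NumPy
archive with an embedded JSON manifest; reports are JSON plus a CSV mirror.
All writes go through a temp-file-then-rename so readers never observe a
partially written artifact.
"""

from __future__ import annotations

import csv
import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import trimesh
from PIL import Image

from .evaluation import EvaluationReport, ReportRow
from .fitting import FitResult, SizePrediction
from .geometry import GeometryError, Mesh3D, RigidTransform2, RigidTransform3
from .reconstruction import PDM, SSM, MaskImage

__all__ = [
    "save_mesh",
    "load_mesh",
    "save_mask",
    "load_mask",
    "save_contour",
    "load_contour",
    "save_models",
    "load_models",
    "save_predictions",
    "load_predictions",
    "save_report",
    "report_to_csv",
    "save_population",
    "load_population_manifest",
]

MODEL_ARCHIVE_VERSION = 1
_MESH_SUFFIXES = (".stl", ".ply")


@contextmanager
def _atomic(path, mode: str = "wb"):
    """Write to a temp file in the destination directory, rename on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix)
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def save_mesh(mesh: Mesh3D, path) -> None:
    """Write a mesh as STL (binary) or PLY, chosen by file extension."""
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise GeometryError(f"unsupported mesh format: {path.suffix!r}")
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    data = tm.export(file_type=path.suffix.lower()[1:])
    if isinstance(data, str):  # pragma: no cover - exporters return bytes
        data = data.encode()
    with _atomic(path) as fh:
        fh.write(data)


def load_mesh(path) -> Mesh3D:
    """Read an STL (binary or ASCII) or PLY mesh."""
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise GeometryError(f"unsupported mesh format: {path.suffix!r}")
    tm = trimesh.load(str(path), file_type=path.suffix.lower()[1:], process=False)
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise GeometryError(f"no triangle mesh in {path}")
    return Mesh3D(np.asarray(tm.vertices, float), np.asarray(tm.faces, int))


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def _mask_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_mask(mask: MaskImage, path) -> None:
    """Write an 8-bit PNG (foreground 255) plus a JSON metadata sidecar."""
    path = Path(path)
    img = Image.fromarray(np.where(mask.pixels, 255, 0).astype(np.uint8))
    with _atomic(path) as fh:
        img.save(fh, format="PNG")
    meta = {
        "spacing": mask.spacing,
        "view": mask.view,
        "bone": mask.bone,
        "side": mask.side,
        "origin": list(mask.origin),
    }
    with _atomic(_mask_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_mask(path) -> MaskImage:
    """Read a mask PNG (foreground = value > 127) and its JSON sidecar."""
    path = Path(path)
    sidecar = _mask_sidecar(path)
    if not sidecar.exists():
        raise GeometryError(f"mask sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    pixels = np.asarray(Image.open(path).convert("L")) > 127
    return MaskImage(
        pixels=pixels,
        spacing=float(meta["spacing"]),
        view=meta["view"],
        bone=meta["bone"],
        side=meta["side"],
        origin=tuple(meta["origin"]),
    )


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------


def save_contour(points: np.ndarray, path) -> None:
    """Write contour points as CSV, one ``x,y[,z]`` row per point."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] not in (2, 3):
        raise GeometryError("contour points must be (N, 2) or (N, 3)")
    with _atomic(path, "w") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "z"][: pts.shape[1]])
        for row in pts:
            w.writerow([repr(float(v)) for v in row])


def load_contour(path) -> np.ndarray:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 2:
        raise GeometryError(f"no contour points in {path}")
    return np.array([[float(v) for v in row] for row in rows[1:]])


# ---------------------------------------------------------------------------
# model archives
# ---------------------------------------------------------------------------


def save_models(ssm: SSM, pdms: dict, path) -> None:
    """Write an SSM and its per-view PDMs as one ``.npz`` archive with a JSON
    manifest (version, bone/frame tag, vertex and mode counts, PDM P)."""
    manifest = {
        "version": MODEL_ARCHIVE_VERSION,
        "bone": ssm.bone,
        "frame": "canonical-right-knee",
        "n_vertices": int(len(ssm.mean_shape)),
        "n_modes": int(ssm.n_modes),
        "views": sorted(pdms),
        "pdm_points": {v: int(p.P) for v, p in pdms.items()},
    }
    arrays = {
        "manifest": np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
        "ssm_mean_shape": ssm.mean_shape,
        "ssm_faces": ssm.faces,
        "ssm_modes": ssm.modes,
        "ssm_eigenvalues": ssm.eigenvalues,
    }
    for view, pdm in pdms.items():
        if pdm.bone != ssm.bone:
            raise GeometryError("PDM bone tag does not match the SSM")
        arrays[f"pdm_{view}_mean_depth"] = pdm.mean_depth
        arrays[f"pdm_{view}_depth_modes"] = pdm.depth_modes
        arrays[f"pdm_{view}_variances"] = pdm.variances
        arrays[f"pdm_{view}_train_mean_extent"] = np.array(pdm.train_mean_extent)
    with _atomic(path) as fh:
        np.savez(fh, **arrays)


def load_models(path) -> tuple[SSM, dict]:
    """Read a model archive; returns ``(ssm, {view: pdm})``."""
    with np.load(path) as z:
        if "manifest" not in z:
            raise GeometryError(f"not a model archive: {path}")
        manifest = json.loads(bytes(z["manifest"].tobytes()).decode())
        if manifest.get("version") != MODEL_ARCHIVE_VERSION:
            raise GeometryError(
                f"unsupported model archive version {manifest.get('version')!r}"
            )
        bone = manifest["bone"]
        ssm = SSM(
            mean_shape=z["ssm_mean_shape"],
            faces=z["ssm_faces"],
            modes=z["ssm_modes"],
            eigenvalues=z["ssm_eigenvalues"],
            bone=bone,
        )
        pdms = {
            view: PDM(
                view=view,
                bone=bone,
                mean_depth=z[f"pdm_{view}_mean_depth"],
                depth_modes=z[f"pdm_{view}_depth_modes"],
                variances=z[f"pdm_{view}_variances"],
                train_mean_extent=float(z[f"pdm_{view}_train_mean_extent"]),
            )
            for view in manifest["views"]
        }
    return ssm, pdms


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------


def _transform_to_dict(tf) -> dict:
    if isinstance(tf, RigidTransform3):
        return {
            "kind": "rigid3",
            "rotation": np.asarray(tf.rotation).ravel().tolist(),
            "translation": np.asarray(tf.translation).tolist(),
        }
    if isinstance(tf, RigidTransform2):
        return {"kind": "rigid2", "theta": tf.theta, "tx": tf.tx, "ty": tf.ty}
    raise GeometryError(f"unknown transform type {type(tf).__name__}")


def _transform_from_dict(d: dict):
    if d["kind"] == "rigid3":
        return RigidTransform3(
            np.asarray(d["rotation"]).reshape(3, 3), np.asarray(d["translation"])
        )
    if d["kind"] == "rigid2":
        return RigidTransform2(d["theta"], d["tx"], d["ty"])
    raise GeometryError(f"unknown transform kind {d['kind']!r}")


def prediction_to_dict(pred: SizePrediction) -> dict:
    return {
        "manufacturer": pred.manufacturer,
        "model": pred.model,
        "component": pred.component,
        "best_by_rmse": pred.best_by_rmse,
        "best_by_ouh": pred.best_by_ouh,
        "all_fits": [
            {
                "size_id": f.size_id,
                "rmse": f.rmse,
                "max_ouh": f.max_ouh,
                "transform": _transform_to_dict(f.transform),
            }
            for f in pred.all_fits
        ],
        "failures": [list(f) for f in pred.failures],
    }


def prediction_from_dict(d: dict) -> SizePrediction:
    fits = [
        FitResult(
            manufacturer=d["manufacturer"],
            model=d["model"],
            component=d["component"],
            size_id=f["size_id"],
            transform=_transform_from_dict(f["transform"]),
            rmse=float(f["rmse"]),
            max_ouh=float(f["max_ouh"]),
        )
        for f in d["all_fits"]
    ]
    return SizePrediction(
        manufacturer=d["manufacturer"],
        model=d["model"],
        component=d["component"],
        best_by_rmse=d["best_by_rmse"],
        best_by_ouh=d["best_by_ouh"],
        all_fits=fits,
        failures=[tuple(f) for f in d.get("failures", [])],
    )


def save_predictions(preds, path, subject_ids=None) -> None:
    """Write per-subject size predictions as JSON.

    ``preds`` is a list of per-chart :class:`SizePrediction` lists, one per
    subject; a single subject's list is also accepted.
    """
    if preds and isinstance(preds[0], SizePrediction):
        preds = [preds]
    payload = {
        "subjects": [
            {
                "subject_id": subject_ids[i] if subject_ids else f"subject-{i:04d}",
                "predictions": [prediction_to_dict(p) for p in plist],
            }
            for i, plist in enumerate(preds)
        ]
    }
    with _atomic(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_predictions(path) -> tuple[list, list]:
    """Read predictions JSON; returns ``(subject_ids, per-subject lists)``."""
    data = json.loads(Path(path).read_text())
    ids, preds = [], []
    for entry in data["subjects"]:
        ids.append(entry["subject_id"])
        preds.append([prediction_from_dict(d) for d in entry["predictions"]])
    return ids, preds


# ---------------------------------------------------------------------------
# evaluation reports
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "manufacturer", "model", "component", "metric", "n",
    "accuracy_pct", "accuracy_pm1_pct",
    "mean_gt_best_rmse", "mean_pred_rmse",
    "mean_gt_best_ouh", "mean_pred_ouh",
    "pct_under_3mm_gt", "pct_under_3mm_pred",
    "spearman_rho_vs_age", "accuracy_F_pct", "accuracy_M_pct",
]


def save_report(report: EvaluationReport, path) -> None:
    with _atomic(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, allow_nan=True)


def report_to_csv(report: EvaluationReport, path) -> None:
    """CSV mirror of the accuracy tables: one row per (model, component,
    metric), accuracy and mean-metric columns plus sex-stratified accuracy."""
    with _atomic(path, "w") as fh:
        w = csv.writer(fh)
        w.writerow(_REPORT_COLUMNS)
        for r in report.rows:
            w.writerow(
                [
                    r.manufacturer, r.model, r.component, r.metric, r.n,
                    f"{r.accuracy_pct:.2f}", f"{r.accuracy_pm1_pct:.2f}",
                    f"{r.mean_gt_best_rmse:.4f}", f"{r.mean_pred_rmse:.4f}",
                    f"{r.mean_gt_best_ouh:.4f}", f"{r.mean_pred_ouh:.4f}",
                    f"{r.pct_under_3mm_gt:.2f}", f"{r.pct_under_3mm_pred:.2f}",
                    f"{r.spearman_rho_vs_age:.4f}",
                    *(
                        f"{r.accuracy_by_sex[s]:.2f}" if s in r.accuracy_by_sex else ""
                        for s in ("F", "M")
                    ),
                ]
            )


def load_report(path) -> EvaluationReport:
    data = json.loads(Path(path).read_text())
    rows = [ReportRow(**row) for row in data["rows"]]
    return EvaluationReport(n_subjects=data["n_subjects"], rows=rows)


# ---------------------------------------------------------------------------
# synthetic populations on disk
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = [
    "subject_id", "sex", "age", "side",
    "true_ML_femur", "true_AP_femur", "true_ML_tibia", "true_AP_tibia",
    "seed",
]


def save_population(subjects, outdir) -> Path:
    """Write a synthetic cohort: per-subject STL meshes and mask PNGs plus a
    ``subjects.csv`` manifest.  Returns the manifest path."""
    outdir = Path(outdir)
    for s in subjects:
        sdir = outdir / s.subject_id
        save_mesh(s.femur_mesh, sdir / "femur.stl")
        save_mesh(s.tibia_mesh, sdir / "tibia.stl")
        for (bone, view), mask in sorted(s.masks.items()):
            save_mask(mask, sdir / f"{bone}_{view}.png")
    manifest = outdir / "subjects.csv"
    with _atomic(manifest, "w") as fh:
        w = csv.writer(fh)
        w.writerow(_MANIFEST_COLUMNS)
        for s in subjects:
            w.writerow(
                [
                    s.subject_id, s.sex, repr(float(s.age)), s.side,
                    repr(float(s.true_ML_femur)), repr(float(s.true_AP_femur)),
                    repr(float(s.true_ML_tibia)), repr(float(s.true_AP_tibia)),
                    s.seed,
                ]
            )
    return manifest


def load_population_manifest(datadir) -> list[dict]:
    """Read ``subjects.csv``; returns one dict per subject with typed fields
    and the subject's data directory under ``dir``."""
    datadir = Path(datadir)
    manifest = datadir / "subjects.csv"
    if not manifest.exists():
        raise GeometryError(f"subjects.csv not found in {datadir}")
    with open(manifest, newline="") as fh:
        rows = list(csv.DictReader(fh))
    out = []
    for row in rows:
        rec = dict(row)
        for k in ("age", "true_ML_femur", "true_AP_femur", "true_ML_tibia", "true_AP_tibia"):
            rec[k] = float(rec[k])
        rec["seed"] = int(rec["seed"])
        rec["dir"] = datadir / rec["subject_id"]
        out.append(rec)
    return out
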