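"""File formats, pipeline configuration and the end-to-end pipeline.

Contours and edit scripts travel as small JSON documents; images as
PNG/TIFF (8- or 16-bit integer or floating point, normalized to [0, 1] on
load); volumes as multi-page TIFF or a lexicographically sorted directory
of slices.  The pipeline runs the delineation stages in order —
control-point fit, optional uniform resample, snake evolution, optional
multiscale edit — writing the contour after every stage plus a manifest
and the fully resolved configuration, so a run is auditable and bit-for-bit
repeatable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .curves import Contour, SamplingParams, fit_closed_curve, resample_uniform
from .multiscale import Edit, EditScript, apply_edits, generate_mesh
from .propagation import Volume
from .snake import EvolutionResult, SnakeParams, evolve, external_energy

__all__ = [
    "CONTOUR_FORMAT", "EDITS_FORMAT",
    "read_contour", "write_contour", "read_control_points", "write_control_points",
    "read_edit_script", "write_edit_script",
    "load_image", "save_image", "load_volume",
    "PipelineConfig", "run_pipeline",
]

log = logging.getLogger(__name__)

CONTOUR_FORMAT = "snakedit-contour-v1"
EDITS_FORMAT = "snakedit-edits-v1"


# ---------------------------------------------------------------------------
# contour / control-point JSON

def _read_points_document(path) -> np.ndarray:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != CONTOUR_FORMAT:
        raise ValueError(f"{path}: expected format {CONTOUR_FORMAT!r}, "
                         f"got {doc.get('format')!r}")
    if not doc.get("closed", False):
        raise ValueError(f"{path}: only closed contours are supported")
    pts = np.asarray(doc["points"], dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"{path}: points must be a list of [x, y] pairs")
    return pts


def _write_points_document(path, pts: np.ndarray) -> None:
    doc = {"format": CONTOUR_FORMAT, "closed": True,
           "points": [[float(x), float(y)] for x, y in pts]}
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_contour(path) -> Contour:
    return Contour(_read_points_document(path))


def write_contour(path, contour: Contour) -> None:
    _write_points_document(path, contour.points)


def read_control_points(path) -> np.ndarray:
    """Control points use the same schema as contours."""
    return _read_points_document(path)


def write_control_points(path, pts) -> None:
    _write_points_document(path, np.asarray(pts, dtype=float))


def read_edit_script(path) -> EditScript:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != EDITS_FORMAT:
        raise ValueError(f"{path}: expected format {EDITS_FORMAT!r}, "
                         f"got {doc.get('format')!r}")
    edits = []
    for e in doc["edits"]:
        edits.append(Edit(
            level=int(e["level"]), index=int(e["index"]),
            new_position=tuple(e["new_position"]) if "new_position" in e else None,
            displacement=tuple(e["displacement"]) if "displacement" in e else None))
    return EditScript(tuple(edits))


def write_edit_script(path, script: EditScript) -> None:
    out = []
    for e in script.edits:
        d: dict = {"level": e.level, "index": e.index}
        if e.new_position is not None:
            d["new_position"] = [float(v) for v in e.new_position]
        else:
            d["displacement"] = [float(v) for v in e.displacement]
        out.append(d)
    Path(path).write_text(json.dumps({"format": EDITS_FORMAT, "edits": out}, sort_keys=True))


# ---------------------------------------------------------------------------
# images and volumes

def _normalize(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:  # collapse RGB(A) to luminance-free mean grayscale
        arr = arr[..., :3].mean(axis=2)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    out = arr.astype(float)
    if not np.all(np.isfinite(out)):
        raise ValueError("image contains non-finite values")
    return np.clip(out, 0.0, 1.0)


def load_image(path) -> np.ndarray:
    """Read a grayscale image and normalize intensities to [0, 1]."""
    return _normalize(iio.imread(Path(path)))


def save_image(path, image: np.ndarray) -> None:
    """Write [0, 1] floats: TIFF keeps float32, PNG quantizes to 16 bit."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    else:
        q = np.round(np.clip(image, 0.0, 1.0) * 65535.0).astype(np.uint16)
        iio.imwrite(path, q)


def load_volume(path) -> Volume:
    """Read a multi-page TIFF or a sorted directory of PNG/TIFF slices."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise ValueError(f"no image slices found in {path}")
        return Volume(slices=[load_image(f) for f in files],
                      ids=[f.stem for f in files])
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return Volume(slices=[_normalize(s) for s in stack],
                  ids=[f"slice{i:03d}" for i in range(len(stack))])


# ---------------------------------------------------------------------------
# pipeline

@dataclass(frozen=True)
class PipelineConfig:
    """Fully resolved configuration of one delineation run."""

    image: str
    control_points: str
    outdir: str
    edits: str | None = None
    alpha: float = 0.1
    beta: float = 1.0
    sigma: float = 2.0
    tau: float = 1.0
    max_iter: int = 50
    tol: float = 0.1
    force_scale: float = 30.0
    delta_s: float = 0.1
    tension: float = 0.5
    resample_n: int | None = None
    base_count: int = 13
    mesh_level: int = 3
    seed: int = 0

    def snake_params(self) -> SnakeParams:
        return SnakeParams(alpha=self.alpha, beta=self.beta, sigma=self.sigma,
                           tau=self.tau, max_iter=self.max_iter, tol=self.tol,
                           force_scale=self.force_scale)

    def sampling(self) -> SamplingParams:
        return SamplingParams(delta_s=self.delta_s)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path, **overrides) -> "PipelineConfig":
        doc = json.loads(Path(path).read_text())
        doc.update({k: v for k, v in overrides.items() if v is not None})
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def run_pipeline(config: PipelineConfig) -> tuple[EvolutionResult, Contour]:
    """Run initialize → (resample) → snake → (multiscale edit).

    Each stage writes its contour to ``outdir`` and reads its input from
    the previous stage's file, so the on-disk chain is the actual data
    path.  A manifest with per-stage info and the resolved config are
    written next to the contours.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    manifest: dict = {"stages": []}
    sp = config.sampling()

    def fail(stage: str, err: Exception):
        manifest["error"] = {"stage": stage, "message": str(err)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # stage 1: Hermite fit through the initial control points
    try:
        ctrl = read_control_points(config.control_points)
        contour = fit_closed_curve(ctrl, sp, config.tension)
    except Exception as err:
        fail("fit", err)
    write_contour(outdir / "stage1_fit.json", contour)
    manifest["stages"].append({"name": "fit", "n_points": len(contour),
                               "output": "stage1_fit.json"})

    # stage 2: optional uniform arc-length resample
    contour = read_contour(outdir / "stage1_fit.json")
    if config.resample_n is not None:
        try:
            contour = resample_uniform(contour, config.resample_n)
        except Exception as err:
            fail("resample", err)
    write_contour(outdir / "stage2_resample.json", contour)
    manifest["stages"].append({"name": "resample", "n_points": len(contour),
                               "output": "stage2_resample.json"})

    # stage 3: snake evolution
    contour = read_contour(outdir / "stage2_resample.json")
    try:
        image = load_image(config.image)
        energy = external_energy(image, config.sigma)
        evo = evolve(contour, energy, config.snake_params())
    except Exception as err:
        fail("snake", err)
    write_contour(outdir / "stage3_snake.json", evo.contour)
    manifest["stages"].append({
        "name": "snake", "n_iter": evo.n_iter, "converged": evo.converged,
        "energy_initial": float(evo.energy_trace[0]),
        "energy_final": float(evo.energy_trace[-1]),
        "output": "stage3_snake.json"})

    # stage 4: optional multiscale control-point edit
    contour = read_contour(outdir / "stage3_snake.json")
    if config.edits is not None:
        try:
            script = read_edit_script(config.edits)
            mesh = generate_mesh(contour, config.mesh_level, config.base_count)
            contour = apply_edits(mesh, script, sp, config.tension)
        except Exception as err:
            fail("edit", err)
        write_contour(outdir / "stage4_edit.json", contour)
        manifest["stages"].append({"name": "edit", "n_edits": len(script),
                                   "output": "stage4_edit.json"})

    write_contour(outdir / "final.json", contour)
    manifest["final"] = "final.json"
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return evo, contour
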