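"""Slice-to-slice contour tracking through an image stack.

When consecutive slices of a volume are thin, the converged contour of one
slice is a near boundary initialization for the next, so a whole 3D region
can be delineated by carrying the snake result forward slice by slice.
Per-slice edit scripts allow scripted correction on slices where the snake
fails; the (possibly edited) contour is what propagates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import Contour, SamplingParams, resample_uniform
from .multiscale import EditScript, apply_edits, generate_mesh
from .snake import EvolutionResult, SnakeDivergenceError, SnakeParams, evolve, external_energy

__all__ = ["Volume", "SliceResult", "track", "track_detailed"]


@dataclass(frozen=True)
class Volume:
    """Ordered stack of same-shape grayscale slices with string identifiers."""

    slices: list
    ids: list

    def __post_init__(self) -> None:
        if len(self.slices) == 0:
            raise ValueError("volume must contain at least one slice")
        if len(self.ids) != len(self.slices):
            raise ValueError("one id per slice required")
        shape = np.asarray(self.slices[0]).shape
        for s in self.slices:
            if np.asarray(s).shape != shape:
                raise ValueError("all slices must share one shape")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(self.slices[0]).shape


@dataclass(frozen=True)
class SliceResult:
    slice_id: str
    contour: Contour
    evolution: EvolutionResult
    edited: bool


def track_detailed(volume: Volume, init: Contour, params: SnakeParams,
                   edits_by_slice: dict[str, EditScript] | None = None,
                   mesh_level: int = 3, base_count: int = 13,
                   sp: SamplingParams = SamplingParams(), tension: float = 0.5,
                   resample: bool = True, reverse: bool = False) -> list[SliceResult]:
    """Track a contour through every slice, carrying the result forward.

    Per slice: evolve the snake from the carried-in contour; if an edit
    script is registered for the slice id, generate a control-point mesh at
    ``mesh_level`` on the converged contour and apply the edits; optionally
    resample the result to uniform arc-length spacing (same point count) to
    prevent point bunching over long stacks.  The returned contour of each
    slice is exactly the contour carried into the next.
    """
    edits_by_slice = edits_by_slice or {}
    order = range(len(volume) - 1, -1, -1) if reverse else range(len(volume))
    current = init
    results: list[SliceResult] = []
    for i in order:
        sid = volume.ids[i]
        field = external_energy(np.asarray(volume.slices[i], dtype=float), params.sigma)
        try:
            evo = evolve(current, field, params)
        except SnakeDivergenceError as err:
            raise SnakeDivergenceError(f"slice {sid!r}: {err}") from err
        contour = evo.contour
        edits = edits_by_slice.get(sid)
        edited = edits is not None and len(edits) > 0
        if edited:
            mesh = generate_mesh(contour, mesh_level, base_count)
            contour = apply_edits(mesh, edits, sp, tension)
        if resample:
            contour = resample_uniform(contour, len(init))
        results.append(SliceResult(slice_id=sid, contour=contour, evolution=evo,
                                   edited=edited))
        current = contour
    return results


def track(volume: Volume, init: Contour, params: SnakeParams,
          edits_by_slice: dict[str, EditScript] | None = None,
          mesh_level: int = 3, **kwargs) -> list[Contour]:
    """Per-slice contours from carry-forward tracking (see :func:`track_detailed`)."""
    return [r.contour for r in track_detailed(volume, init, params, edits_by_slice,
                                              mesh_level, **kwargs)]
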