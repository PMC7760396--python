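"""Core data model for time-resolved flow fields on tetrahedral meshes.

This module holds the containers every downstream metric operates on — an
unstructured tetrahedral mesh with labeled boundary patches, time-ordered
field frames (node positions, velocity, pressure) and unit-tagged scalar
waveforms — together with the geometric queries they need: point location
with barycentric weights, boundary-patch volume flux and planar
cross-sections.

Internal units are SI (m, s, Pa, kg).  Reporting units follow clinical
convention (cm², mL/s, mmHg, mW) and conversions are applied only at the
reporting boundary of each operation.

Field series are exchanged on disk as per-frame legacy ASCII VTK (or ASCII
``.vtu``) files plus a YAML manifest; boundary-patch labels travel in a
sidecar CSV referenced by the manifest.
"""

from __future__ import annotations

import math
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "PhysicalConstants",
    "ScalarWaveform",
    "UnstructuredMesh",
    "FieldFrame",
    "FieldSeries",
    "MeshError",
    "FieldSeriesError",
    "CrossSectionError",
    "locate_cell",
    "boundary_flux",
    "cross_section",
    "read_field_series",
    "write_field_series",
    "PA_PER_MMHG",
    "ML_PER_M3",
    "CM2_PER_M2",
    "MW_PER_W",
    "CAP_PATCHES",
    "WALL_PATCH",
]

# ---------------------------------------------------------------------------
# Constants and unit conversions
# ---------------------------------------------------------------------------

#: Conversion factor between pascal and millimetres of mercury.
PA_PER_MMHG = 133.322
#: Millilitres per cubic metre.
ML_PER_M3 = 1.0e6
#: Square centimetres per square metre.
CM2_PER_M2 = 1.0e4
#: Milliwatt per watt.
MW_PER_W = 1.0e3

#: The four vessel caps of a total cavopulmonary connection: the Fontan
#: pathway and superior vena cava inlets, the left/right pulmonary artery
#: outlets.
CAP_PATCHES = ("FP", "SVC", "LPA", "RPA")
WALL_PATCH = "WALL"


class MeshError(ValueError):
    """Raised when a mesh violates a structural invariant."""


class FieldSeriesError(ValueError):
    """Raised for inconsistent or unreadable field series."""


class CrossSectionError(ValueError):
    """Raised when a cutting plane misses or ambiguously cuts a branch."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the blood-flow problem.

    Defaults are the standard Fontan modelling assumptions: Newtonian blood
    with density 1000 kg/m³ and kinematic viscosity 3.5e-6 m²/s, and a
    resting cardiac cycle of 0.86 s.
    """

    density: float = 1000.0  # kg/m^3
    kinematic_viscosity: float = 3.5e-6  # m^2/s
    cycle_period: float = 0.86  # s
    pa_per_mmhg: float = PA_PER_MMHG

    def __post_init__(self) -> None:
        for name in ("density", "kinematic_viscosity", "cycle_period", "pa_per_mmhg"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"PhysicalConstants.{name} must be strictly positive")

    @property
    def dynamic_viscosity(self) -> float:
        """Dynamic viscosity mu = rho * nu in Pa·s."""
        return self.density * self.kinematic_viscosity

    def mmhg(self, pressure_pa: float | np.ndarray):
        """Convert pascal to mmHg."""
        return np.asarray(pressure_pa) / self.pa_per_mmhg

    def pa(self, pressure_mmhg: float | np.ndarray):
        """Convert mmHg to pascal."""
        return np.asarray(pressure_mmhg) * self.pa_per_mmhg


# ---------------------------------------------------------------------------
# Scalar waveforms
# ---------------------------------------------------------------------------


@dataclass
class ScalarWaveform:
    """A unit-tagged scalar time series (area, flow, volume, pressure, power).

    Times must be strictly increasing and match the value array length.
    """

    times: np.ndarray
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("waveform times and values must be 1-D")
        if self.times.size != self.values.size:
            raise ValueError("waveform times and values must have equal length")
        if self.times.size == 0:
            raise ValueError("waveform must contain at least one sample")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("non-monotone times in waveform")

    def __len__(self) -> int:
        return self.times.size

    @property
    def vmin(self) -> float:
        return float(np.min(self.values))

    @property
    def vmax(self) -> float:
        return float(np.max(self.values))

    @property
    def vrange(self) -> float:
        """Peak-to-peak range max - min."""
        return self.vmax - self.vmin

    def mean(self) -> float:
        """Arithmetic mean of the samples."""
        return float(np.mean(self.values))

    def time_average(self) -> float:
        """Trapezoidal time average over the sampled interval."""
        if self.times.size == 1:
            return float(self.values[0])
        span = self.times[-1] - self.times[0]
        return float(np.trapezoid(self.values, self.times) / span)


# ---------------------------------------------------------------------------
# Mesh
# ---------------------------------------------------------------------------


def _tet_volumes(points: np.ndarray, cells: np.ndarray) -> np.ndarray:
    a, b, c, d = (points[cells[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def _sorted_faces(cells: np.ndarray) -> np.ndarray:
    """All 4*m tet faces as sorted node triples, cell-major order.

    Face j of cell c is the face opposite local vertex j.
    """
    f = np.stack(
        [
            cells[:, [1, 2, 3]],
            cells[:, [0, 2, 3]],
            cells[:, [0, 1, 3]],
            cells[:, [0, 1, 2]],
        ],
        axis=1,
    ).reshape(-1, 3)
    return np.sort(f, axis=1)


class UnstructuredMesh:
    """Tetrahedral mesh with labeled boundary patches.

    Parameters
    ----------
    points
        Reference node coordinates in metres, shape (n, 3).
    cells
        Tetrahedra as 4 node indices each, shape (m, 4).  Reordered on
        construction so every cell has positive volume.
    boundary_faces
        Boundary triangles as 3 node indices each.  Reoriented on
        construction so the facet normal points out of the domain.
    boundary_labels
        One patch label per boundary face, from ``CAP_PATCHES`` + ``WALL``.
    patch_kinds
        Mapping label -> "inlet" | "outlet" | "wall" for every patch.
    """

    def __init__(
        self,
        points: np.ndarray,
        cells: np.ndarray,
        boundary_faces: np.ndarray,
        boundary_labels: Sequence[str],
        patch_kinds: dict[str, str],
        validate: bool = True,
        cap_planarity_tol: float = 1e-6,
    ) -> None:
        self.points = np.ascontiguousarray(points, dtype=float)
        self.cells = np.ascontiguousarray(cells, dtype=np.int64)
        self.boundary_faces = np.ascontiguousarray(boundary_faces, dtype=np.int64)
        self.boundary_labels = np.asarray(boundary_labels, dtype=object)
        self.patch_kinds = dict(patch_kinds)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise MeshError("points must have shape (n, 3)")
        if self.cells.ndim != 2 or self.cells.shape[1] != 4:
            raise MeshError("cells must have shape (m, 4)")
        if self.boundary_faces.shape[0] != self.boundary_labels.shape[0]:
            raise MeshError("one label per boundary face required")
        self._fix_cell_orientation()
        self._orient_boundary_faces()
        if validate:
            self.validate(cap_planarity_tol=cap_planarity_tol)

    # -- structural properties ---------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    @cached_property
    def cell_volumes(self) -> np.ndarray:
        return _tet_volumes(self.points, self.cells)

    @cached_property
    def cell_neighbors(self) -> np.ndarray:
        """(m, 4) neighbor cell across the face opposite local vertex j; -1
        on the boundary."""
        m = self.n_cells
        faces = _sorted_faces(self.cells)
        order = np.lexsort(faces.T)
        fs = faces[order]
        owner = order // 4  # owning cell of each face slot
        slot = order % 4
        nbr = np.full((m, 4), -1, dtype=np.int64)
        same = np.all(fs[1:] == fs[:-1], axis=1)
        i = np.nonzero(same)[0]
        nbr[owner[i], slot[i]] = owner[i + 1]
        nbr[owner[i + 1], slot[i + 1]] = owner[i]
        return nbr

    @cached_property
    def _boundary_face_owner(self) -> np.ndarray:
        """Owning cell index of each boundary face."""
        faces = _sorted_faces(self.cells)
        lookup = {tuple(f): i // 4 for i, f in enumerate(map(tuple, faces))}
        owners = np.empty(self.boundary_faces.shape[0], dtype=np.int64)
        for k, f in enumerate(np.sort(self.boundary_faces, axis=1)):
            key = tuple(f)
            if key not in lookup:
                raise MeshError(f"boundary face {k} is not a face of any cell")
            owners[k] = lookup[key]
        return owners

    def _fix_cell_orientation(self) -> None:
        vol = _tet_volumes(self.points, self.cells)
        flip = vol < 0
        if np.any(flip):
            c = self.cells[flip]
            c[:, [2, 3]] = c[:, [3, 2]]
            self.cells[flip] = c

    def _orient_boundary_faces(self) -> None:
        """Flip boundary face node order so normals point out of the domain."""
        owners = self._boundary_face_owner
        a = self.points[self.boundary_faces[:, 0]]
        b = self.points[self.boundary_faces[:, 1]]
        c = self.points[self.boundary_faces[:, 2]]
        n = np.cross(b - a, c - a)
        cent = self.points[self.cells[owners]].mean(axis=1)
        inward = np.einsum("ij,ij->i", n, cent - a) > 0
        if np.any(inward):
            f = self.boundary_faces[inward]
            f[:, [1, 2]] = f[:, [2, 1]]
            self.boundary_faces[inward] = f

    def validate(self, cap_planarity_tol: float = 1e-6) -> None:
        """Check the structural invariants; raise :class:`MeshError` if violated."""
        if np.any(self.cells < 0) or np.any(self.cells >= self.n_nodes):
            raise MeshError("cell node index out of range")
        vol = self.cell_volumes
        if np.any(vol <= 0):
            raise MeshError(f"{int(np.sum(vol <= 0))} cells with non-positive volume")
        # boundary closure: the unpaired tet faces must equal the declared set
        unpaired_slots = np.nonzero(self.cell_neighbors.ravel() < 0)[0]
        faces = _sorted_faces(self.cells)[unpaired_slots]
        declared = np.sort(self.boundary_faces, axis=1)
        fa = {tuple(f) for f in faces}
        fb = {tuple(f) for f in declared}
        if fa != fb:
            missing = len(fa - fb)
            extra = len(fb - fa)
            raise MeshError(
                "boundary facet set is not closed: "
                f"{missing} mesh boundary faces unlabeled, {extra} labels match no face"
            )
        for label in np.unique(self.boundary_labels):
            if label not in self.patch_kinds:
                raise MeshError(f"patch '{label}' missing from patch_kinds registry")
        for label, kind in self.patch_kinds.items():
            if kind not in ("inlet", "outlet", "wall"):
                raise MeshError(f"patch '{label}' has unknown kind '{kind}'")
            if kind != "wall":
                self._check_cap_planarity(label, cap_planarity_tol)

    def _check_cap_planarity(self, label: str, tol: float) -> None:
        nodes = self.patch_nodes(label)
        if nodes.size == 0:
            raise MeshError(f"cap patch '{label}' has no facets")
        pts = self.points[nodes]
        center = pts.mean(axis=0)
        _, s, vt = np.linalg.svd(pts - center, full_matrices=False)
        dev = np.abs((pts - center) @ vt[2])
        if dev.max() > tol:
            raise MeshError(
                f"cap patch '{label}' is not planar: max deviation {dev.max():.3e} m"
            )

    # -- patch queries ------------------------------------------------------

    def patch_labels(self) -> list[str]:
        return sorted(set(self.boundary_labels.tolist()))

    def _require_patch(self, label: str) -> None:
        if label not in self.patch_kinds or not np.any(self.boundary_labels == label):
            raise MeshError(
                f"unknown patch label '{label}'; available: {self.patch_labels()}"
            )

    def patch_faces(self, label: str) -> np.ndarray:
        """Outward-oriented boundary triangles of a patch."""
        self._require_patch(label)
        return self.boundary_faces[self.boundary_labels == label]

    def patch_nodes(self, label: str) -> np.ndarray:
        """Unique node indices of a patch."""
        return np.unique(self.patch_faces(label))

    def patch_plane(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """Centroid and unit outward normal of a (planar) cap patch."""
        faces = self.patch_faces(label)
        a, b, c = (self.points[faces[:, i]] for i in range(3))
        n = np.cross(b - a, c - a).sum(axis=0)
        n /= np.linalg.norm(n)
        center = self.points[np.unique(faces)].mean(axis=0)
        return center, n

    def patch_area(self, label: str, positions: np.ndarray | None = None) -> float:
        """Total facet area of a patch in m² (deformed if positions given)."""
        pos = self.points if positions is None else positions
        faces = self.patch_faces(label)
        a, b, c = (pos[faces[:, i]] for i in range(3))
        return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())

    # -- uniform-grid candidate lookup -------------------------------------

    @cached_property
    def _grid(self) -> "_UniformGrid":
        return _UniformGrid(self)

    def grid_candidates(self, point: np.ndarray) -> np.ndarray:
        """Candidate cells (ascending index) whose inflated bounding box
        contains ``point``."""
        return self._grid.candidates(point)

    def set_locator_margin(self, margin: float) -> None:
        """Inflate the locator grid's cell bounding boxes by ``margin``
        metres (needed when frames deform nodes away from the reference)."""
        self.__dict__.pop("_grid", None)
        self._locator_margin = margin

    @property
    def locator_margin(self) -> float:
        return getattr(self, "_locator_margin", 0.0)


class _UniformGrid:
    """Uniform spatial bin -> candidate-cell lookup (CSR layout)."""

    def __init__(self, mesh: UnstructuredMesh, target_cells_per_bin: float = 8.0):
        pts = mesh.points
        margin = mesh.locator_margin
        lo = pts.min(axis=0) - 1e-12 - margin
        hi = pts.max(axis=0) + 1e-12 + margin
        extent = hi - lo
        nbins = max(1, int((mesh.n_cells / target_cells_per_bin) ** (1.0 / 3.0)))
        self.origin = lo
        self.shape = np.maximum(1, (extent / extent.max() * nbins).astype(int))
        self.h = extent / self.shape
        cell_pts = pts[mesh.cells]
        cmin = cell_pts.min(axis=1) - margin
        cmax = cell_pts.max(axis=1) + margin
        bmin = np.clip(((cmin - lo) / self.h).astype(int), 0, self.shape - 1)
        bmax = np.clip(((cmax - lo) / self.h).astype(int), 0, self.shape - 1)
        counts = np.prod(bmax - bmin + 1, axis=1)
        total = int(counts.sum())
        cell_ids = np.repeat(np.arange(mesh.n_cells), counts)
        bin_ids = np.empty(total, dtype=np.int64)
        pos = 0
        sx, sy, sz = (int(s) for s in self.shape)
        for c in range(mesh.n_cells):
            x0, y0, z0 = bmin[c]
            x1, y1, z1 = bmax[c]
            for ix in range(x0, x1 + 1):
                for iy in range(y0, y1 + 1):
                    for iz in range(z0, z1 + 1):
                        bin_ids[pos] = (ix * sy + iy) * sz + iz
                        pos += 1
        order = np.lexsort((cell_ids, bin_ids))
        bin_ids = bin_ids[order]
        self.cell_ids = cell_ids[order]
        nb = sx * sy * sz
        self.starts = np.searchsorted(bin_ids, np.arange(nb + 1))

    def candidates(self, point: np.ndarray) -> np.ndarray:
        idx = ((np.asarray(point) - self.origin) / self.h).astype(int)
        if np.any(idx < 0) or np.any(idx >= self.shape):
            return np.empty(0, dtype=np.int64)
        sx, sy, sz = (int(s) for s in self.shape)
        b = (idx[0] * sy + idx[1]) * sz + idx[2]
        return self.cell_ids[self.starts[b] : self.starts[b + 1]]


# ---------------------------------------------------------------------------
# Field frames and series
# ---------------------------------------------------------------------------


@dataclass
class FieldFrame:
    """One time sample of the solution: node positions, velocity, pressure.

    In rigid runs ``node_positions`` equals the mesh reference coordinates.
    """

    time: float
    node_positions: np.ndarray
    velocity: np.ndarray
    pressure: np.ndarray

    def __post_init__(self) -> None:
        self.node_positions = np.asarray(self.node_positions, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        n = self.node_positions.shape[0]
        if self.node_positions.shape != (n, 3) or self.velocity.shape != (n, 3):
            raise FieldSeriesError("positions and velocity must have shape (n, 3)")
        if self.pressure.shape != (n,):
            raise FieldSeriesError("pressure must have shape (n,)")
        for name in ("node_positions", "velocity", "pressure"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise FieldSeriesError(f"non-finite values in frame {name} at t={self.time}")


@dataclass
class FieldSeries:
    """Ordered field frames over one or more cardiac cycles on a shared mesh."""

    mesh: UnstructuredMesh
    frames: list[FieldFrame]
    period: float
    n_cycles_stored: int = 1
    periodic: bool = True

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise FieldSeriesError("field series must contain at least one frame")
        n = self.mesh.n_nodes
        for k, fr in enumerate(self.frames):
            if fr.node_positions.shape[0] != n:
                raise FieldSeriesError(
                    f"frame {k} has {fr.node_positions.shape[0]} nodes, mesh has {n}"
                )
        times = self.times
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise FieldSeriesError("non-monotone times in field series")
        if not self.period > 0:
            raise FieldSeriesError("period must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def is_rigid(self, tol: float = 0.0) -> bool:
        ref = self.mesh.points
        return all(
            np.allclose(fr.node_positions, ref, rtol=0.0, atol=tol) for fr in self.frames
        )

    def max_displacement(self) -> float:
        """Largest node displacement from the reference over all frames (m)."""
        ref = self.mesh.points
        return max(
            float(np.linalg.norm(fr.node_positions - ref, axis=1).max())
            for fr in self.frames
        )

    def sample(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (node_positions, velocity) at absolute time
        ``t``, extending the stored cycle(s) periodically."""
        times = self.times
        t0 = times[0]
        span = times[-1] - t0
        if self.periodic:
            tau = t0 + math.fmod(t - t0, self.period)
            if tau < t0:
                tau += self.period
        else:
            tau = min(max(t, t0), times[-1])
        if tau <= times[0]:
            fr = self.frames[0]
            return fr.node_positions, fr.velocity
        if tau >= times[-1]:
            if self.periodic and span < self.period - 1e-12:
                # wrap gap between the last stored frame and the repeat of
                # the first one a full period later
                fa, fb = self.frames[-1], self.frames[0]
                tb = times[0] + self.period
                w = (tau - times[-1]) / (tb - times[-1])
            else:
                fr = self.frames[-1]
                return fr.node_positions, fr.velocity
        else:
            k = int(np.searchsorted(times, tau, side="right") - 1)
            fa, fb = self.frames[k], self.frames[k + 1]
            w = (tau - times[k]) / (times[k + 1] - times[k])
        pos = (1.0 - w) * fa.node_positions + w * fb.node_positions
        vel = (1.0 - w) * fa.velocity + w * fb.velocity
        return pos, vel


# ---------------------------------------------------------------------------
# Point location
# ---------------------------------------------------------------------------

_BARY_TOL = 1e-10


def _bary_weights(pos: np.ndarray, cells: np.ndarray, c: int, p: np.ndarray) -> np.ndarray:
    """Barycentric weights of point p in cell c (may be negative outside)."""
    verts = pos[cells[c]]
    T = (verts[1:] - verts[0]).T
    try:
        w123 = np.linalg.solve(T, p - verts[0])
    except np.linalg.LinAlgError:
        raise MeshError(f"degenerate (zero-volume) cell {c} encountered")
    return np.concatenate(([1.0 - w123.sum()], w123))


def _contains(w: np.ndarray, tol: float) -> bool:
    return bool(np.min(w) >= -tol)


def _scan_candidates(
    mesh: UnstructuredMesh,
    pos: np.ndarray,
    p: np.ndarray,
    candidates: np.ndarray,
    tol: float,
):
    """Vectorized containment test over ascending candidate cells; returns
    the lowest containing cell or None."""
    cand = np.asarray(candidates, dtype=np.int64)
    if cand.size == 0:
        return None
    verts = pos[mesh.cells[cand]]  # (k,4,3)
    w, bad = _bary_solve(verts, p - verts[:, 0])
    ok = (np.min(w, axis=1) >= -tol) & ~bad
    hits = np.nonzero(ok)[0]
    if hits.size == 0:
        return None
    i = int(hits[0])
    return int(cand[i]), w[i]


def _bary_solve(verts: np.ndarray, rhs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric weights via the explicit 3x3 (cross-product) solve.

    ``verts``: (k,4,3) tet vertices, ``rhs``: (k,3) point minus vertex 0.
    Returns (weights (k,4), degenerate mask).
    """
    e1 = verts[:, 1] - verts[:, 0]
    e2 = verts[:, 2] - verts[:, 0]
    e3 = verts[:, 3] - verts[:, 0]

    def cr(a, b):  # np.cross has heavy per-call overhead for small batches
        out = np.empty_like(a)
        out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
        out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
        out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        return out

    c23 = cr(e2, e3)
    c31 = cr(e3, e1)
    c12 = cr(e1, e2)
    det = np.einsum("ij,ij->i", e1, c23)
    bad = np.abs(det) < 1e-300
    inv = 1.0 / np.where(bad, 1.0, det)
    w = np.empty((verts.shape[0], 4))
    w[:, 1] = np.einsum("ij,ij->i", rhs, c23) * inv
    w[:, 2] = np.einsum("ij,ij->i", rhs, c31) * inv
    w[:, 3] = np.einsum("ij,ij->i", rhs, c12) * inv
    w[:, 0] = 1.0 - w[:, 1] - w[:, 2] - w[:, 3]
    return w, bad


def locate_cell(
    mesh: UnstructuredMesh,
    point: np.ndarray,
    positions: np.ndarray | None = None,
    hint: int | None = None,
    tol: float = _BARY_TOL,
):
    """Find the tetrahedron containing ``point``.

    Returns ``(cell_index, weights)`` with the four barycentric weights
    (>= -tol, summing to 1), or ``None`` if the point lies outside the mesh.

    With ``hint`` the search walks from that cell toward the point through
    face-neighbors; without a hint (or when the walk leaves the mesh) a
    uniform-grid candidate scan is used.  When the point lies exactly on a
    cell interface the tie is broken to the lowest incident cell index.
    """
    p = np.asarray(point, dtype=float)
    pos = mesh.points if positions is None else positions
    if hint is not None and 0 <= hint < mesh.n_cells:
        nbr = mesh.cell_neighbors
        c = int(hint)
        for _ in range(4 * int(mesh.n_cells ** (1 / 3)) + 64):
            w = _bary_weights(pos, mesh.cells, c, p)
            if _contains(w, tol):
                if np.min(w) < tol:  # on a face/edge/vertex: normalize tie
                    hit = _scan_candidates(mesh, pos, p, mesh.grid_candidates(p), tol)
                    if hit is not None:
                        return hit
                return c, w
            nxt = int(nbr[c, int(np.argmin(w))])
            if nxt < 0:
                break
            c = nxt
    return _scan_candidates(mesh, pos, p, mesh.grid_candidates(p), tol)


def locate_cell_brute(
    mesh: UnstructuredMesh,
    point: np.ndarray,
    positions: np.ndarray | None = None,
    tol: float = _BARY_TOL,
):
    """Exhaustive-scan reference locator (lowest containing cell index)."""
    p = np.asarray(point, dtype=float)
    pos = mesh.points if positions is None else positions
    return _scan_candidates(mesh, pos, p, np.arange(mesh.n_cells), tol)


# ---------------------------------------------------------------------------
# Boundary flux
# ---------------------------------------------------------------------------


def _patch_outward_flux(
    mesh: UnstructuredMesh, patch: str, positions: np.ndarray, velocity: np.ndarray
) -> float:
    """Exact integral of the P1 velocity's outward normal component (m³/s)."""
    faces = mesh.patch_faces(patch)
    a, b, c = (positions[faces[:, i]] for i in range(3))
    nvec = 0.5 * np.cross(b - a, c - a)  # area-weighted outward normal
    vbar = (velocity[faces[:, 0]] + velocity[faces[:, 1]] + velocity[faces[:, 2]]) / 3.0
    return float(np.einsum("ij,ij->", nvec, vbar))


def boundary_flux(mesh: UnstructuredMesh, frame: FieldFrame, patch: str) -> float:
    """Volumetric flow through a boundary patch in mL/s.

    Sign convention: positive *into* the domain for inlet patches, positive
    *out of* the domain for outlet patches; wall patches return the raw
    outward flux.
    """
    mesh._require_patch(patch)
    out = _patch_outward_flux(mesh, patch, frame.node_positions, frame.velocity)
    kind = mesh.patch_kinds[patch]
    if kind == "inlet":
        out = -out
    return out * ML_PER_M3


# ---------------------------------------------------------------------------
# Cross-sections
# ---------------------------------------------------------------------------

# edges of a tetrahedron as local vertex pairs
_TET_EDGES = np.array([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])


@dataclass
class CrossSection:
    """A planar cut through one branch: area and the per-cell polygons."""

    area_cm2: float
    polygons: list[np.ndarray]
    cells: np.ndarray


def _cut_polygon(verts: np.ndarray, d: np.ndarray) -> np.ndarray | None:
    """Intersection polygon of a tet (4x3 verts, signed distances d) with the
    d=0 plane, ordered around its centroid; None if degenerate."""
    pts = []
    for i, j in _TET_EDGES:
        if (d[i] > 0) != (d[j] > 0):
            t = d[i] / (d[i] - d[j])
            pts.append(verts[i] + t * (verts[j] - verts[i]))
    if len(pts) < 3:
        return None
    poly = np.array(pts)
    centroid = poly.mean(axis=0)
    rel = poly - centroid
    normal = np.cross(rel[0], rel[1])
    nn = np.linalg.norm(normal)
    if nn == 0.0:
        # first two directions collinear; try another pair
        normal = np.cross(rel[0], rel[-1])
        nn = np.linalg.norm(normal)
        if nn == 0.0:
            return None
    normal /= nn
    e1 = rel[0] / np.linalg.norm(rel[0])
    e2 = np.cross(normal, e1)
    ang = np.arctan2(rel @ e2, rel @ e1)
    return poly[np.argsort(ang)]


def _polygon_area(poly: np.ndarray) -> float:
    c = poly.mean(axis=0)
    v = poly - c
    s = np.zeros(3)
    for i in range(len(poly)):
        s += np.cross(v[i], v[(i + 1) % len(poly)])
    return float(0.5 * np.linalg.norm(s))


def cross_section(
    mesh: UnstructuredMesh,
    frame: FieldFrame,
    plane_point: np.ndarray,
    plane_normal: np.ndarray,
    branch: str | None = None,
) -> CrossSection:
    """Planar cross-section through a single branch of the mesh.

    The cut must intersect exactly one connected component of cells; the
    returned area (cm²) is the sum of the per-cell plane/tet intersection
    polygons evaluated at the frame's node positions.
    """
    p0 = np.asarray(plane_point, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    pos = frame.node_positions
    d = (pos - p0) @ n
    # nudge nodes exactly on the plane to one side for a well-defined cut
    d = np.where(d == 0.0, 1e-300, d)
    dc = d[mesh.cells]
    cut = (dc.min(axis=1) < 0) & (dc.max(axis=1) > 0)
    cut_cells = np.nonzero(cut)[0]
    name = branch or "branch"
    if cut_cells.size == 0:
        raise CrossSectionError(f"plane misses {name}")
    comp = _connected_components(mesh, cut_cells)
    if len(comp) > 1:
        sizes = sorted((len(c) for c in comp), reverse=True)
        raise CrossSectionError(
            f"cut intersects {len(comp)} components (cell counts {sizes}); "
            f"restrict the plane to the {name} branch"
        )
    polys: list[np.ndarray] = []
    area = 0.0
    for c in cut_cells:
        poly = _cut_polygon(pos[mesh.cells[c]], d[mesh.cells[c]])
        if poly is None:
            continue
        polys.append(poly)
        area += _polygon_area(poly)
    return CrossSection(area_cm2=area * CM2_PER_M2, polygons=polys, cells=cut_cells)


def _connected_components(mesh: UnstructuredMesh, cell_subset: np.ndarray) -> list[np.ndarray]:
    """Connected components of a cell subset under face adjacency."""
    inset = np.zeros(mesh.n_cells, dtype=bool)
    inset[cell_subset] = True
    nbr = mesh.cell_neighbors
    seen = np.zeros(mesh.n_cells, dtype=bool)
    comps = []
    for start in cell_subset:
        if seen[start]:
            continue
        stack = [int(start)]
        seen[start] = True
        comp = []
        while stack:
            c = stack.pop()
            comp.append(c)
            for nb in nbr[c]:
                if nb >= 0 and inset[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(int(nb))
        comps.append(np.array(comp))
    return comps


# ---------------------------------------------------------------------------
# I/O: legacy VTK / VTU frames + YAML manifest + patch sidecar CSV
# ---------------------------------------------------------------------------


def _write_vtk_legacy(path: Path, points: np.ndarray, cells: np.ndarray,
                      velocity: np.ndarray | None = None,
                      pressure: np.ndarray | None = None) -> None:
    n, m = points.shape[0], cells.shape[0]
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ntcpcflow field frame\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {n} double\n")
        np.savetxt(f, points, fmt="%.17g")
        f.write(f"CELLS {m} {5 * m}\n")
        np.savetxt(f, np.column_stack([np.full(m, 4, dtype=np.int64), cells]), fmt="%d")
        f.write(f"CELL_TYPES {m}\n")
        np.savetxt(f, np.full(m, 10, dtype=np.int64), fmt="%d")
        if velocity is not None or pressure is not None:
            f.write(f"POINT_DATA {n}\n")
        if velocity is not None:
            f.write("VECTORS velocity double\n")
            np.savetxt(f, velocity, fmt="%.17g")
        if pressure is not None:
            f.write("SCALARS pressure double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, pressure.reshape(-1, 1), fmt="%.17g")


def _read_vtk_legacy(path: Path):
    with open(path) as f:
        tokens = f.read().split()
    idx = {tok.upper(): i for i, tok in enumerate(tokens)}

    def _block(after: int, count: int, width: int, dtype):
        flat = np.array(tokens[after : after + count * width], dtype=dtype)
        return flat.reshape(count, width)

    if "POINTS" not in idx:
        raise FieldSeriesError(f"{path}: no POINTS block")
    i = idx["POINTS"]
    n = int(tokens[i + 1])
    points = _block(i + 3, n, 3, float)
    i = idx["CELLS"]
    m = int(tokens[i + 1])
    raw = _block(i + 3, m, 5, np.int64)
    if not np.all(raw[:, 0] == 4):
        raise FieldSeriesError(f"{path}: non-tetrahedral cells present")
    cells = raw[:, 1:]
    velocity = pressure = None
    if "VECTORS" in idx:
        velocity = _block(idx["VECTORS"] + 3, n, 3, float)
    if "SCALARS" in idx:
        # layout: SCALARS name type [numComp] LOOKUP_TABLE default <values>
        lt = idx["SCALARS"]
        while tokens[lt].upper() != "LOOKUP_TABLE":
            lt += 1
        pressure = np.array(tokens[lt + 2 : lt + 2 + n], dtype=float)
    return points, cells, velocity, pressure


def _write_vtu(path: Path, points: np.ndarray, cells: np.ndarray,
               velocity: np.ndarray | None = None,
               pressure: np.ndarray | None = None) -> None:
    n, m = points.shape[0], cells.shape[0]

    def arr(name, data, comps):
        return (
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{comps}" format="ascii">\n'
            + "\n".join(" ".join(f"{x:.17g}" for x in row) for row in np.atleast_2d(data.reshape(-1, comps)))
            + "\n</DataArray>\n"
        )

    pdata = ""
    if velocity is not None or pressure is not None:
        pdata = "<PointData>\n"
        if velocity is not None:
            pdata += arr("velocity", velocity, 3)
        if pressure is not None:
            pdata += arr("pressure", pressure, 1)
        pdata += "</PointData>\n"
    conn = " ".join(str(x) for x in cells.ravel())
    offs = " ".join(str(4 * (i + 1)) for i in range(m))
    types = " ".join("10" for _ in range(m))
    xml = (
        '<?xml version="1.0"?>\n'
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n'
        "<UnstructuredGrid>\n"
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n'
        + pdata
        + "<Points>\n" + arr("points", points, 3) + "</Points>\n"
        "<Cells>\n"
        f'<DataArray type="Int64" Name="connectivity" format="ascii">\n{conn}\n</DataArray>\n'
        f'<DataArray type="Int64" Name="offsets" format="ascii">\n{offs}\n</DataArray>\n'
        f'<DataArray type="UInt8" Name="types" format="ascii">\n{types}\n</DataArray>\n'
        "</Cells>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n"
    )
    path.write_text(xml)


def _read_vtu(path: Path):
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise FieldSeriesError(f"{path}: no <Piece> element")
    n = int(piece.get("NumberOfPoints"))
    m = int(piece.get("NumberOfCells"))

    def data(parent_tag, name, dtype, shape):
        for da in piece.findall(f".//{parent_tag}/DataArray"):
            if da.get("Name") == name:
                return np.array(da.text.split(), dtype=dtype).reshape(shape)
        return None

    pts = None
    for da in piece.findall(".//Points/DataArray"):
        pts = np.array(da.text.split(), dtype=float).reshape(n, 3)
    conn = data("Cells", "connectivity", np.int64, (m, 4))
    if pts is None or conn is None:
        raise FieldSeriesError(f"{path}: missing points or connectivity")
    velocity = data("PointData", "velocity", float, (n, 3))
    pressure = data("PointData", "pressure", float, (n,))
    return pts, conn, velocity, pressure


def _read_frame_file(path: Path):
    if path.suffix == ".vtu":
        return _read_vtu(path)
    return _read_vtk_legacy(path)


def write_field_series(series: FieldSeries, out_dir: os.PathLike | str,
                       fmt: str = "vtk") -> Path:
    """Write a field series as per-frame VTK/VTU files plus a YAML manifest.

    Returns the manifest path.  ``read_field_series`` of the result restores
    the series up to floating-point text representation.
    """
    if fmt not in ("vtk", "vtu"):
        raise ValueError(f"unknown format '{fmt}'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mesh = series.mesh
    writer = _write_vtk_legacy if fmt == "vtk" else _write_vtu
    writer(out / f"mesh.{fmt}", mesh.points, mesh.cells)
    # patch sidecar: one facet per line
    import pandas as pd

    pd.DataFrame(
        {
            "label": series.mesh.boundary_labels,
            "n0": mesh.boundary_faces[:, 0],
            "n1": mesh.boundary_faces[:, 1],
            "n2": mesh.boundary_faces[:, 2],
        }
    ).to_csv(out / "patches.csv", index=False)
    frames_meta = []
    for k, fr in enumerate(series.frames):
        fname = f"frame_{k:04d}.{fmt}"
        writer(out / fname, fr.node_positions, mesh.cells, fr.velocity, fr.pressure)
        frames_meta.append({"file": fname, "time": float(fr.time)})
    manifest = {
        "schema": 1,
        "period": float(series.period),
        "n_cycles_stored": int(series.n_cycles_stored),
        "periodic": bool(series.periodic),
        "units": {"length": "m", "velocity": "m/s", "pressure": "Pa", "time": "s"},
        "mesh": f"mesh.{fmt}",
        "patch_file": "patches.csv",
        "patch_kinds": dict(mesh.patch_kinds),
        "frames": frames_meta,
    }
    mpath = out / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return mpath


def read_field_series(manifest_path: os.PathLike | str) -> FieldSeries:
    """Read a field series written by :func:`write_field_series`.

    Raises :class:`FieldSeriesError` naming the offending file/frame for
    missing frames, inconsistent connectivity, non-monotone times or
    unlabeled patches.
    """
    import pandas as pd

    mpath = Path(manifest_path)
    manifest = yaml.safe_load(mpath.read_text())
    base = mpath.parent
    for key in ("period", "frames", "mesh", "patch_file", "patch_kinds"):
        if key not in manifest:
            raise FieldSeriesError(f"manifest missing required key '{key}'")
    times = [f["time"] for f in manifest["frames"]]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise FieldSeriesError("non-monotone times in manifest")
    mesh_file = base / manifest["mesh"]
    if not mesh_file.exists():
        raise FieldSeriesError(f"mesh file missing: {mesh_file}")
    ref_points, cells, _, _ = _read_frame_file(mesh_file)
    patches = pd.read_csv(base / manifest["patch_file"])
    if patches.empty:
        raise FieldSeriesError("patch sidecar table is empty: unlabeled patches")
    mesh = UnstructuredMesh(
        ref_points,
        cells,
        patches[["n0", "n1", "n2"]].to_numpy(dtype=np.int64),
        patches["label"].tolist(),
        manifest["patch_kinds"],
    )
    frames = []
    for k, meta in enumerate(manifest["frames"]):
        fpath = base / meta["file"]
        if not fpath.exists():
            raise FieldSeriesError(f"missing frame file: {fpath} (frame {k})")
        pts, fcells, vel, pres = _read_frame_file(fpath)
        if pts.shape[0] != ref_points.shape[0]:
            raise FieldSeriesError(
                f"frame {k} ({meta['file']}): node count {pts.shape[0]} "
                f"!= mesh node count {ref_points.shape[0]}"
            )
        if fcells.shape != cells.shape or not np.array_equal(fcells, cells):
            raise FieldSeriesError(
                f"frame {k} ({meta['file']}): connectivity differs from mesh"
            )
        if vel is None or pres is None:
            raise FieldSeriesError(
                f"frame {k} ({meta['file']}): missing velocity or pressure data"
            )
        frames.append(FieldFrame(meta["time"], pts, vel, pres))
    return FieldSeries(
        mesh=mesh,
        frames=frames,
        period=manifest["period"],
        n_cycles_stored=manifest.get("n_cycles_stored", 1),
        periodic=manifest.get("periodic", True),
    )
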