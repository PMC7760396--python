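"""Idealized TCPC geometries and analytic flow-field series with known truth.

The generator stands in for a patient-specific flow solution so every
downstream metric can be exercised at desk scale against closed forms:

* :func:`build_idealized_tcpc` meshes a four-branch junction — Fontan
  pathway (FP) and superior vena cava (SVC) inlets on a vertical duct,
  left/right pulmonary artery (LPA/RPA) outlets on a horizontal duct — as a
  Cartesian tetrahedral mesh of the union of the two circular ducts.  Caps
  are exactly planar; the boundary is closed by construction.
* :func:`make_field_series` fills the mesh with per-branch parabolic
  (Poiseuille) velocity profiles blended across the junction, either with
  rigid walls or with a prescribed radial dilation of the FP branch whose
  cavity volume is a closed-form cubic in the motion scale, so mass balance
  at the caps holds exactly.
* :func:`poiseuille_fixture` provides a body-fitted straight-pipe series
  whose pressure drop, power loss and transit times all have textbook
  closed forms, used as the analytic oracle throughout the test-suite.

Per-branch nodal profiles are rescaled once per mesh so that the discrete
facet quadrature at each cap carries exactly the prescribed flow; the
rescaling factor is 1 + O(h²) and makes inlet/outlet mass closure exact
rather than mesh-limited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .mesh_and_fields import (
    CAP_PATCHES,
    ML_PER_M3,
    FieldFrame,
    FieldSeries,
    MeshError,
    PhysicalConstants,
    ScalarWaveform,
    UnstructuredMesh,
    WALL_PATCH,
    _patch_outward_flux,
)

__all__ = [
    "SyntheticConfig",
    "WallModelParams",
    "build_idealized_tcpc",
    "build_pipe_mesh",
    "make_inflow_waveforms",
    "make_field_series",
    "poiseuille_fixture",
    "poiseuille_pressure_drop_pa",
    "analytic_volume",
    "analytic_volume_rate",
]

_CM = 1e-2
_MM = 1e-3


@dataclass(frozen=True)
class WallModelParams:
    """Linear-elastic vessel-wall parameters.

    Defaults follow the standard intra-atrial Fontan wall model: Young's
    modulus 0.07 MPa, Poisson ratio 0.3, wall thickness 2.0 mm.  The wall is
    never solved here; these parameterize the stiffness-to-motion-amplitude
    mapping used by the calibration loop in :mod:`tcpcflow.lumped_model`.
    """

    young_modulus_mpa: float = 0.07
    poisson_ratio: float = 0.3
    thickness_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.young_modulus_mpa <= 0 or self.thickness_mm <= 0:
            raise ValueError("wall modulus and thickness must be positive")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")


@dataclass(frozen=True)
class SyntheticConfig:
    """Geometry, discretization and inflow parameters of the synthetic TCPC.

    Branch radii default to the patient-scale vessel calibres implied by
    the printed cross-sectional areas (FP 3.74 cm² -> R 1.09 cm, SVC
    1.99 cm² -> R 0.80 cm) with typical pulmonary-artery calibres for the
    outlets.  The cardiac cycle is 0.86 s; the solver-scale time step is
    5e-4 s.  Inflow waveforms are configurable Fourier series around resting
    venous-return means (FP 30 mL/s, SVC 15 mL/s, ~2.7 L/min total).

    ``wall_amplitude`` is the dimensionless peak radial dilation of the FP
    branch in moving-wall mode; the default 0.013 yields a deformation index
    of ~5%, the scale observed in compliant intra-atrial pathways.
    """

    r_fp_cm: float = 1.09
    r_svc_cm: float = 0.80
    r_lpa_cm: float = 0.65
    r_rpa_cm: float = 0.65
    l_fp_cm: float = 3.0
    l_svc_cm: float = 2.5
    l_lpa_cm: float = 3.0
    l_rpa_cm: float = 3.0
    junction_offset_cm: float = 0.0
    edge_length_mm: float = 1.5
    cycle_period: float = 0.86
    time_step: float = 5.0e-4
    frame_interval: float = 0.01
    mean_inflow_fp_ml_s: float = 30.0
    mean_inflow_svc_ml_s: float = 15.0
    fp_harmonics: tuple[tuple[float, float], ...] = ((12.0, 0.0), (4.0, 1.2))
    svc_harmonics: tuple[tuple[float, float], ...] = ((3.0, 0.6),)
    lpa_fraction: float = 0.5
    fp_swirl_ratio: float = 0.3
    wall_amplitude: float = 0.013
    junction_pressure_mmhg: float = 11.0
    seed: int = 0
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self) -> None:
        for name in (
            "r_fp_cm", "r_svc_cm", "r_lpa_cm", "r_rpa_cm",
            "l_fp_cm", "l_svc_cm", "l_lpa_cm", "l_rpa_cm",
            "edge_length_mm", "cycle_period", "time_step", "frame_interval",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"SyntheticConfig.{name} must be positive")
        if not 0.0 <= self.lpa_fraction <= 1.0:
            raise ValueError("lpa_fraction must lie in [0, 1]")
        if not 0.0 <= self.wall_amplitude <= 0.3:
            raise ValueError("wall_amplitude must lie in [0, 0.3]")
        if self.frame_interval < self.time_step:
            raise ValueError("frame_interval must be >= time_step")

    # -- derived geometry (SI) ---------------------------------------------

    def radius_m(self, branch: str) -> float:
        return {"FP": self.r_fp_cm, "SVC": self.r_svc_cm,
                "LPA": self.r_lpa_cm, "RPA": self.r_rpa_cm}[branch] * _CM

    def length_m(self, branch: str) -> float:
        return {"FP": self.l_fp_cm, "SVC": self.l_svc_cm,
                "LPA": self.l_lpa_cm, "RPA": self.l_rpa_cm}[branch] * _CM

    def junction_extent_m(self, branch: str) -> float:
        """Axial distance from the junction center at which a branch clears
        the perpendicular duct, plus a fractional-radius blend margin."""
        cross = (
            max(self.r_lpa_cm, self.r_rpa_cm)
            if branch in ("FP", "SVC")
            else max(self.r_fp_cm, self.r_svc_cm)
        ) * _CM
        return cross + 0.3 * self.radius_m(branch)

    def blend_width_m(self, branch: str) -> float:
        return 0.5 * self.radius_m(branch)

    def motion_zone_m(self) -> tuple[float, float, float]:
        """(z_lo, z_hi, ramp) of the FP wall-motion window, in metres.

        The window sits on the straight FP segment between the fixed cap and
        the junction blend region, with 20% margins and cos² ramps over a
        quarter of the remaining span, so caps and junction stay fixed.
        """
        a = self.length_m("FP")
        b = self.junction_extent_m("FP") + self.blend_width_m("FP")
        span = a - b
        if span <= 0:
            raise MeshError("FP branch too short for a wall-motion window")
        m = 0.2 * span
        z_lo, z_hi = -a + m, -b - m
        return z_lo, z_hi, 0.25 * (z_hi - z_lo)

    def fp_probe_plane(self) -> tuple[np.ndarray, np.ndarray]:
        """Cut plane (point, normal) at the middle of the FP motion plateau,
        where moving-wall cross-section areas scale by the closed form."""
        z_lo, z_hi, _ = self.motion_zone_m()
        return np.array([0.0, 0.0, 0.5 * (z_lo + z_hi)]), np.array([0.0, 0.0, 1.0])

    def svc_probe_plane(self) -> tuple[np.ndarray, np.ndarray]:
        b = self.junction_extent_m("SVC") + self.blend_width_m("SVC")
        z = 0.5 * (b + self.length_m("SVC"))
        return np.array([0.0, 0.0, z]), np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# Tetrahedralization helpers
# ---------------------------------------------------------------------------


def _prisms_to_tets(bottom: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Split vertical prisms into 3 tets each, consistently across shared
    quad faces.

    Each quad face over a bottom edge (u, v) receives the diagonal leaving
    the smaller of u, v; because the three bottom ids of a prism are totally
    ordered this never produces the untetrahedralizable cyclic case, and
    neighbouring prisms agree on every shared diagonal.
    """
    order = np.argsort(bottom, axis=1)
    b = np.take_along_axis(bottom, order, axis=1)
    t = np.take_along_axis(top, order, axis=1)
    a_, b_, c_ = b[:, 0], b[:, 1], b[:, 2]
    A_, B_, C_ = t[:, 0], t[:, 1], t[:, 2]
    tets = np.empty((bottom.shape[0], 3, 4), dtype=np.int64)
    tets[:, 0] = np.stack([a_, b_, c_, C_], axis=1)
    tets[:, 1] = np.stack([a_, b_, C_, B_], axis=1)
    tets[:, 2] = np.stack([a_, B_, C_, A_], axis=1)
    return tets.reshape(-1, 4)


def _boundary_faces_of(cells: np.ndarray) -> np.ndarray:
    """Unpaired (boundary) faces of a tet mesh, as unsorted node triples."""
    f = np.stack(
        [cells[:, [1, 2, 3]], cells[:, [0, 2, 3]],
         cells[:, [0, 1, 3]], cells[:, [0, 1, 2]]],
        axis=1,
    ).reshape(-1, 3)
    fs = np.sort(f, axis=1)
    order = np.lexsort(fs.T)
    fs_sorted = fs[order]
    dup = np.zeros(fs_sorted.shape[0], dtype=bool)
    same = np.all(fs_sorted[1:] == fs_sorted[:-1], axis=1)
    dup[1:] |= same
    dup[:-1] |= same
    return f[order[~dup]]


# ---------------------------------------------------------------------------
# Straight-pipe mesh (body-fitted, extruded disk)
# ---------------------------------------------------------------------------


def _disk_triangulation(radius: float, edge: float) -> tuple[np.ndarray, np.ndarray]:
    """Structured triangulation of a disk: rings of 6j nodes at radius j*R/m."""
    m = max(1, round(radius / edge))
    pts = [(0.0, 0.0)]
    rings: list[list[int]] = [[0]]
    for j in range(1, m + 1):
        n = 6 * j
        start = len(pts)
        r = radius * j / m
        ang = 2.0 * np.pi * np.arange(n) / n
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
        rings.append(list(range(start, start + n)))
    tris: list[tuple[int, int, int]] = []
    for j in range(1, m + 1):
        inner, outer = rings[j - 1], rings[j]
        n1, n2 = len(inner), len(outer)
        if n1 == 1:
            for i in range(n2):
                tris.append((inner[0], outer[i], outer[(i + 1) % n2]))
            continue
        i1 = i2 = 0
        while i1 < n1 or i2 < n2:
            f1 = (i1 + 1) / n1
            f2 = (i2 + 1) / n2
            if i1 < n1 and (i2 == n2 or f1 <= f2):
                tris.append((inner[i1 % n1], inner[(i1 + 1) % n1], outer[i2 % n2]))
                i1 += 1
            else:
                tris.append((outer[i2 % n2], outer[(i2 + 1) % n2], inner[i1 % n1]))
                i2 += 1
    return np.asarray(pts), np.asarray(tris, dtype=np.int64)


def build_pipe_mesh(
    radius_cm: float,
    length_cm: float,
    edge_length_mm: float = 1.5,
    inlet_label: str = "FP",
    outlet_label: str = "LPA",
) -> UnstructuredMesh:
    """Body-fitted tetrahedral mesh of a straight circular pipe along +z.

    The inlet cap sits at z=0, the outlet at z=L; caps are exactly planar
    and the lateral surface is labeled WALL.
    """
    R, L, h = radius_cm * _CM, length_cm * _CM, edge_length_mm * _MM
    disk, tris = _disk_triangulation(R, h)
    n_layer = disk.shape[0]
    nk = max(1, round(L / h))
    z = np.linspace(0.0, L, nk + 1)
    points = np.empty((n_layer * (nk + 1), 3))
    for k, zk in enumerate(z):
        points[k * n_layer : (k + 1) * n_layer, :2] = disk
        points[k * n_layer : (k + 1) * n_layer, 2] = zk
    cells = []
    for k in range(nk):
        bottom = tris + k * n_layer
        top = tris + (k + 1) * n_layer
        cells.append(_prisms_to_tets(bottom, top))
    cells = np.concatenate(cells)
    faces = _boundary_faces_of(cells)
    fz = points[faces, 2]
    on_in = np.all(np.abs(fz - 0.0) < 1e-12, axis=1)
    on_out = np.all(np.abs(fz - L) < 1e-12, axis=1)
    labels = np.where(on_in, inlet_label, np.where(on_out, outlet_label, WALL_PATCH))
    return UnstructuredMesh(
        points, cells, faces, labels,
        {inlet_label: "inlet", outlet_label: "outlet", WALL_PATCH: "wall"},
    )


# ---------------------------------------------------------------------------
# Idealized TCPC mesh (Cartesian tetrahedralization of two crossed ducts)
# ---------------------------------------------------------------------------


def _inside_tcpc(config: SyntheticConfig, xyz: np.ndarray) -> np.ndarray:
    x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    zoff = config.junction_offset_cm * _CM
    r_v = np.where(z < 0, config.radius_m("FP"), config.radius_m("SVC"))
    vert = (x * x + y * y < r_v * r_v)
    vert &= (z >= -config.length_m("FP")) & (z <= config.length_m("SVC"))
    r_h = np.where(x < 0, config.radius_m("LPA"), config.radius_m("RPA"))
    horiz = (y * y + (z - zoff) ** 2 < r_h * r_h)
    horiz &= (x >= -config.length_m("LPA")) & (x <= config.length_m("RPA"))
    return vert | horiz


def build_idealized_tcpc(config: SyntheticConfig) -> UnstructuredMesh:
    """Watertight labeled tetrahedral mesh of the idealized four-branch TCPC.

    The union of the vertical (FP/SVC) and horizontal (LPA/RPA) circular
    ducts is voxelized on a Cartesian grid of the configured edge length and
    each kept hexahedron is split into six tetrahedra with globally
    consistent face diagonals.  The four cap patches are exactly planar;
    construction is deterministic for a fixed config.
    """
    zoff = config.junction_offset_cm * _CM
    r_pa = max(config.radius_m("LPA"), config.radius_m("RPA"))
    if abs(zoff) + r_pa >= config.length_m("SVC") or abs(zoff) + r_pa >= config.length_m("FP"):
        raise MeshError("junction offset pushes the PA duct off the vertical duct")
    if not (-config.radius_m("FP") < zoff < config.radius_m("SVC")):
        raise MeshError("junction offset produces a non-manifold junction: "
                        "the PA axis misses the vertical duct")
    for br in CAP_PATCHES:
        if config.length_m(br) <= config.junction_extent_m(br) + config.blend_width_m(br):
            raise MeshError(f"branch {br} too short to clear the junction blend region")

    h = config.edge_length_mm * _MM
    x0, x1 = -config.length_m("LPA"), config.length_m("RPA")
    ymax = max(config.radius_m(b) for b in CAP_PATCHES)
    y0, y1 = -ymax, ymax
    z0, z1 = -config.length_m("FP"), config.length_m("SVC")
    # odd x/y cell counts keep the node lattice clear of the x=0 / y=0
    # symmetry planes (otherwise symmetric configs strand seeds on the
    # zero-lateral-velocity plane)
    nx = max(3, round((x1 - x0) / h)) | 1
    ny = max(3, round((y1 - y0) / h)) | 1
    nz = max(2, round((z1 - z0) / h))
    xg = np.linspace(x0, x1, nx + 1)
    yg = np.linspace(y0, y1, ny + 1)
    zg = np.linspace(z0, z1, nz + 1)

    # hex centers and inclusion
    cx = 0.5 * (xg[:-1] + xg[1:])
    cy = 0.5 * (yg[:-1] + yg[1:])
    cz = 0.5 * (zg[:-1] + zg[1:])
    CX, CY, CZ = np.meshgrid(cx, cy, cz, indexing="ij")
    centers = np.column_stack([CX.ravel(), CY.ravel(), CZ.ravel()])
    keep = _inside_tcpc(config, centers).reshape(nx, ny, nz)
    if not keep.any():
        raise MeshError("no grid cell lies inside the configured geometry")

    def nid(ix, iy, iz):
        return (ix * (ny + 1) + iy) * (nz + 1) + iz

    ix, iy, iz = np.nonzero(keep)
    c000 = nid(ix, iy, iz)
    c100 = nid(ix + 1, iy, iz)
    c110 = nid(ix + 1, iy + 1, iz)
    c010 = nid(ix, iy + 1, iz)
    dz = 1  # +1 in iz == +1 in flat node id
    bottomA = np.stack([c000, c100, c110], axis=1)
    bottomB = np.stack([c000, c110, c010], axis=1)
    cells = np.concatenate(
        [_prisms_to_tets(bottomA, bottomA + dz), _prisms_to_tets(bottomB, bottomB + dz)]
    )
    # compress to used nodes
    used, inv = np.unique(cells, return_inverse=True)
    cells = inv.reshape(cells.shape).astype(np.int64)
    uix = used // ((ny + 1) * (nz + 1))
    rem = used % ((ny + 1) * (nz + 1))
    uiy = rem // (nz + 1)
    uiz = rem % (nz + 1)
    points = np.column_stack([xg[uix], yg[uiy], zg[uiz]])

    faces = _boundary_faces_of(cells)
    fpts = points[faces]
    labels = np.full(faces.shape[0], WALL_PATCH, dtype=object)
    tol = 1e-12
    labels[np.all(np.abs(fpts[:, :, 2] - z0) < tol, axis=1)] = "FP"
    labels[np.all(np.abs(fpts[:, :, 2] - z1) < tol, axis=1)] = "SVC"
    labels[np.all(np.abs(fpts[:, :, 0] - x0) < tol, axis=1)] = "LPA"
    labels[np.all(np.abs(fpts[:, :, 0] - x1) < tol, axis=1)] = "RPA"
    mesh = UnstructuredMesh(
        points, cells, faces, labels,
        {"FP": "inlet", "SVC": "inlet", "LPA": "outlet", "RPA": "outlet",
         WALL_PATCH: "wall"},
    )
    for cap in CAP_PATCHES:
        if not np.any(mesh.boundary_labels == cap):
            raise MeshError(f"cap patch {cap} has no facets at this resolution")
    return mesh


# ---------------------------------------------------------------------------
# Inflow waveforms
# ---------------------------------------------------------------------------


def _inflow_fn(mean: float, harmonics, period: float) -> Callable[[np.ndarray], np.ndarray]:
    def q(t):
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, float(mean))
        for k, (amp, phase) in enumerate(harmonics, start=1):
            out = out + amp * np.cos(2.0 * np.pi * k * t / period - phase)
        return out
    return q


def make_inflow_waveforms(config: SyntheticConfig) -> dict[str, ScalarWaveform]:
    """Periodic FP and SVC inflow waveforms (mL/s) sampled at frame times.

    Each waveform is its configured mean plus a truncated Fourier series of
    (amplitude, phase) harmonics of the cardiac cycle.
    """
    T = config.cycle_period
    n = max(1, round(T / config.frame_interval))
    times = np.linspace(0.0, T, n + 1)
    out = {}
    for br, mean, harm in (
        ("FP", config.mean_inflow_fp_ml_s, config.fp_harmonics),
        ("SVC", config.mean_inflow_svc_ml_s, config.svc_harmonics),
    ):
        out[br] = ScalarWaveform(times, _inflow_fn(mean, harm, T)(times), unit="mL/s")
    return out


# ---------------------------------------------------------------------------
# Field synthesis
# ---------------------------------------------------------------------------

_BRANCH_GEOM = {
    # flow direction (unit), axial coordinate sign picking distance from junction
    "FP": {"dir": np.array([0.0, 0.0, 1.0]), "axis": "z", "sign": -1},
    "SVC": {"dir": np.array([0.0, 0.0, -1.0]), "axis": "z", "sign": +1},
    "LPA": {"dir": np.array([-1.0, 0.0, 0.0]), "axis": "x", "sign": -1},
    "RPA": {"dir": np.array([1.0, 0.0, 0.0]), "axis": "x", "sign": +1},
}


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _branch_fields(config: SyntheticConfig, mesh: UnstructuredMesh):
    """Per-branch static nodal data: profile shape, blend weight, distances."""
    pts = mesh.points
    zoff = config.junction_offset_cm * _CM
    data = {}
    for br, geom in _BRANCH_GEOM.items():
        R = config.radius_m(br)
        j = config.junction_extent_m(br)
        if geom["axis"] == "z":
            rho2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
            d = geom["sign"] * pts[:, 2]
            r_eff = np.full(pts.shape[0], R)
        else:
            rho2 = pts[:, 1] ** 2 + (pts[:, 2] - zoff) ** 2
            d = geom["sign"] * pts[:, 0]
            # outlet capture funnel: at the junction the PA field spans the
            # whole vertical-duct cross-section (caval flow turns into the
            # PAs there), narrowing to the true PA radius by the end of the
            # junction region -- without it the junction corners above the
            # PA calibre would be stagnation traps
            r_vert = max(config.radius_m("FP"), config.radius_m("SVC"))
            r_big = 1.6 * r_vert
            taper = np.clip(1.0 - np.abs(pts[:, 0]) / j, 0.0, 1.0)
            r_eff = R + (r_big - R) * taper
        shape = np.clip(1.0 - rho2 / (r_eff * r_eff), 0.0, None)  # parabolic profile
        dirfield = np.broadcast_to(geom["dir"], (pts.shape[0], 3)).copy()
        if br == "FP" and config.fp_swirl_ratio != 0.0:
            # secondary (swirling) component of the caval inflow, solid-body
            # scaled: tangential at the cap (leaves the cap flux untouched)
            # and carries near-axis particles off the junction's stagnation
            # plane, as real asymmetric caval inflow does
            s = config.fp_swirl_ratio / R
            dirfield[:, 0] += -s * pts[:, 1]
            dirfield[:, 1] += s * pts[:, 0]
        if geom["axis"] == "x":
            # damp the funnel toward the *union* wall (whichever duct wall
            # is nearest) so the lateral pull respects no-slip without
            # killing it in the duct-intersection corner pockets
            rho_v2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
            v_lin = np.clip(1.0 - rho_v2 / (r_vert * r_vert), 0.0, None)
            pa_lin = np.clip(1.0 - rho2 / (R * R), 0.0, None)
            damp = np.sqrt(np.maximum(v_lin, pa_lin))
            shape = shape * (taper * damp + (1.0 - taper))
            # converging-nozzle radial component: streamlines follow the
            # shrinking funnel envelope rho ~ r_eff(x), so v_rho/v_axial =
            # (d r_eff / d x_toward_cap) * rho / r_eff -- without it
            # particles stall on the funnel lip at the PA entrance
            rho = np.sqrt(rho2)
            conv = np.where((d > 0.0) & (d < j), -(r_big - R) / j, 0.0) * rho / r_eff
            inv_rho = np.where(rho > 1e-14, 1.0 / rho, 0.0)
            dirfield[:, 1] += conv * pts[:, 1] * inv_rho
            dirfield[:, 2] += conv * (pts[:, 2] - zoff) * inv_rho
        inside = rho2 < r_eff * r_eff * 1.0001
        inside = rho2 < r_eff * r_eff * 1.0001
        w = config.blend_width_m(br)
        # small junction-core floor so the partition of unity never vanishes
        # at the junction center; it dies off on the branch's far side (so
        # opposed branch fields do not cancel across the junction) and well
        # before the caps (so cap profiles stay pure single-branch and the
        # cap-flux calibration is exact)
        floor = 0.01 * _smoothstep((d + 0.75 * R) / (0.5 * R))
        psi = inside * (floor + _smoothstep((d - j) / w))
        data[br] = {"shape": shape, "psi": psi, "d": d, "R": R,
                    "dir": geom["dir"], "dirfield": dirfield}
    total = sum(b["psi"] for b in data.values())
    total = np.where(total > 0, total, 1.0)
    for br in data:
        data[br]["phi"] = data[br]["psi"] / total
    return data


def _wall_node_normals(mesh: UnstructuredMesh) -> tuple[np.ndarray, np.ndarray]:
    """Wall node indices and their averaged outward facet normals."""
    faces = mesh.patch_faces(WALL_PATCH)
    a, b, c = (mesh.points[faces[:, i]] for i in range(3))
    fn = np.cross(b - a, c - a)  # area-weighted outward
    acc = np.zeros_like(mesh.points)
    np.add.at(acc, faces[:, 0], fn)
    np.add.at(acc, faces[:, 1], fn)
    np.add.at(acc, faces[:, 2], fn)
    nodes = mesh.patch_nodes(WALL_PATCH)
    nrm = acc[nodes]
    nrm /= np.maximum(np.linalg.norm(nrm, axis=1), 1e-300)[:, None]
    return nodes, nrm


def _motion_window(config: SyntheticConfig, z: np.ndarray) -> np.ndarray:
    """Axial window of the FP wall motion: cos² ramps around a plateau,
    vanishing at the FP cap and before the junction."""
    z_lo, z_hi, ramp = config.motion_zone_m()
    w = np.zeros_like(z)
    up = (z > z_lo) & (z < z_lo + ramp)
    w[up] = np.sin(0.5 * np.pi * (z[up] - z_lo) / ramp) ** 2
    w[(z >= z_lo + ramp) & (z <= z_hi - ramp)] = 1.0
    down = (z > z_hi - ramp) & (z < z_hi)
    w[down] = np.sin(0.5 * np.pi * (z_hi - z[down]) / ramp) ** 2
    return w


def _deformed_positions(mesh: UnstructuredMesh, window: np.ndarray,
                        eps: float, s: float) -> np.ndarray:
    f = 1.0 + eps * s * window
    pos = mesh.points.copy()
    pos[:, 0] *= f
    pos[:, 1] *= f
    return pos


def _volume_polynomial(mesh: UnstructuredMesh, window: np.ndarray,
                       eps: float) -> np.ndarray:
    """Coefficients (a0..a3) of the exact mesh volume V(s) = sum tet volumes
    under the radial dilation map, a cubic polynomial in the motion scale s."""
    svals = np.array([-1.0, -1.0 / 3.0, 1.0 / 3.0, 1.0])
    from .mesh_and_fields import _tet_volumes

    vols = np.array([
        _tet_volumes(_deformed_positions(mesh, window, eps, s), mesh.cells).sum()
        for s in svals
    ])
    V = np.vander(svals, 4, increasing=True)
    return np.linalg.solve(V, vols)


def analytic_volume(mesh: UnstructuredMesh, config: SyntheticConfig,
                    times: np.ndarray) -> ScalarWaveform:
    """Closed-form cavity volume V(t) (mL) of the moving-wall series."""
    window = _motion_window(config, mesh.points[:, 2])
    coef = _volume_polynomial(mesh, window, config.wall_amplitude)
    s = np.sin(2.0 * np.pi * np.asarray(times) / config.cycle_period)
    v = coef[0] + coef[1] * s + coef[2] * s**2 + coef[3] * s**3
    return ScalarWaveform(times, v * ML_PER_M3, unit="mL")


def analytic_volume_rate(mesh: UnstructuredMesh, config: SyntheticConfig,
                         times: np.ndarray) -> ScalarWaveform:
    """Closed-form dV/dt (mL/s) of the moving-wall series."""
    if config.wall_amplitude == 0.0:
        return ScalarWaveform(times, np.zeros(len(times)), unit="mL/s")
    window = _motion_window(config, mesh.points[:, 2])
    coef = _volume_polynomial(mesh, window, config.wall_amplitude)
    om = 2.0 * np.pi / config.cycle_period
    t = np.asarray(times, dtype=float)
    s = np.sin(om * t)
    sdot = om * np.cos(om * t)
    dv = (coef[1] + 2.0 * coef[2] * s + 3.0 * coef[3] * s**2) * sdot
    return ScalarWaveform(times, dv * ML_PER_M3, unit="mL/s")


def make_field_series(
    mesh: UnstructuredMesh,
    config: SyntheticConfig,
    mode: Literal["rigid", "moving"] = "rigid",
) -> FieldSeries:
    """Analytic velocity/pressure frames over one cardiac cycle.

    Velocity is the per-branch parabolic profile carrying that branch's
    instantaneous flow, blended by a partition of unity across the junction;
    each cap profile is rescaled so the discrete facet flux equals the
    prescribed flow exactly.  Pressure drops linearly along each branch at
    its Poiseuille resistance around a common junction pressure.

    In ``moving`` mode the FP branch dilates radially by
    ``wall_amplitude * sin(2 pi t / T)`` inside an axial window (caps and
    junction fixed); outlet flows are reduced by the exact cavity volume
    rate dV/dt so global mass balance holds to machine precision, and the
    wall-motion velocity field is added so near-wall fluid follows the wall.
    """
    if mode not in ("rigid", "moving"):
        raise ValueError(f"invalid mode '{mode}': expected 'rigid' or 'moving'")
    cfg = config
    cst = cfg.constants
    T = cfg.cycle_period
    n = max(2, round(T / cfg.frame_interval))
    times = np.linspace(0.0, T, n + 1)
    branch = _branch_fields(cfg, mesh)

    wall_nodes, wall_normals = _wall_node_normals(mesh)

    def project_wall(v: np.ndarray) -> np.ndarray:
        """No-penetration at the discrete wall: remove the wall-normal
        velocity component at wall nodes (the analytic profiles vanish on
        the ideal duct surface, not on the mesh's actual boundary facets).
        Linear, so it commutes with the flux calibration below."""
        vn = np.einsum("ij,ij->i", v[wall_nodes], wall_normals)
        v[wall_nodes] -= vn[:, None] * wall_normals
        return v

    # discrete cap-flux normalization of the unit-flow profile
    cal = {}
    for br in CAP_PATCHES:
        b = branch[br]
        unit_vel = (b["phi"] * b["shape"] * 2.0 / (np.pi * b["R"] ** 2))[:, None] * b["dirfield"]
        unit_vel = project_wall(unit_vel)
        flux = _patch_outward_flux(mesh, br, mesh.points, unit_vel)
        if mesh.patch_kinds[br] == "inlet":
            flux = -flux
        if abs(flux) < 1e-30:
            raise MeshError(f"degenerate cap flux on patch {br}")
        cal[br] = 1.0 / flux  # multiplies a flow in m^3/s

    q_fp = _inflow_fn(cfg.mean_inflow_fp_ml_s, cfg.fp_harmonics, T)
    q_svc = _inflow_fn(cfg.mean_inflow_svc_ml_s, cfg.svc_harmonics, T)

    moving = mode == "moving" and cfg.wall_amplitude > 0.0
    window = _motion_window(cfg, mesh.points[:, 2])
    if moving:
        coef = _volume_polynomial(mesh, window, cfg.wall_amplitude)
        om = 2.0 * np.pi / T
        # cumulative storage fraction along the FP axis (for the local axial flow)
        z_lo, z_hi, _ = cfg.motion_zone_m()
        zf = np.linspace(z_lo, z_hi, 801)
        wf = _motion_window(cfg, zf)
        gcum = np.concatenate([[0.0], np.cumsum(0.5 * (wf[1:] + wf[:-1]) * np.diff(zf))])
        gcum /= gcum[-1]
        g_node = np.interp(mesh.points[:, 2], zf, gcum, left=0.0, right=1.0)
    mu = cst.dynamic_viscosity
    p_j = cst.pa(cfg.junction_pressure_mmhg)

    frames = []
    for t in times:
        qf = float(q_fp(t)) / ML_PER_M3  # m^3/s
        qs = float(q_svc(t)) / ML_PER_M3
        if moving:
            s = math.sin(om * t)
            sdot = om * math.cos(om * t)
            dvdt = float((coef[1] + 2 * coef[2] * s + 3 * coef[3] * s**2) * sdot)
            pos = _deformed_positions(mesh, window, cfg.wall_amplitude, s)
        else:
            dvdt = 0.0
            pos = mesh.points
        q_out = qf + qs - dvdt
        flows = {
            "SVC": qs,
            "LPA": cfg.lpa_fraction * q_out,
            "RPA": (1.0 - cfg.lpa_fraction) * q_out,
        }
        vel = np.zeros_like(mesh.points)
        pres = np.full(mesh.n_nodes, p_j)
        for br in CAP_PATCHES:
            b = branch[br]
            if br == "FP":
                q_node = qf - dvdt * g_node if moving else np.full(mesh.n_nodes, qf)
            else:
                q_node = np.full(mesh.n_nodes, flows[br])
            base = b["phi"] * b["shape"] * (2.0 * cal[br] / (np.pi * b["R"] ** 2))
            vel += (base * q_node)[:, None] * b["dirfield"]
            # linear pressure drop at the branch's Poiseuille resistance
            g_res = 8.0 * mu / (np.pi * b["R"] ** 4)
            q_ref = qf if br == "FP" else flows[br]
            sign = 1.0 if mesh.patch_kinds[br] == "inlet" else -1.0
            pres += b["phi"] * sign * g_res * q_ref * np.clip(b["d"], 0.0, None)
        vel = project_wall(vel)
        if moving:
            # wall-motion velocity added after the projection: the fluid
            # velocity *relative to the wall* then has zero normal component
            sfac = cfg.wall_amplitude * sdot * window
            vel[:, 0] += sfac * mesh.points[:, 0]
            vel[:, 1] += sfac * mesh.points[:, 1]
        frames.append(FieldFrame(float(t), pos, vel, pres))
    return FieldSeries(mesh=mesh, frames=frames, period=T, n_cycles_stored=1,
                       periodic=True)


# ---------------------------------------------------------------------------
# Poiseuille fixture (analytic oracle carrier)
# ---------------------------------------------------------------------------


def poiseuille_pressure_drop_pa(radius_cm: float, length_cm: float,
                                flow_ml_s: float,
                                constants: PhysicalConstants = PhysicalConstants()) -> float:
    """Hagen-Poiseuille pressure drop dP = 8 mu L Q / (pi R^4) in Pa."""
    R, L = radius_cm * _CM, length_cm * _CM
    Q = flow_ml_s / ML_PER_M3
    return 8.0 * constants.dynamic_viscosity * L * Q / (np.pi * R**4)


def poiseuille_fixture(
    radius_cm: float,
    length_cm: float,
    flow_ml_s: float,
    constants: PhysicalConstants = PhysicalConstants(),
    edge_length_mm: float = 1.5,
    n_frames: int = 2,
) -> FieldSeries:
    """Steady Poiseuille flow in a straight pipe, exact at the nodes.

    Velocity is the parabolic profile u_z(r) = 2Q/(pi R^2)(1 - r^2/R^2) and
    pressure falls linearly from 8 mu L Q/(pi R^4) at the inlet (labeled FP,
    z=0) to zero at the outlet (labeled LPA, z=L).
    """
    if min(radius_cm, length_cm, flow_ml_s) <= 0:
        raise ValueError("radius, length and flow must be positive")
    mesh = build_pipe_mesh(radius_cm, length_cm, edge_length_mm)
    R, L = radius_cm * _CM, length_cm * _CM
    Q = flow_ml_s / ML_PER_M3
    r2 = mesh.points[:, 0] ** 2 + mesh.points[:, 1] ** 2
    uz = 2.0 * Q / (np.pi * R * R) * np.clip(1.0 - r2 / (R * R), 0.0, None)
    vel = np.zeros_like(mesh.points)
    vel[:, 2] = uz
    dp = poiseuille_pressure_drop_pa(radius_cm, length_cm, flow_ml_s, constants)
    pres = dp * (1.0 - mesh.points[:, 2] / L)
    times = np.linspace(0.0, constants.cycle_period, max(1, n_frames))
    frames = [FieldFrame(float(t), mesh.points, vel, pres) for t in times]
    return FieldSeries(mesh=mesh, frames=frames, period=constants.cycle_period,
                       n_cycles_stored=1, periodic=True)
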