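"""Axisymmetric corneoscleral shell geometry and quadratic triangular meshing.

The shell cross-section is built from ellipse segments in the (r, z)
half-plane, z along the optic axis with the corneal apex at the maximum z
(placed at z = 0) and the posterior pole at the minimum z.  All lengths are
in millimetres.

Construction
------------
* Cornea: a conic with apical radius of curvature ``R_c`` and eccentricity
  ``e`` (prolate ellipse with semi-axes ``a_r = R_c/sqrt(1-e^2)``,
  ``a_z = R_c/(1-e^2)``), trimmed at the white-to-white chord
  ``r = WTW/2``.
* Sclera: an oblate ellipse with equatorial semi-axis equal to the scleral
  radius of curvature and axial (posterior) semi-axis scaled by the
  posterior-to-equatorial radius ratio; its centre on the axis is placed so
  the ellipse passes through the corneal trim point (the limbal junction).
* The cornea and sclera are divided by the radial line through the scleral
  ellipse centre and the junction; a narrow angular transition band around
  that line receives blended material properties and a refined mesh.
* Wall thickness is interpolated with a monotone (PCHIP) spline through the
  printed stations -- central cornea, anterior / equatorial / posterior
  sclera -- as a function of the polar angle about the scleral centre, and
  the inner boundary is the outer boundary offset inward along its normal by
  that thickness.

The mesher lays a structured grid in (angle, thickness-fraction) space and
emits 6-node quadratic triangles whose mid-edge nodes lie on the true curved
surfaces.  ``target_element_size`` controls the meridional spacing; the
number of through-thickness layers is ``ceil(mean thickness / size)`` (at
least 2), and the meridional spacing is halved inside the transition band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

__all__ = [
    "EyeGeometry",
    "ShellSection",
    "ShellMesh",
    "GeometryError",
    "MeshError",
    "build_geometry",
    "generate_mesh",
    "spherical_geometry",
    "BASELINE_GEOMETRY",
]


class GeometryError(ValueError):
    """Shell cross-section could not be constructed."""


class MeshError(ValueError):
    """Shell cross-section could not be meshed at the requested density."""


@dataclass(frozen=True)
class EyeGeometry:
    """Dimensions of the axisymmetric corneoscleral shell (mm / degrees).

    Defaults are the porcine averages: CCT 0.96 mm, corneal radius of
    curvature 7.5 mm with eccentricity 0.5, WTW 13.5 mm, scleral radius
    12.8 mm, anterior/equatorial/posterior scleral thickness
    0.89/0.58/1.12 mm, posterior-to-equatorial radius ratio 0.86.
    """

    central_corneal_thickness: float = 0.96
    corneal_radius_of_curvature: float = 7.5
    corneal_eccentricity: float = 0.5
    white_to_white_diameter: float = 13.5
    scleral_radius_of_curvature: float = 12.8
    anterior_scleral_thickness: float = 0.89
    equatorial_scleral_thickness: float = 0.58
    posterior_scleral_thickness: float = 1.12
    posterior_to_equatorial_radius_ratio: float = 0.86
    transition_zone_angular_width: float = 5.0

    def __post_init__(self) -> None:
        lengths = {
            "central_corneal_thickness": self.central_corneal_thickness,
            "corneal_radius_of_curvature": self.corneal_radius_of_curvature,
            "white_to_white_diameter": self.white_to_white_diameter,
            "scleral_radius_of_curvature": self.scleral_radius_of_curvature,
            "anterior_scleral_thickness": self.anterior_scleral_thickness,
            "equatorial_scleral_thickness": self.equatorial_scleral_thickness,
            "posterior_scleral_thickness": self.posterior_scleral_thickness,
        }
        for name, value in lengths.items():
            if value <= 0:
                raise GeometryError(f"{name} must be strictly positive")
        if not 0.0 <= self.corneal_eccentricity < 1.0:
            raise GeometryError("corneal_eccentricity must lie in [0, 1)")
        if not 0.0 < self.posterior_to_equatorial_radius_ratio <= 1.0:
            raise GeometryError("posterior_to_equatorial_radius_ratio must lie in (0, 1]")
        if self.transition_zone_angular_width <= 0:
            raise GeometryError("transition_zone_angular_width must be positive")
        p = 1.0 - self.corneal_eccentricity**2
        a_r = self.corneal_radius_of_curvature / np.sqrt(p)
        if self.white_to_white_diameter / 2.0 >= a_r:
            raise GeometryError(
                "white-to-white radius exceeds the corneal ellipse equatorial semi-axis"
            )

    @classmethod
    def from_dict(cls, data: dict) -> "EyeGeometry":
        return cls(**{k: float(v) for k, v in data.items()})


BASELINE_GEOMETRY = EyeGeometry()


def spherical_geometry(mid_surface_radius: float, thickness: float) -> EyeGeometry:
    """Degenerate uniform spherical shell, used by the closed-form oracle tests.

    Corneal and scleral radii coincide, eccentricity is zero and the radius
    ratio is one, so inner and outer boundaries are concentric circles of
    radius ``mid_surface_radius -/+ thickness/2``.
    """
    r_out = mid_surface_radius + 0.5 * thickness
    return EyeGeometry(
        central_corneal_thickness=thickness,
        corneal_radius_of_curvature=r_out,
        corneal_eccentricity=0.0,
        white_to_white_diameter=r_out,  # junction chord at r = r_out/2, arbitrary
        scleral_radius_of_curvature=r_out,
        anterior_scleral_thickness=thickness,
        equatorial_scleral_thickness=thickness,
        posterior_scleral_thickness=thickness,
        posterior_to_equatorial_radius_ratio=1.0,
    )


@dataclass
class ShellSection:
    """Parametric description of the shell cross-section.

    The outer and inner boundaries are smooth curves parametrised by the
    polar angle ``theta`` about the scleral ellipse centre (theta = 0 at the
    anterior axis through the corneal apex, theta = pi at the posterior
    pole).  ``theta_junction`` is the angle of the cornea--sclera dividing
    line, ``band_halfwidth`` half the transition-zone angular width (rad).
    """

    params: EyeGeometry
    theta_dense: np.ndarray
    outer_dense: np.ndarray  # (N, 2) of (r, z)
    inner_dense: np.ndarray
    #: raw inward-offset points, index-aligned with ``outer_dense``: each is
    #: its outer point displaced by the local thickness along the outer normal
    inner_offset_dense: np.ndarray
    theta_junction: float
    band_halfwidth: float
    scleral_center_z: float
    thickness_stations: tuple[tuple[float, float], ...]
    _outer_spline: CubicSpline = field(repr=False, default=None)
    _inner_spline: CubicSpline = field(repr=False, default=None)
    _thickness: PchipInterpolator = field(repr=False, default=None)

    def outer(self, theta):
        """Outer boundary point(s) (r, z) at polar angle(s) theta."""
        return self._outer_spline(theta)

    def inner(self, theta):
        return self._inner_spline(theta)

    def thickness_at(self, theta):
        """Prescribed wall thickness (mm) at polar angle theta."""
        return self._thickness(theta)

    def cornea_weight(self, theta):
        """Corneal material fraction: 1 anterior of the transition band,
        0 posterior of it, linear in between."""
        theta = np.asarray(theta, dtype=float)
        lo = self.theta_junction - self.band_halfwidth
        hi = self.theta_junction + self.band_halfwidth
        w = np.clip((hi - theta) / (hi - lo), 0.0, 1.0)
        return w if w.ndim else float(w)

    def midsurface_arclength(self) -> np.ndarray:
        mid = 0.5 * (self.outer_dense + self.inner_dense)
        seg = np.linalg.norm(np.diff(mid, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


def _corneal_ellipse(params: EyeGeometry):
    """Semi-axes and trim angle of the corneal conic (apex at z = 0)."""
    p = 1.0 - params.corneal_eccentricity**2
    a_r = params.corneal_radius_of_curvature / np.sqrt(p)
    a_z = params.corneal_radius_of_curvature / p
    r_j = params.white_to_white_diameter / 2.0
    phi_j = np.arcsin(r_j / a_r)
    return a_r, a_z, phi_j


def build_geometry(params: EyeGeometry, n_dense: int = 4000) -> ShellSection:
    """Construct the closed outer/inner boundary curves and the dividing line.

    Raises :class:`GeometryError` if the inward thickness offset folds the
    inner boundary (thickness exceeding the local radius of curvature), with
    the offending angular station named.
    """
    a_r, a_z, phi_j = _corneal_ellipse(params)
    r_j = params.white_to_white_diameter / 2.0
    z_j = -a_z + a_z * np.cos(phi_j)

    b_r = params.scleral_radius_of_curvature
    b_z = params.posterior_to_equatorial_radius_ratio * b_r
    if r_j >= b_r:
        raise GeometryError("white-to-white radius exceeds the scleral equatorial radius")
    # place the scleral ellipse centre so it passes through the limbal junction
    psi_j = np.arcsin(r_j / b_r)
    z_c = z_j - b_z * np.cos(psi_j)

    # dense outer polyline: cornea (apex -> junction) then sclera (junction -> pole)
    n_half = n_dense // 2
    phi = np.linspace(0.0, phi_j, n_half)
    cornea = np.column_stack([a_r * np.sin(phi), -a_z + a_z * np.cos(phi)])
    psi = np.linspace(psi_j, np.pi, n_dense - n_half + 1)[1:]
    sclera = np.column_stack([b_r * np.sin(psi), z_c + b_z * np.cos(psi)])
    outer = np.vstack([cornea, sclera])
    outer[0, 0] = 0.0
    outer[-1, 0] = 0.0

    theta = np.arctan2(outer[:, 0], outer[:, 1] - z_c)
    theta[0] = 0.0
    theta[-1] = np.pi
    if np.any(np.diff(theta) <= 0):
        raise GeometryError("outer boundary is not monotone in polar angle about the scleral centre")
    theta_j = float(np.arctan2(r_j, z_j - z_c))

    stations = [
        (0.0, params.central_corneal_thickness),
        (theta_j, params.anterior_scleral_thickness),
        (np.pi / 2.0, params.equatorial_scleral_thickness),
        (np.pi, params.posterior_scleral_thickness),
    ]
    stations = sorted(stations)
    xs = np.array([s[0] for s in stations])
    ys = np.array([s[1] for s in stations])
    if np.any(np.diff(xs) <= 1e-9):
        # degenerate overlap (e.g. junction at the equator); drop duplicates
        keep = np.concatenate([[True], np.diff(xs) > 1e-9])
        xs, ys = xs[keep], ys[keep]
    if len(xs) >= 2:
        thickness = PchipInterpolator(xs, ys)
    else:  # uniform shell
        thickness = PchipInterpolator([0.0, np.pi], [ys[0], ys[0]])

    # inward offset along the outer normal
    seg = np.linalg.norm(np.diff(outer, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    dr = np.gradient(outer[:, 0], s)
    dz = np.gradient(outer[:, 1], s)
    norm = np.hypot(dr, dz)
    # outward normal of the CCW-about-the-cavity curve is (-dz, dr)/|.|
    n_out = np.column_stack([-dz / norm, dr / norm])
    t = thickness(theta)
    inner = outer - t[:, None] * n_out
    # enforce exact axis closure at the poles (the normal is axial by symmetry)
    for idx, name in ((0, "corneal apex"), (-1, "posterior pole")):
        if abs(inner[idx, 0]) > 1e-3:
            raise GeometryError(f"inner boundary fails to close on the axis at the {name}")
        inner[idx, 0] = 0.0
    if np.any(inner[1:-1, 0] <= 0.0):
        k = int(np.argmax(inner[1:-1, 0] <= 0.0)) + 1
        raise GeometryError(
            f"inner boundary crosses the axis near theta = {theta[k]:.3f} rad: "
            "thickness exceeds the local radius"
        )
    theta_in = np.arctan2(inner[:, 0], inner[:, 1] - z_c)
    theta_in[0], theta_in[-1] = 0.0, np.pi
    if np.any(np.diff(theta_in) <= 0):
        k = int(np.argmax(np.diff(theta_in) <= 0))
        raise GeometryError(
            f"inner boundary folds near theta = {theta[k]:.3f} rad: "
            "thickness exceeds the local radius of curvature"
        )

    band = np.deg2rad(params.transition_zone_angular_width) / 2.0
    outer_spline = CubicSpline(theta, outer)
    # re-sample the inner curve onto the same theta grid before fitting
    inner_r = np.interp(theta, theta_in, inner[:, 0])
    inner_z = np.interp(theta, theta_in, inner[:, 1])
    inner_rs = np.column_stack([inner_r, inner_z])
    inner_spline = CubicSpline(theta, inner_rs)

    return ShellSection(
        params=params,
        theta_dense=theta,
        outer_dense=outer,
        inner_dense=inner_rs,
        inner_offset_dense=inner,
        theta_junction=theta_j,
        band_halfwidth=band,
        scleral_center_z=float(z_c),
        thickness_stations=tuple((float(a), float(b)) for a, b in zip(xs, ys)),
        _outer_spline=outer_spline,
        _inner_spline=inner_spline,
        _thickness=thickness,
    )


# --------------------------------------------------------------------------
# meshing


REGION_NAMES = ("cornea", "transition", "sclera")


@dataclass
class ShellMesh:
    """Quadratic-triangle mesh of the shell cross-section.

    ``points`` are (r, z) node coordinates in mm; ``cells`` index six nodes
    per element (three corners counter-clockwise, then the mid-edge nodes of
    edges 0-1, 1-2, 2-0, matching the VTK quadratic-triangle convention).
    ``region`` labels each element cornea / transition / sclera, and
    ``cornea_weight`` gives the blended corneal material fraction used in
    the transition band.  ``inner_edges`` lists the quadratic boundary edges
    of the inner (cavity) surface ordered from the corneal apex to the
    posterior pole as (start, end, mid) node triples.
    """

    points: np.ndarray  # (n_nodes, 2)
    cells: np.ndarray  # (n_elements, 6)
    region: np.ndarray  # (n_elements,) strings
    cornea_weight: np.ndarray  # (n_elements,)
    node_sets: dict  # axis_of_symmetry, inner_surface, outer_surface
    inner_edges: np.ndarray  # (n_edges, 3)
    section: ShellSection
    target_element_size: float

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_elements(self) -> int:
        return len(self.cells)

    def element_centroids(self) -> np.ndarray:
        return self.points[self.cells[:, :3]].mean(axis=1)

    def corner_areas(self) -> np.ndarray:
        """Signed areas of the straight-sided corner triangles."""
        p = self.points[self.cells[:, :3]]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])


def _meridional_stations(section: ShellSection, size: float) -> np.ndarray:
    """Place meridional stations so local spacing ~ size (size/2 in the band)."""
    theta = section.theta_dense
    s = section.midsurface_arclength()
    d = np.abs(theta - section.theta_junction)
    half, full = section.band_halfwidth, 2.0 * section.band_halfwidth
    factor = np.where(d <= half, 0.5, np.where(d >= full, 1.0, 0.5 + 0.5 * (d - half) / half))
    density = 1.0 / (size * factor)  # stations per unit arc length
    measure = np.concatenate([[0.0], np.cumsum(0.5 * (density[1:] + density[:-1]) * np.diff(s))])
    n_s = max(4, int(np.ceil(measure[-1])))
    targets = np.linspace(0.0, measure[-1], 2 * n_s + 1)
    return np.interp(targets, measure, theta)


def generate_mesh(section: ShellSection, target_element_size: float) -> ShellMesh:
    """Mesh the cross-section with 6-node triangles at the requested density.

    The element count grows as 1/size^2.  Raises :class:`MeshError` for a
    non-positive size or one exceeding the thinnest wall section.
    """
    if target_element_size <= 0:
        raise MeshError("target_element_size must be positive")
    t_min = float(np.min([t for _, t in section.thickness_stations]))
    if target_element_size >= t_min:
        raise MeshError(
            f"target_element_size {target_element_size} mm is not smaller than the "
            f"thinnest wall section ({t_min} mm)"
        )

    theta_fine = _meridional_stations(section, target_element_size)
    n_s = (len(theta_fine) - 1) // 2
    t_mean = float(np.mean(section.thickness_at(theta_fine)))
    n_t = max(2, int(np.ceil(t_mean / target_element_size)))

    inner_pts = section.inner(theta_fine)  # (2n_s+1, 2)
    outer_pts = section.outer(theta_fine)
    frac = np.linspace(0.0, 1.0, 2 * n_t + 1)
    # points[k, j] = inner + frac_j * (outer - inner)
    pts = inner_pts[:, None, :] + frac[None, :, None] * (outer_pts - inner_pts)[:, None, :]
    pts[0, :, 0] = 0.0
    pts[-1, :, 0] = 0.0
    n_cols, n_rows = pts.shape[0], pts.shape[1]
    points = pts.reshape(-1, 2)

    def nid(k, j):
        return k * n_rows + j

    cells = []
    wts = []
    for i in range(n_s):
        k0, k1, k2 = 2 * i, 2 * i + 1, 2 * i + 2
        theta_e = theta_fine[k1]
        w = section.cornea_weight(theta_e)
        for j in range(n_t):
            j0, j1, j2 = 2 * j, 2 * j + 1, 2 * j + 2
            a, b, c, d = nid(k0, j0), nid(k2, j0), nid(k2, j2), nid(k0, j2)
            cells.append([a, b, c, nid(k1, j0), nid(k2, j1), nid(k1, j1)])
            cells.append([a, c, d, nid(k1, j1), nid(k1, j2), nid(k0, j1)])
            wts.extend([w, w])
    cells = np.asarray(cells, dtype=np.int64)
    cornea_weight = np.asarray(wts)

    region = np.where(
        cornea_weight >= 1.0, "cornea", np.where(cornea_weight <= 0.0, "sclera", "transition")
    )

    axis_nodes = np.concatenate([np.arange(n_rows), nid(n_cols - 1, 0) + np.arange(n_rows)])
    inner_nodes = np.arange(n_cols) * n_rows
    outer_nodes = np.arange(n_cols) * n_rows + (n_rows - 1)
    inner_edges = np.column_stack(
        [inner_nodes[0:-2:2], inner_nodes[2::2], inner_nodes[1:-1:2]]
    )

    mesh = ShellMesh(
        points=points,
        cells=cells,
        region=region,
        cornea_weight=cornea_weight,
        node_sets={
            "axis_of_symmetry": axis_nodes,
            "inner_surface": inner_nodes,
            "outer_surface": outer_nodes,
        },
        inner_edges=inner_edges,
        section=section,
        target_element_size=target_element_size,
    )
    areas = mesh.corner_areas()
    if np.any(areas <= 0):
        raise MeshError("mesher produced inverted elements; reduce the target element size")
    return mesh
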