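"""Plane linear-elastic FEM of a single-edge-notch (SEN) specimen.

The specimen is a rectangle of width ``W`` (x) and height ``H`` (y) with a
sharp edge crack along ``y = H/2`` from the left edge to ``x = a``.  Loading
is an opening grip displacement: the top edge moves up by ``+delta/2`` and
the bottom edge down by ``-delta/2`` (vertical components prescribed,
horizontal free, one pinned node).  Elements are linear (constant-strain)
triangles on a structured grid geometrically graded toward the crack tip;
the crack is a duplicated-node slit, so no singular elements are used — the
J-integral is evaluated with the equivalent-domain-integral form, which is
accurate on graded linear meshes.

From the displacement solution the module extracts

* ``delta5`` — the crack-tip opening displacement measured between two gauge
  points straddling the *original* crack tip at a fixed gauge length, and
* ``J`` — the energy release rate per unit crack area, and
* the "load until the computed CTOD matches a measured value, then report
  J" procedure, which by linearity needs a single solve per crack length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import GeometryError, InvalidSpecError, SolverError


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic linear-elastic constants (aragonite defaults)."""

    youngs_modulus: float = 120.0   # GPa
    poisson_ratio: float = 0.3
    plane: str = "strain"           # "strain" (default) or "stress"

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise InvalidSpecError("youngs_modulus must be positive")
        if not -1.0 < self.poisson_ratio < 0.5:
            raise InvalidSpecError("poisson_ratio must lie in (-1, 0.5)")
        if self.plane not in ("strain", "stress"):
            raise InvalidSpecError("plane must be 'strain' or 'stress'")

    @property
    def d_matrix(self) -> np.ndarray:
        """3x3 constitutive matrix for [eps_xx, eps_yy, gamma_xy] (GPa)."""
        E, nu = self.youngs_modulus, self.poisson_ratio
        if self.plane == "strain":
            c = E / ((1 + nu) * (1 - 2 * nu))
            return c * np.array(
                [[1 - nu, nu, 0], [nu, 1 - nu, 0], [0, 0, (1 - 2 * nu) / 2]]
            )
        c = E / (1 - nu**2)
        return c * np.array([[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]])

    @property
    def e_prime(self) -> float:
        """Effective modulus in J = K^2 / E' (GPa)."""
        E, nu = self.youngs_modulus, self.poisson_ratio
        return E / (1 - nu**2) if self.plane == "strain" else E


@dataclass(frozen=True)
class SpecimenGeometry:
    """SEN specimen geometry (nm)."""

    width: float = 1000.0
    height: float = 4000.0
    crack_length: float = 400.0
    notch_root_radius: float = 0.0   # 0 = ideally sharp slit
    mesh_refinement: int = 3         # grading levels toward the tip

    def __post_init__(self) -> None:
        if not 0 <= self.crack_length < self.width:
            raise GeometryError("need 0 <= crack_length < width")
        if self.height <= 0 or self.width <= 0:
            raise GeometryError("width and height must be positive")
        if self.mesh_refinement < 0:
            raise GeometryError("mesh_refinement must be >= 0")


@dataclass
class Mesh:
    """Triangulated SEN specimen with duplicated crack-face nodes."""

    nodes: np.ndarray        # (N, 2) nm
    elements: np.ndarray     # (E, 3) int
    crack_tip: np.ndarray    # (2,) nm
    top_nodes: np.ndarray
    bottom_nodes: np.ndarray
    n_duplicated: int = 0

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]


def _graded_axis(lo: float, hi: float, focus: float, n_coarse: int,
                 refinement: int, ratio: float = 0.5) -> np.ndarray:
    """1D coordinates on [lo, hi] geometrically refined toward ``focus``.

    Starts from a uniform grid with ``n_coarse`` intervals (snapped so that
    ``focus`` is a grid point) and, per refinement level, inserts points that
    halve the two intervals adjacent to ``focus``; the minimum spacing thus
    shrinks by ``2**refinement``.
    """
    base = np.linspace(lo, hi, n_coarse + 1)
    if lo < focus < hi:
        base[np.argmin(np.abs(base - focus))] = focus
    pts = set(np.round(base, 9))
    for _ in range(refinement):
        arr = np.array(sorted(pts))
        i = int(np.argmin(np.abs(arr - focus)))
        for j in (i - 1, i):
            if 0 <= j < len(arr) - 1:
                pts.add(round((arr[j] + arr[j + 1]) / 2 * (1 - 0) , 9))
    return np.array(sorted(pts))


def generate_sen_mesh(geometry: SpecimenGeometry, n_coarse_x: int = 16,
                      n_coarse_y: int = 24) -> Mesh:
    """Conforming triangulation with a duplicated-node crack slit.

    The crack tip ``(a, H/2)`` is a grid point; crack-face nodes (``y = H/2``,
    ``x < a``) are duplicated and elements above the crack line reference the
    upper copies.  With ``crack_length = 0`` the mesh is simply connected.
    """
    g = geometry
    xs = _graded_axis(0.0, g.width, g.crack_length, n_coarse_x, g.mesh_refinement)
    ys = _graded_axis(0.0, g.height, g.height / 2, n_coarse_y, g.mesh_refinement)
    ymid = g.height / 2
    nxp, nyp = len(xs), len(ys)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return j * nxp + i

    tris = []
    for j in range(nyp - 1):
        for i in range(nxp - 1):
            n00, n10 = nid(i, j), nid(i + 1, j)
            n01, n11 = nid(i, j + 1), nid(i + 1, j + 1)
            # split direction alternates for isotropy
            if (i + j) % 2 == 0:
                tris += [[n00, n10, n11], [n00, n11, n01]]
            else:
                tris += [[n00, n10, n01], [n10, n11, n01]]
    elements = np.array(tris, dtype=np.int64)

    n_dup = 0
    if g.crack_length > 0:
        jmid = int(np.argmin(np.abs(ys - ymid)))
        crack_ids = [nid(i, jmid) for i in range(nxp) if xs[i] < g.crack_length - 1e-9]
        dup_map = {}
        new_nodes = [nodes]
        for cid in crack_ids:
            dup_map[cid] = len(nodes) + n_dup
            new_nodes.append(nodes[cid][None, :])
            n_dup += 1
        nodes = np.vstack(new_nodes)
        cent_y = nodes[elements].mean(axis=1)[:, 1]
        above = cent_y > ymid
        for e in np.nonzero(above)[0]:
            for v in range(3):
                if elements[e, v] in dup_map:
                    elements[e, v] = dup_map[elements[e, v]]

    top = np.nonzero(np.abs(nodes[:, 1] - g.height) < 1e-9)[0]
    bottom = np.nonzero(np.abs(nodes[:, 1]) < 1e-9)[0]
    return Mesh(
        nodes=nodes,
        elements=elements,
        crack_tip=np.array([g.crack_length, ymid]),
        top_nodes=top,
        bottom_nodes=bottom,
        n_duplicated=n_dup,
    )


@dataclass
class SpecimenField:
    """FEM mesh plus displacement solution at a given grip opening."""

    mesh: Mesh
    material: ElasticMaterial
    displacement: np.ndarray       # (N, 2) nm
    applied_displacement: float    # nm (total opening between grips)
    reaction_force: float = 0.0    # GPa * nm per unit thickness (force/thickness)


def _element_b_matrices(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Areas (E,) and B matrices (E, 3, 6) of all CST elements."""
    p = mesh.nodes[mesh.elements]            # (E, 3, 2)
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area2 = (
        (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
        - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0])
    )
    E = len(mesh.elements)
    B = np.zeros((E, 3, 6))
    B[:, 0, 0::2] = b
    B[:, 1, 1::2] = c
    B[:, 2, 0::2] = c
    B[:, 2, 1::2] = b
    B /= area2[:, None, None]
    return area2 / 2.0, B


def solve_elastic(mesh: Mesh, material: ElasticMaterial,
                  applied_displacement: float) -> SpecimenField:
    """Grip-opening solve: top edge +delta/2, bottom edge -delta/2.

    The solution is linear in ``applied_displacement``.  Raises
    :class:`SolverError` on a singular (under-constrained) system.
    """
    area, B = _element_b_matrices(mesh)
    D = material.d_matrix
    ke = np.einsum("e,eki,kl,elj->eij", area, B, D, B)  # (E, 6, 6)
    dofs = np.repeat(2 * mesh.elements, 2, axis=1)
    dofs[:, 1::2] += 1
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    n = 2 * mesh.n_nodes
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    fixed = np.zeros(n, dtype=bool)
    vals = np.zeros(n)
    fixed[2 * mesh.top_nodes + 1] = True
    vals[2 * mesh.top_nodes + 1] = applied_displacement / 2
    fixed[2 * mesh.bottom_nodes + 1] = True
    vals[2 * mesh.bottom_nodes + 1] = -applied_displacement / 2
    fixed[2 * mesh.bottom_nodes[0]] = True  # pin one horizontal component

    free = ~fixed
    Kff = K[free][:, free].tocsc()
    Kfc = K[free][:, fixed]
    try:
        lu = splu(Kff)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise SolverError(f"singular stiffness matrix: {exc}") from exc
    uf = lu.solve(-Kfc @ vals[fixed])
    if not np.all(np.isfinite(uf)):
        raise SolverError("elastic solve produced non-finite displacements")
    u = np.empty(n)
    u[fixed] = vals[fixed]
    u[free] = uf

    reaction = K @ u
    f_top = float(reaction[2 * mesh.top_nodes + 1].sum())
    return SpecimenField(
        mesh=mesh,
        material=material,
        displacement=u.reshape(-1, 2),
        applied_displacement=applied_displacement,
        reaction_force=f_top,
    )


def solve_elastic_traction(mesh: Mesh, material: ElasticMaterial,
                           sigma: float) -> SpecimenField:
    """Remote uniform tension ``sigma`` (GPa) on the top/bottom edges.

    Edge tractions are lumped to nodal forces with trapezoidal weights;
    rigid-body modes are removed by pinning one corner node and the vertical
    component of the opposite bottom corner.  Used mainly as the loading that
    matches handbook stress-intensity solutions for edge-cracked strips.
    """
    area, B = _element_b_matrices(mesh)
    D = material.d_matrix
    ke = np.einsum("e,eki,kl,elj->eij", area, B, D, B)
    dofs = np.repeat(2 * mesh.elements, 2, axis=1)
    dofs[:, 1::2] += 1
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    n = 2 * mesh.n_nodes
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    f = np.zeros(n)
    for ids, sign in ((mesh.top_nodes, +1.0), (mesh.bottom_nodes, -1.0)):
        order = np.argsort(mesh.nodes[ids, 0])
        ids = ids[order]
        x = mesh.nodes[ids, 0]
        w = np.zeros(len(x))
        w[:-1] += np.diff(x) / 2
        w[1:] += np.diff(x) / 2
        f[2 * ids + 1] += sign * sigma * w

    fixed = np.zeros(n, dtype=bool)
    bl = mesh.bottom_nodes[np.argmin(mesh.nodes[mesh.bottom_nodes, 0])]
    br = mesh.bottom_nodes[np.argmax(mesh.nodes[mesh.bottom_nodes, 0])]
    fixed[[2 * bl, 2 * bl + 1, 2 * br + 1]] = True
    free = ~fixed
    uf = splu(K[free][:, free].tocsc()).solve(f[free])
    u = np.zeros(n)
    u[free] = uf
    return SpecimenField(
        mesh=mesh,
        material=material,
        displacement=u.reshape(-1, 2),
        applied_displacement=np.nan,
        reaction_force=sigma * mesh.nodes[:, 0].max(),
    )


def _interp_displacement(field: SpecimenField, point: np.ndarray) -> np.ndarray:
    """Barycentric interpolation of the displacement at one point."""
    mesh = field.mesh
    p = mesh.nodes[mesh.elements]
    v0 = p[:, 1] - p[:, 0]
    v1 = p[:, 2] - p[:, 0]
    d = point[None, :] - p[:, 0]
    det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    l1 = (d[:, 0] * v1[:, 1] - d[:, 1] * v1[:, 0]) / det
    l2 = (v0[:, 0] * d[:, 1] - v0[:, 1] * d[:, 0]) / det
    l0 = 1.0 - l1 - l2
    tol = 1e-9
    inside = (l0 >= -tol) & (l1 >= -tol) & (l2 >= -tol)
    if not inside.any():
        raise GeometryError(f"point {point} lies outside the mesh")
    e = int(np.nonzero(inside)[0][0])
    lam = np.array([l0[e], l1[e], l2[e]])
    return lam @ field.displacement[mesh.elements[e]]


def compute_delta5(field: SpecimenField, gauge_length: float,
                   gauge_x: float | None = None) -> float:
    """delta-5 CTOD: relative opening between two gauge points.

    The points sit at ``(gauge_x, H/2 +/- gauge_length/2)``, straddling the
    original crack tip (``gauge_x`` defaults to the current tip).  A rigid
    translation of the field leaves the value unchanged.
    """
    mesh = field.mesh
    ymid = mesh.crack_tip[1]
    xg = mesh.crack_tip[0] if gauge_x is None else gauge_x
    up = _interp_displacement(field, np.array([xg, ymid + gauge_length / 2]))
    dn = _interp_displacement(field, np.array([xg, ymid - gauge_length / 2]))
    return float(up[1] - dn[1])


def compute_j_domain_integral(
    field: SpecimenField,
    domain_radii: tuple[float, float],
) -> float:
    """J by the equivalent domain integral over an annulus around the tip.

    ``domain_radii = (r1, r2)`` in nm: the weight q is 1 inside r1, 0 outside
    r2, linear in between.  The annulus must stay clear of the loaded edges.
    Units: material in GPa, lengths in nm -> J in GPa*nm = J/m^2.
    """
    r1, r2 = domain_radii
    if not 0 < r1 < r2:
        raise GeometryError("need 0 < r1 < r2")
    mesh = field.mesh
    tip = mesh.crack_tip
    H = mesh.nodes[mesh.top_nodes[0], 1]
    if r2 >= min(tip[1], H - tip[1]):
        raise GeometryError("integration annulus reaches the loaded boundary")

    r_nodes = np.linalg.norm(mesh.nodes - tip, axis=1)
    q = np.clip((r2 - r_nodes) / (r2 - r1), 0.0, 1.0)

    area, B = _element_b_matrices(mesh)
    u_el = field.displacement[mesh.elements].reshape(len(mesh.elements), 6)
    strain = np.einsum("eij,ej->ei", B, u_el)          # (E, 3)
    stress = strain @ field.material.d_matrix.T        # (E, 3) GPa
    W = 0.5 * np.einsum("ei,ei->e", stress, strain)

    # displacement gradient d u_i / d x_1 per element
    ux = u_el[:, 0::2]
    uy = u_el[:, 1::2]
    # B rows: [du/dx; dv/dy; du/dy+dv/dx]; need du/dx, dv/dx separately:
    bx = B[:, 0, 0::2]   # d/dx shape functions
    by = B[:, 1, 1::2]   # d/dy shape functions
    du1_dx = np.einsum("ei,ei->e", bx, ux)
    du2_dx = np.einsum("ei,ei->e", bx, uy)

    q_el = q[mesh.elements]
    dq_dx = np.einsum("ei,ei->e", bx, q_el)
    dq_dy = np.einsum("ei,ei->e", by, q_el)

    s11, s22, s12 = stress[:, 0], stress[:, 1], stress[:, 2]
    term = (
        (s11 * du1_dx + s12 * du2_dx - W) * dq_dx
        + (s12 * du1_dx + s22 * du2_dx) * dq_dy
    )
    return float((term * area).sum())


def j_path_independence(field: SpecimenField, radii: list[tuple[float, float]]) -> list[float]:
    """J evaluated on several annuli (path-independence diagnostic)."""
    return [compute_j_domain_integral(field, r) for r in radii]


def j_at_matched_ctod(
    ctod_curve: pd.DataFrame,
    geometry: SpecimenGeometry,
    material: ElasticMaterial,
    gauge_length: float | None = None,
) -> pd.DataFrame:
    """J versus crack extension, with the load matched to a measured CTOD.

    ``ctod_curve`` needs columns ``crack_extension_nm`` and ``delta5_nm``.
    For each row the crack is extended to ``a0 + crack_extension``, a unit
    grip opening is solved, and the load is scaled so the computed delta-5
    equals the measured one (exact by linearity); J at that load is reported
    (quadratic in the scale factor).  Non-positive targets are skipped with
    a warning.  Returns columns ``crack_extension_nm, delta5_nm, J_J_per_m2``.
    """
    if gauge_length is None:
        gauge_length = 0.05 * geometry.width
    a0 = geometry.crack_length
    records = []
    for _, row in ctod_curve.iterrows():
        da = float(row["crack_extension_nm"])
        target = float(row["delta5_nm"])
        if target <= 0:
            if target < 0:
                warnings.warn(f"skipping negative delta5 target at extension {da}")
                continue
            records.append({"crack_extension_nm": da, "delta5_nm": 0.0,
                            "J_J_per_m2": 0.0})
            continue
        geo = SpecimenGeometry(
            width=geometry.width, height=geometry.height,
            crack_length=a0 + da, notch_root_radius=geometry.notch_root_radius,
            mesh_refinement=geometry.mesh_refinement,
        )
        mesh = generate_sen_mesh(geo)
        field = solve_elastic(mesh, material, applied_displacement=1.0)
        d5_unit = compute_delta5(field, gauge_length, gauge_x=a0)
        if d5_unit <= 0:
            warnings.warn(f"non-opening delta5 at extension {da}; skipped")
            continue
        lam = target / d5_unit
        rmax = 0.8 * min(geo.crack_length, geometry.width - geo.crack_length,
                         geometry.height / 2)
        j_unit = compute_j_domain_integral(field, (0.4 * rmax, 0.9 * rmax))
        records.append(
            {"crack_extension_nm": da, "delta5_nm": target,
             "J_J_per_m2": lam**2 * j_unit}
        )
    return pd.DataFrame(records)
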