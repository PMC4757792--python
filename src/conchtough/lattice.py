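"""Triangular spring lattices with carved crack patterns.

The coarse-grained medium is a 2D triangular network of linear central-force
springs.  Nodes sit on staggered rows a distance ``sqrt(3)/2`` apart (in units
of the bond rest length) and every interior node has six nearest neighbours.
Cracks — one primary edge crack plus an optional periodic nanocrack array —
are introduced by deleting every bond whose segment is properly crossed by a
crack segment.

Internally all geometry is nondimensional: the bond rest length is 1 and the
bond stiffness is 1.  Physical units (nm, N/m) enter only when toughness and
stress are reported, via :class:`LatticeSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import GeometryError, InvalidSpecError

ROW_HEIGHT = np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry and bond law of a triangular spring lattice.

    Parameters
    ----------
    nx, ny
        Node counts along x and y (rows).  Must be at least 2.
    spacing
        Bond rest length in nm.  One lattice spacing defaults to 25 nm so a
        200 nm nanocrack spans 8 bonds.
    bond_stiffness
        Spring constant in N/m (force per unit stretch).
    critical_stretch
        Dimensionless bond strain at which a bond breaks (brittle, abrupt).
    thickness
        Out-of-plane thickness in nm, used only to normalise energies and
        stresses.
    """

    nx: int = 110
    ny: int = 76
    spacing: float = 25.0
    bond_stiffness: float = 1.0
    critical_stretch: float = 0.04
    thickness: float = 100.0

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise InvalidSpecError(f"need nx, ny >= 2, got {self.nx}x{self.ny}")
        if self.spacing <= 0 or self.bond_stiffness <= 0 or self.thickness <= 0:
            raise InvalidSpecError("spacing, bond_stiffness and thickness must be positive")
        if not 0 < self.critical_stretch < 1:
            raise InvalidSpecError("critical_stretch must lie in (0, 1)")

    @property
    def width(self) -> float:
        """Specimen width in internal units (bond lengths)."""
        return float(self.nx - 1)

    @property
    def height(self) -> float:
        """Specimen height in internal units."""
        return float(self.ny - 1) * ROW_HEIGHT


@dataclass(frozen=True)
class NanocrackPattern:
    """Periodic array of straight nanocracks around the main crack path.

    ``orientation='y'`` means cracks run perpendicular to the (horizontal)
    primary crack: vertical segments of length ``2*half_length_a`` arranged in
    columns; successive cracks within a column are separated by a ligament
    ``spacing_d`` (tip-to-tip) and successive columns by the period
    ``period_s`` along x.  ``orientation='x'`` means cracks parallel to the
    primary crack: horizontal segments in rows placed symmetrically off the
    main crack plane, rows ``period_s`` apart, collinear neighbours separated
    by ``spacing_d``.  All lengths are nm.  ``jitter`` adds zero-mean uniform
    positional noise (nm) to each crack centre.
    """

    orientation: Literal["x", "y"]
    half_length_a: float = 100.0
    spacing_d: float = 200.0
    period_s: float = 400.0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.orientation not in ("x", "y"):
            raise InvalidSpecError(f"orientation must be 'x' or 'y', got {self.orientation!r}")
        if self.half_length_a <= 0 or self.spacing_d <= 0 or self.period_s <= 0:
            raise InvalidSpecError("half_length_a, spacing_d, period_s must be positive")
        if self.jitter < 0:
            raise InvalidSpecError("jitter must be >= 0")

    @property
    def s_over_2a(self) -> float:
        return self.period_s / (2.0 * self.half_length_a)


@dataclass
class LatticeGraph:
    """Discrete triangular network: node coordinates, bonds, boundary sets."""

    coords: np.ndarray          # (N, 2) float64, internal units
    bonds: np.ndarray           # (M, 2) int32 node-index pairs, i < j
    alive: np.ndarray           # (M,) bool
    boundary_sets: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bonds.shape[0]

    def copy(self) -> "LatticeGraph":
        return LatticeGraph(
            coords=self.coords.copy(),
            bonds=self.bonds.copy(),
            alive=self.alive.copy(),
            boundary_sets={k: v.copy() for k, v in self.boundary_sets.items()},
        )

    def bond_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Rest-length bond unit vectors and lengths, shape (M, 2) and (M,)."""
        d = self.coords[self.bonds[:, 1]] - self.coords[self.bonds[:, 0]]
        length = np.linalg.norm(d, axis=1)
        return d / length[:, None], length


def build_triangular_lattice(spec: LatticeSpec) -> LatticeGraph:
    """Build an intact staggered triangular lattice.

    Row ``j`` sits at ``y = j*sqrt(3)/2`` with x offset ``(j % 2)/2``; node
    ids are ``j*nx + i``.  Bonds connect nearest neighbours only (distance 1
    in internal units): horizontal pairs within a row and the two diagonal
    families between adjacent rows.
    """
    nx, ny = spec.nx, spec.ny
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="xy")
    x = ii + 0.5 * (jj % 2)
    y = jj * ROW_HEIGHT
    coords = np.column_stack([x.ravel(), y.ravel()]).astype(np.float64)

    def nid(i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return j * nx + i

    pairs = []
    # horizontal bonds
    i = np.arange(nx - 1)
    for j in range(ny):
        pairs.append(np.column_stack([nid(i, j), nid(i + 1, j)]))
    # diagonal bonds between row j and j+1
    for j in range(ny - 1):
        i = np.arange(nx)
        if j % 2 == 0:  # even row offset 0, upper row offset 1/2
            up_same = i           # neighbour at x + 1/2
            up_left = i - 1       # neighbour at x - 1/2
        else:           # odd row offset 1/2, upper row offset 0
            up_same = i           # neighbour at x - 1/2
            up_left = i + 1       # neighbour at x + 1/2
        for upper in (up_same, up_left):
            ok = (upper >= 0) & (upper < nx)
            pairs.append(np.column_stack([nid(i[ok], j), nid(upper[ok], j + 1)]))

    bonds = np.vstack(pairs).astype(np.int32)
    bonds.sort(axis=1)
    # deterministic ordering: by (min node, max node)
    order = np.lexsort((bonds[:, 1], bonds[:, 0]))
    bonds = bonds[order]

    node_ids = np.arange(nx * ny).reshape(ny, nx)
    boundary_sets = {
        "bottom": node_ids[0, :].copy(),
        "top": node_ids[-1, :].copy(),
        "left": node_ids[:, 0].copy(),
        "right": node_ids[:, -1].copy(),
    }
    return LatticeGraph(
        coords=coords,
        bonds=bonds,
        alive=np.ones(bonds.shape[0], dtype=bool),
        boundary_sets=boundary_sets,
    )


def primary_crack_y(spec: LatticeSpec) -> float:
    """y (internal units) of the primary crack line, between two node rows."""
    return (spec.ny // 2 - 0.5) * ROW_HEIGHT


# Crack x-coordinates are nudged off node columns so that no crack segment
# passes exactly through a node or along a bond; 0.26 of a spacing is an
# arbitrary irregular offset that cannot coincide with node x positions
# (which are multiples of 1/2).
_X_NUDGE = 0.26


def pattern_segments(
    spec: LatticeSpec,
    primary_crack_length: float,
    pattern: NanocrackPattern,
    rng: np.random.Generator | None = None,
    margin: float = 10.0,
) -> np.ndarray:
    """Crack segments (internal units) of a periodic nanocrack array.

    Returns an array of shape (K, 4): ``x0, y0, x1, y1`` per segment.  The
    array is a *material microstructure*: it tiles the whole interior of the
    specimen (not just the region ahead of the tip), staying at least
    ``margin`` spacings away from every free boundary to suppress boundary
    image effects on shielding.

    ``orientation='y'``: vertical cracks in columns a period ``s`` apart
    along x; within a column, crack centres sit a pitch ``2a + d`` apart
    (``d`` = tip-to-tip ligament).  Even columns have one crack straddling
    the main-crack plane (the blocking configuration seen ahead of arrested
    tips); odd columns are offset by half a pitch, so the plane passes
    through a shielded ligament gap — the staggered arrangement of the
    observed patterns.  The array phase is anchored to the crack in the
    direction of its period: the nearest column ahead of the initial tip
    sits ``s/2`` from it (as in the observed tip-pattern arrangement), which
    keeps the tip-to-pattern distance comparable across the period sweep.

    ``orientation='x'``: horizontal cracks in rows at ``y_c +/- s/2,
    +/- 3s/2, ...`` (rows on the plane itself would merely extend the main
    crack), collinear neighbours a pitch ``2a + d`` apart along x.

    Raises :class:`GeometryError` when not even a single crack fits.
    """
    L = spec.spacing
    a = pattern.half_length_a / L
    d = pattern.spacing_d / L
    s = pattern.period_s / L
    jit = pattern.jitter / L
    if jit > 0 and rng is None:
        rng = np.random.default_rng(0)

    tip_x = primary_crack_length / L
    y_c = primary_crack_y(spec)
    x_lo, x_hi = margin, spec.width - margin
    y_lo, y_hi = margin, spec.height - margin
    y_nudge = _X_NUDGE * ROW_HEIGHT   # keeps horizontal cracks off node rows

    segs: list[tuple[float, float, float, float]] = []
    pitch = 2 * a + d
    if pattern.orientation == "y":
        k = -int(np.ceil((tip_x + s / 2 - x_lo) / s))
        while True:
            xc = tip_x + s / 2 + k * s
            if xc > x_hi:
                break
            if xc >= x_lo:
                off = 0.0 if k % 2 == 0 else pitch / 2
                m = -int(np.floor((y_c - y_lo) / pitch)) - 1
                while True:
                    yc = y_c + off + m * pitch
                    if yc - a > y_hi:
                        break
                    if yc - a >= y_lo and yc + a <= y_hi:
                        xj, yj = xc + _X_NUDGE, yc
                        if jit > 0:
                            xj += rng.uniform(-jit, jit)
                            yj += rng.uniform(-jit, jit)
                        segs.append((xj, yj - a, xj, yj + a))
                    m += 1
            k += 1
    else:
        row = 0
        while (row + 0.5) * s <= max(y_hi - y_c, y_c - y_lo):
            y_off = (row + 0.5) * s
            for sign in (+1.0, -1.0):
                yc = y_c + sign * y_off + y_nudge
                if yc < y_lo or yc > y_hi:
                    continue
                xc = x_lo + a
                while xc + a <= x_hi:
                    xj, yj = xc + _X_NUDGE, yc
                    if jit > 0:
                        xj += rng.uniform(-jit, jit)
                        yj += rng.uniform(-jit, jit)
                    segs.append((xj - a, yj, xj + a, yj))
                    xc += pitch
            row += 1

    if not segs:
        raise GeometryError(
            "nanocrack pattern does not fit inside the interior margin "
            f"(margin={margin} spacings, lattice {spec.nx}x{spec.ny})"
        )
    return np.asarray(segs, dtype=np.float64)


def _proper_crossings(p0, p1, q0, q1) -> np.ndarray:
    """Vectorised strict segment crossing test.

    ``p0, p1``: (M, 2) bond endpoints; ``q0, q1``: (2,) crack endpoints.
    A bond is cut only when the two segments properly cross (each segment's
    endpoints lie strictly on opposite sides of the other's line); touching
    at an endpoint does not cut.
    """
    def cross(o, a, b):
        return (a[..., 0] - o[..., 0]) * (b[..., 1] - o[..., 1]) - (
            a[..., 1] - o[..., 1]
        ) * (b[..., 0] - o[..., 0])

    eps = 1e-12
    d1 = cross(q0, q1, p0)
    d2 = cross(q0, q1, p1)
    d3 = cross(p0, p1, q0[None, :])
    d4 = cross(p0, p1, q1[None, :])
    return (d1 * d2 < -eps) & (d3 * d4 < -eps)


def carve_cracks(
    lattice: LatticeGraph,
    spec: LatticeSpec,
    primary_crack_length: float,
    pattern: NanocrackPattern | None = None,
    rng: np.random.Generator | None = None,
    margin: float = 10.0,
) -> tuple[LatticeGraph, int]:
    """Mark every bond crossed by the primary crack or a nanocrack as dead.

    ``primary_crack_length`` is in nm, measured from the left edge along the
    line midway between the two central node rows.  Returns the modified copy
    of the lattice and the number of bonds killed.
    """
    out = lattice.copy()
    segs: list[np.ndarray] = []
    if primary_crack_length > 0:
        a0 = primary_crack_length / spec.spacing
        if a0 >= spec.width:
            raise GeometryError("primary crack must end inside the lattice")
        y_c = primary_crack_y(spec)
        segs.append(np.array([[-1.0, y_c, a0, y_c]]))
    if pattern is not None:
        segs.append(pattern_segments(spec, primary_crack_length, pattern, rng, margin))
    if not segs:
        return out, 0

    p0 = out.coords[out.bonds[:, 0]]
    p1 = out.coords[out.bonds[:, 1]]
    dead = np.zeros(out.n_bonds, dtype=bool)
    for block in segs:
        for x0, y0, x1, y1 in block:
            dead |= _proper_crossings(p0, p1, np.array([x0, y0]), np.array([x1, y1]))
    n_killed = int(np.count_nonzero(dead & out.alive))
    out.alive &= ~dead
    return out, n_killed
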