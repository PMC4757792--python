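"""Quasi-static brittle fracture of triangular spring lattices.

Loading is mode I: the top and bottom node rows are pulled apart by a
prescribed vertical displacement (roller grips: the vertical component is
prescribed, the horizontal one is free except for a single pinned node that
removes the rigid x-translation).  Because the bond law is linear up to an
abrupt break, the quasi-static trajectory can be integrated event by event:
for a fixed bond topology the whole solution scales linearly with the grip
displacement ``U``, so the next breaking event is found from a single unit
solve, the displacement jumps straight to it, the most-stretched bond is
removed, and the lattice is re-equilibrated at fixed ``U`` (cascades break
one bond at a time, ties going to the lowest bond index).

Removing one bond is a rank-one update of the stiffness matrix, so the
re-solves reuse one sparse factorisation through a Sherman-Morrison-Woodbury
correction and re-factorise only every ``refactor_every`` events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .errors import SolverError
from .lattice import LatticeGraph, LatticeSpec, NanocrackPattern, carve_cracks

#: Tikhonov regularisation added to the free-free stiffness block, relative
#: to the (unit) bond stiffness.  Keeps the solve well-posed when bond removal
#: creates floating fragments; such fragments carry no load and hence do not
#: enter the energy bookkeeping.
REGULARIZATION = 1e-9

_TENSILE_TOL = 1e-12


def mode_i_bc(lattice: LatticeGraph) -> tuple[np.ndarray, np.ndarray]:
    """Roller-grip boundary maps for a unit grip opening.

    Returns ``(fixed_mask, fixed_vals)`` of shape (N, 2): top row
    ``uy = +1/2``, bottom row ``uy = -1/2``, plus ``ux = 0`` on the first
    bottom node to pin the horizontal rigid mode.
    """
    n = lattice.n_nodes
    mask = np.zeros((n, 2), dtype=bool)
    vals = np.zeros((n, 2))
    top = lattice.boundary_sets["top"]
    bot = lattice.boundary_sets["bottom"]
    mask[top, 1] = True
    vals[top, 1] = 0.5
    mask[bot, 1] = True
    vals[bot, 1] = -0.5
    mask[bot[0], 0] = True
    return mask, vals


def _bond_incidence(lattice: LatticeGraph) -> tuple[np.ndarray, np.ndarray]:
    """Per-bond DOF indices (M, 4) and signed direction entries (M, 4).

    Bond b with unit vector n contributes the gradient vector
    ``b_vec = (+n at node i, -n at node j)``; the bond stiffness matrix is
    ``k * b_vec b_vec^T`` and the elongation is ``-b_vec . u``.
    """
    nhat, _ = lattice.bond_vectors()
    i, j = lattice.bonds[:, 0], lattice.bonds[:, 1]
    dofs = np.column_stack([2 * i, 2 * i + 1, 2 * j, 2 * j + 1])
    vals = np.column_stack([nhat[:, 0], nhat[:, 1], -nhat[:, 0], -nhat[:, 1]])
    return dofs, vals


def assemble_stiffness(lattice: LatticeGraph, stiffness: float = 1.0) -> sp.csr_matrix:
    """Global (2N x 2N) stiffness matrix of all alive bonds."""
    dofs, vals = _bond_incidence(lattice)
    alive = lattice.alive
    dofs, vals = dofs[alive], vals[alive]
    rows = np.repeat(dofs, 4, axis=1).ravel()
    cols = np.tile(dofs, (1, 4)).ravel()
    data = stiffness * (vals[:, :, None] * vals[:, None, :]).ravel()
    n = 2 * lattice.n_nodes
    return sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def equilibrium_solve(
    lattice: LatticeGraph,
    fixed_mask: np.ndarray,
    fixed_vals: np.ndarray,
    stiffness: float = 1.0,
    reg: float = 0.0,
) -> np.ndarray:
    """Displacements minimising the harmonic bond energy under Dirichlet BCs.

    ``fixed_mask``/``fixed_vals`` are (N, 2) arrays selecting and prescribing
    individual displacement components.  Raises :class:`SolverError` when no
    component at all is constrained or when the constrained system is still
    singular (e.g. floating fragments after bond removal); passing a small
    ``reg`` > 0 pins such fragments instead.
    """
    if not fixed_mask.any():
        raise SolverError("at least one displacement component must be prescribed")
    K = assemble_stiffness(lattice, stiffness)
    fmask = fixed_mask.ravel()
    free = ~fmask
    uc = fixed_vals.ravel()[fmask]
    Kff = K[free][:, free].tocsc()
    Kfc = K[free][:, fmask]
    A = Kff + reg * stiffness * sp.identity(Kff.shape[0], format="csc")
    try:
        uf = splu(A).solve(-Kfc @ uc)
    except RuntimeError as exc:
        raise SolverError(
            f"singular lattice system (floating fragments?): {exc}"
        ) from exc
    if not np.all(np.isfinite(uf)):
        raise SolverError("singular lattice system produced non-finite solution")
    u = np.empty(2 * lattice.n_nodes)
    u[fmask] = uc
    u[free] = uf
    return u.reshape(-1, 2)


class _GripSystem:
    """Reduced linear system under unit grip opening with low-rank updates."""

    def __init__(self, lattice: LatticeGraph, stiffness: float = 1.0,
                 refactor_every: int = 50):
        self.lat = lattice
        self.k = stiffness
        self.refactor_every = refactor_every
        self.fixed_mask, self.fixed_vals = mode_i_bc(lattice)
        self._fmask = self.fixed_mask.ravel()
        self._free = ~self._fmask
        self._free_index = -np.ones(2 * lattice.n_nodes, dtype=np.int64)
        self._free_index[self._free] = np.arange(self._free.sum())
        self._uc = self.fixed_vals.ravel()[self._fmask]
        self._dofs, self._bvals = _bond_incidence(lattice)
        self._refactorize()

    def _refactorize(self) -> None:
        K = assemble_stiffness(self.lat, self.k)
        Kff = K[self._free][:, self._free].tocsc()
        Kfc = K[self._free][:, self._fmask]
        nf = Kff.shape[0]
        self._lu = splu(Kff + REGULARIZATION * self.k * sp.identity(nf, format="csc"))
        self._r0 = -(Kfc @ self._uc)
        self._y0 = self._lu.solve(self._r0)
        # Woodbury state for bonds removed since the last factorisation
        self._Z = np.empty((nf, 0))
        self._Bf: list[tuple[np.ndarray, np.ndarray]] = []  # (free-dof idx, vals)
        self._M = np.empty((0, 0))
        self._beta = np.empty(0)

    def _bond_free_vector(self, b: int) -> tuple[np.ndarray, np.ndarray, float]:
        """Free-part sparse vector of bond b and its constrained-part dot with uc."""
        dofs, vals = self._dofs[b], self._bvals[b]
        on_free = self._free[dofs]
        fidx = self._free_index[dofs[on_free]]
        fvals = vals[on_free]
        beta = float(vals[~on_free] @ self.fixed_vals.ravel()[dofs[~on_free]])
        return fidx, fvals, beta

    def remove_bond(self, b: int) -> None:
        self.lat.alive[b] = False
        if len(self._Bf) >= self.refactor_every:
            self._refactorize()
            return
        fidx, fvals, beta = self._bond_free_vector(b)
        dense_b = np.zeros(self._Z.shape[0])
        dense_b[fidx] = fvals
        z = self._lu.solve(dense_b)
        r = len(self._Bf)
        M = np.empty((r + 1, r + 1))
        M[:r, :r] = self._M
        for l, (fi, fv) in enumerate(self._Bf):
            M[l, r] = M[r, l] = fv @ z[fi]
        M[r, r] = fvals @ z[fidx]
        self._M = M
        self._Z = np.column_stack([self._Z, z])
        self._Bf.append((fidx, fvals))
        self._beta = np.append(self._beta, beta)

    def unit_solve(self) -> np.ndarray:
        """Full displacement field (N, 2) at unit grip opening."""
        r = len(self._Bf)
        if r == 0:
            uf = self._y0
        else:
            y = self._y0 + self._Z @ (self.k * self._beta)
            Bty = np.array([fv @ y[fi] for fi, fv in self._Bf])
            C = np.eye(r) / self.k - self._M
            try:
                w = np.linalg.solve(C, Bty)
            except np.linalg.LinAlgError:
                self._refactorize()
                return self.unit_solve()
            uf = y + self._Z @ w
        u = np.empty(2 * self.lat.n_nodes)
        u[self._fmask] = self._uc
        u[self._free] = uf
        return u.reshape(-1, 2)

    def strains(self, u: np.ndarray) -> np.ndarray:
        """Bond strains (elongation / rest length) for all bonds; dead = 0."""
        flat = u.ravel()
        e = -(self._bvals * flat[self._dofs]).sum(axis=1)  # elongation, L = 1
        e[~self.lat.alive] = 0.0
        return e


def _grips_connected(lattice: LatticeGraph) -> bool:
    alive = lattice.bonds[lattice.alive]
    n = lattice.n_nodes
    g = sp.coo_matrix(
        (np.ones(len(alive)), (alive[:, 0], alive[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(g, directed=False)
    top = set(labels[lattice.boundary_sets["top"]])
    bot = set(labels[lattice.boundary_sets["bottom"]])
    return bool(top & bot)


@dataclass
class LoadingProtocol:
    """Monotone grip-opening protocol (internal displacement units).

    ``max_displacement = None`` derives a generous bound from the lattice:
    several times the grip opening at which an intact strip reaches the
    critical bond strain.
    """

    max_displacement: float | None = None

    def resolved(self, spec: LatticeSpec) -> float:
        if self.max_displacement is not None:
            return self.max_displacement
        return 8.0 * spec.critical_stretch * spec.height


@dataclass
class BreakEvent:
    bond: int
    displacement: float
    force: float
    dissipated: float
    crack_advance: float


@dataclass
class FractureTrajectory:
    """Ordered bond-breaking record of one quasi-static run."""

    events: list[BreakEvent] = field(default_factory=list)
    work_input: float = 0.0
    stored_final: float = 0.0
    peak_force: float = 0.0
    separated: bool = False
    aborted: bool = False
    primary_crack_length: float = 0.0  # internal units

    @property
    def dissipated_total(self) -> float:
        return float(sum(e.dissipated for e in self.events))

    @property
    def crack_advance_total(self) -> float:
        return self.events[-1].crack_advance if self.events else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "bond": e.bond,
                    "displacement": e.displacement,
                    "force": e.force,
                    "dissipated": e.dissipated,
                    "crack_advance": e.crack_advance,
                }
                for e in self.events
            ]
        )


def quasistatic_fracture(
    lattice: LatticeGraph,
    spec: LatticeSpec,
    loading: LoadingProtocol | None = None,
    primary_crack_length: float = 0.0,
    max_events: int = 20000,
) -> FractureTrajectory:
    """Run the sequential bond-breaking protocol until separation.

    ``primary_crack_length`` (nm) locates the initial tip for the projected
    crack-advance bookkeeping; the crack itself must already be carved into
    ``lattice``.  The input lattice is not modified.
    """
    lat = lattice.copy()
    loading = loading or LoadingProtocol()
    u_max = loading.resolved(spec)
    ec = spec.critical_stretch
    tip_x = primary_crack_length / spec.spacing

    traj = FractureTrajectory(primary_crack_length=tip_x)
    if not _grips_connected(lat):
        warnings.warn("grips are not connected; nothing to fracture")
        return traj

    sys_ = _GripSystem(lat)
    mid_x = 0.5 * (lat.coords[lat.bonds[:, 0], 0] + lat.coords[lat.bonds[:, 1], 0])

    U = 0.0
    u_hat = sys_.unit_solve()
    e_hat = sys_.strains(u_hat)
    phi = 0.5 * float(np.sum(e_hat**2))  # stored energy at U = 1
    phi_initial = phi
    advance = 0.0

    for _ in range(max_events):
        tensile = e_hat > _TENSILE_TOL
        if not tensile.any():
            break
        u_req = np.full(lat.n_bonds, np.inf)
        u_req[tensile] = ec / e_hat[tensile]
        b = int(np.argmin(u_req))  # ties -> lowest bond index
        u_star = u_req[b]
        if u_star > U * (1.0 + 1e-12):
            if u_star > u_max:
                break
            # elastic loading segment at fixed topology
            traj.work_input += phi * (u_star**2 - U**2)
            U = u_star
        force = 2.0 * U * phi
        traj.peak_force = max(traj.peak_force, force)
        stored_before = U**2 * phi

        sys_.remove_bond(b)
        advance = max(advance, mid_x[b] - tip_x)
        u_hat = sys_.unit_solve()
        e_hat = sys_.strains(u_hat)
        phi_new = 0.5 * float(np.sum(e_hat**2))
        # separation: grips topologically disconnected, or the residual
        # grip-to-grip stiffness has dropped to numerical zero (a dangling
        # hinge chain can stay "connected" while carrying no load)
        separated = phi_new <= 1e-9 * phi_initial or not _grips_connected(lat)
        dissipated = stored_before - U**2 * phi_new
        traj.events.append(
            BreakEvent(b, U, force, max(dissipated, 0.0), max(advance, 0.0))
        )
        phi = phi_new
        if separated:
            traj.separated = True
            break
    else:
        traj.aborted = True

    traj.stored_final = U**2 * phi
    return traj


@dataclass
class ToughnessResult:
    """Physical-unit toughness measures of one fracture trajectory."""

    work_of_fracture: float      # J/m^2
    critical_stress: float       # GPa
    effective_modulus: float     # GPa
    enhancement_factor: float = 1.0
    crack_advance_nm: float = 0.0
    undefined: bool = False      # zero crack advance


def toughness(
    trajectory: FractureTrajectory,
    spec: LatticeSpec,
    effective_modulus_gpa: float = 0.0,
) -> ToughnessResult:
    """Work of fracture and critical stress, in J/m^2 and GPa.

    Work of fracture is the cumulative dissipated bond energy divided by the
    projected primary-crack advance area.  Internal (spacing = 1, stiffness
    = 1) energies convert through the bond stiffness [N/m] and the spacing
    [nm]; forces through stiffness x spacing.
    """
    if not trajectory.events:
        raise SolverError("trajectory contains no events")
    L_m = spec.spacing * 1e-9
    t_m = spec.thickness * 1e-9
    k = spec.bond_stiffness
    adv = trajectory.crack_advance_total
    energy_J = trajectory.dissipated_total * k * L_m**2
    if adv <= 0:
        warnings.warn("zero projected crack advance; work of fracture undefined")
        return ToughnessResult(
            work_of_fracture=np.nan,
            critical_stress=trajectory.peak_force * k * L_m / (spec.width * L_m * t_m) / 1e9,
            effective_modulus=effective_modulus_gpa,
            crack_advance_nm=0.0,
            undefined=True,
        )
    wof = energy_J / (adv * L_m * t_m)
    sigma_c = trajectory.peak_force * k * L_m / (spec.width * L_m * t_m)
    return ToughnessResult(
        work_of_fracture=wof,
        critical_stress=sigma_c / 1e9,
        effective_modulus=effective_modulus_gpa,
        crack_advance_nm=adv * spec.spacing,
    )


def effective_modulus(lattice: LatticeGraph, spec: LatticeSpec) -> float:
    """Small-strain uniaxial stiffness (GPa) between the grips.

    The grip reaction per unit applied strain is normalised by the loaded
    cross-section (width x thickness).  Returns 0 with a warning when the
    load path between the grips is severed.
    """
    if not _grips_connected(lattice):
        warnings.warn("load path between grips is severed; modulus = 0")
        return 0.0
    sys_ = _GripSystem(lattice)
    u = sys_.unit_solve()
    e = sys_.strains(u)
    phi = 0.5 * float(np.sum(e**2))
    force_int = 2.0 * phi              # dE/dU at U = 1
    strain = 1.0 / spec.height
    e_int = force_int / (spec.width * strain)
    t_m = spec.thickness * 1e-9
    return e_int * spec.bond_stiffness / t_m / 1e9


@dataclass
class SweepRow:
    orientation: str
    s_nm: float
    s_over_2a: float
    enhancement_factor: float
    work_of_fracture: float
    effective_modulus: float
    critical_stress: float


@dataclass
class SweepResult:
    table: pd.DataFrame
    argmax: pd.Series | None   # row with the largest enhancement factor
    baseline: ToughnessResult


def enhancement_sweep(
    spec: LatticeSpec,
    patterns: list[NanocrackPattern],
    primary_crack_length: float,
    loading: LoadingProtocol | None = None,
    rng: np.random.Generator | None = None,
    margin: float = 10.0,
) -> SweepResult:
    """Toughness-enhancement table over a family of nanocrack patterns.

    Runs one homogeneous (pattern-free) baseline plus one quasi-static
    fracture per pattern and reports the work-of-fracture ratio.  A failed
    individual run is recorded as a NaN row and the sweep continues.
    """
    from .lattice import build_triangular_lattice

    base = build_triangular_lattice(spec)
    cracked, _ = carve_cracks(base, spec, primary_crack_length)
    e0 = effective_modulus(cracked, spec)
    traj0 = quasistatic_fracture(cracked, spec, loading, primary_crack_length)
    tough0 = toughness(traj0, spec, e0)
    if not np.isfinite(tough0.work_of_fracture) or tough0.work_of_fracture <= 0:
        raise SolverError("homogeneous baseline produced no measurable work of fracture")

    rows = [
        SweepRow("none", np.nan, np.nan, 1.0, tough0.work_of_fracture,
                 tough0.effective_modulus, tough0.critical_stress)
    ]
    for pat in patterns:
        try:
            carved, _ = carve_cracks(base, spec, primary_crack_length, pat,
                                     rng=rng, margin=margin)
            em = effective_modulus(carved, spec)
            traj = quasistatic_fracture(carved, spec, loading, primary_crack_length)
            res = toughness(traj, spec, em)
            rows.append(
                SweepRow(pat.orientation, pat.period_s, pat.s_over_2a,
                         res.work_of_fracture / tough0.work_of_fracture,
                         res.work_of_fracture, em, res.critical_stress)
            )
        except Exception as exc:  # noqa: BLE001 - sweep must survive bad cells
            warnings.warn(f"sweep cell {pat} failed: {exc}")
            rows.append(SweepRow(pat.orientation, pat.period_s, pat.s_over_2a,
                                 np.nan, np.nan, np.nan, np.nan))

    table = pd.DataFrame(
        {
            "orientation": [r.orientation for r in rows],
            "s_nm": [r.s_nm for r in rows],
            "s_over_2a": [r.s_over_2a for r in rows],
            "enhancement_factor": [r.enhancement_factor for r in rows],
            "work_of_fracture_J_per_m2": [r.work_of_fracture for r in rows],
            "effective_modulus_GPa": [r.effective_modulus for r in rows],
            "critical_stress_GPa": [r.critical_stress for r in rows],
        }
    )
    pattern_rows = table[table.orientation != "none"]
    argmax = None
    if pattern_rows.enhancement_factor.notna().any():
        argmax = pattern_rows.loc[pattern_rows.enhancement_factor.idxmax()]
    return SweepResult(table=table, argmax=argmax, baseline=tough0)
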