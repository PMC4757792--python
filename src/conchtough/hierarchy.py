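"""Bottom-up self-similar hierarchical composite (tension-shear chain).

Each hierarchy level is a staggered arrangement of hard platelets — made of
the composite one level below — bonded by thin soft organic layers.  The
platelets carry tension; the organic transfers load in shear.  Level 0 is
the mineral building block (here: the nanotwin-toughened aragonite lamella).

Per level the bottom-up design route is:

* platelet thickness ``h_n`` = flaw-tolerant size of the level-n material,
  ``h_n = alpha * Gamma_n * E_n / S_n**2`` — the thickness below which the
  platelet's strength is insensitive to pre-existing cracks;
* aspect ratio ``rho_n = S_n / tau_org`` — the largest ratio at which load
  transferred by organic shear does not fracture the platelet (equal-strength
  design: the tension- and shear-limited strength branches coincide);
* effective modulus (series tension-shear-chain formula)
  ``1/E = 4(1-phi)/(G_org phi^2 rho^2) + 1/(phi E_lower)``;
* effective strength ``S = (phi/2) min(rho tau_org, S_lower)`` (the factor
  1/2 is the mean-to-peak platelet stress ratio of the linear transfer
  profile; the governing branch is recorded);
* effective fracture energy from organic shear dissipated over the platelet
  pull-out volume.  Two regimes are implemented: ``"pullout"`` (default) —
  shear resistance tau is sustained over complete platelet pull-out
  (mineral-bridge / asperity friction picture),
  ``Gamma = phi tau rho^2 h / 4``; and ``"strain_limited"`` — sliding stops
  at the organic failure strain, ``Gamma = tau gamma_f (1-phi) rho h``.

Unit system: GPa and nm; note 1 GPa*nm = 1 J/m^2, so fracture energies are
numerically in J/m^2 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InvalidSpecError

#: dimensionless prefactor of the flaw-tolerance size (order unity; the
#: Griffith estimate for a platelet-spanning edge crack gives ~1)
FLAW_TOLERANCE_ALPHA = 1.0


@dataclass(frozen=True)
class ConstituentProps:
    """Mineral building block and organic matrix constants (GPa, J/m^2)."""

    mineral_modulus: float = 100.0          # GPa (aragonite)
    mineral_strength: float = 3.3           # GPa (~E/30, flaw-free nanoscale)
    mineral_fracture_energy: float = 1.0    # J/m^2
    organic_shear_modulus: float = 1.0      # GPa (protein matrix)
    organic_shear_strength: float = 0.04    # GPa (interface shear strength)
    organic_failure_strain: float = 10.0    # large: unfolding/sliding capacity

    def __post_init__(self) -> None:
        for name in (
            "mineral_modulus", "mineral_strength", "mineral_fracture_energy",
            "organic_shear_modulus", "organic_shear_strength",
            "organic_failure_strain",
        ):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")


@dataclass
class LevelSpec:
    """Geometry and effective properties of one hierarchy level.

    For level ``n >= 1``, ``platelet_thickness`` and ``aspect_ratio``
    describe the level-(n-1) platelets this level is assembled from;
    for level 0 they are undefined (NaN).
    """

    level_index: int
    mineral_fraction: float
    aspect_ratio: float
    platelet_thickness: float       # nm
    effective_modulus: float        # GPa
    effective_strength: float       # GPa
    effective_fracture_energy: float  # J/m^2
    governing_branch: str = "n/a"   # "tension" | "shear" | "n/a"


@dataclass
class HierarchyDesign:
    """Ordered levels (0 = mineral) of a self-similar staggered composite."""

    levels: list[LevelSpec] = field(default_factory=list)

    @property
    def overall_toughness(self) -> float:
        return self.levels[-1].effective_fracture_energy

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "level": l.level_index,
                    "mineral_fraction": l.mineral_fraction,
                    "aspect_ratio": l.aspect_ratio,
                    "platelet_thickness_nm": l.platelet_thickness,
                    "E_GPa": l.effective_modulus,
                    "S_GPa": l.effective_strength,
                    "Gamma_J_per_m2": l.effective_fracture_energy,
                    "governing_branch": l.governing_branch,
                }
                for l in self.levels
            ]
        )


def mineral_level(constituents: ConstituentProps) -> LevelSpec:
    """Level 0: the bare mineral building block."""
    return LevelSpec(
        level_index=0,
        mineral_fraction=1.0,
        aspect_ratio=np.nan,
        platelet_thickness=np.nan,
        effective_modulus=constituents.mineral_modulus,
        effective_strength=constituents.mineral_strength,
        effective_fracture_energy=constituents.mineral_fracture_energy,
    )


def flaw_tolerant_thickness(level: LevelSpec, alpha: float = FLAW_TOLERANCE_ALPHA) -> float:
    """Largest platelet thickness (nm) insensitive to cracks, alpha*Gamma*E/S^2."""
    return (
        alpha
        * level.effective_fracture_energy
        * level.effective_modulus
        / level.effective_strength**2
    )


def design_level(
    lower: LevelSpec,
    organic: ConstituentProps,
    mineral_fraction: float,
    alpha: float = FLAW_TOLERANCE_ALPHA,
    dissipation: str = "pullout",
    aspect_ratio: float | None = None,
) -> LevelSpec:
    """One bottom-up design step: level n material -> level n+1 composite.

    ``aspect_ratio`` overrides the equal-strength design value ``S_n/tau``
    (useful for fixed-geometry sensitivity studies).
    """
    phi = mineral_fraction
    if not 0 < phi < 1:
        raise InvalidSpecError(f"mineral_fraction must lie in (0,1), got {phi}")
    if dissipation not in ("pullout", "strain_limited"):
        raise InvalidSpecError(f"unknown dissipation regime {dissipation!r}")

    G = organic.organic_shear_modulus
    tau = organic.organic_shear_strength
    E_low = lower.effective_modulus
    S_low = lower.effective_strength

    h = flaw_tolerant_thickness(lower, alpha)
    rho = S_low / tau if aspect_ratio is None else aspect_ratio

    compliance = 4 * (1 - phi) / (G * phi**2 * rho**2) + 1 / (phi * E_low)
    E_eff = 1.0 / compliance

    s_tension = 0.5 * phi * S_low
    s_shear = 0.5 * phi * rho * tau
    if s_tension <= s_shear:
        S_eff, branch = s_tension, "tension"
    else:
        S_eff, branch = s_shear, "shear"

    if dissipation == "pullout":
        gamma = 0.25 * phi * tau * rho**2 * h
    else:
        gamma = tau * organic.organic_failure_strain * (1 - phi) * rho * h

    return LevelSpec(
        level_index=lower.level_index + 1,
        mineral_fraction=phi,
        aspect_ratio=rho,
        platelet_thickness=h,
        effective_modulus=E_eff,
        effective_strength=S_eff,
        effective_fracture_energy=gamma,
        governing_branch=branch,
    )


def default_fractions(n_levels: int, total_mineral: float = 0.99) -> list[float]:
    """Per-level mineral fractions giving ``total_mineral`` overall content."""
    n_composite = max(n_levels - 1, 1)
    return [total_mineral ** (1.0 / n_composite)] * n_composite


def build_hierarchy(
    n_levels: int,
    constituents: ConstituentProps,
    fractions: list[float] | None = None,
    alpha: float = FLAW_TOLERANCE_ALPHA,
    dissipation: str = "pullout",
) -> HierarchyDesign:
    """Iterate the design step bottom-up.

    ``n_levels`` counts all material levels including the mineral (level 0);
    the conch-like baseline is ``n_levels = 3`` — nanotwinned third-order
    lamellae assembled into second- and then first-order lamellae.
    """
    if n_levels < 1:
        raise InvalidSpecError("n_levels must be >= 1")
    if fractions is None:
        fractions = default_fractions(n_levels)
    if len(fractions) < n_levels - 1:
        raise InvalidSpecError(
            f"need {n_levels - 1} mineral fractions, got {len(fractions)}"
        )
    levels = [mineral_level(constituents)]
    for n in range(n_levels - 1):
        try:
            levels.append(
                design_level(levels[-1], constituents, fractions[n], alpha, dissipation)
            )
        except InvalidSpecError as exc:
            raise InvalidSpecError(f"level {n + 1}: {exc}") from exc
    return HierarchyDesign(levels=levels)


def toughness_amplification(
    constituents: ConstituentProps,
    level0_scale: float,
    n_levels: int = 3,
    fractions: list[float] | None = None,
    alpha: float = FLAW_TOLERANCE_ALPHA,
    dissipation: str = "pullout",
) -> float:
    """Overall-toughness ratio when level-0 toughness and strength scale.

    Rebuilds the whole hierarchy with ``mineral_fracture_energy`` and
    ``mineral_strength`` multiplied by ``level0_scale`` (flaw-tolerant sizes
    and aspect ratios re-derived) and returns
    ``overall_toughness(scaled) / overall_toughness(baseline)``.
    """
    if level0_scale <= 0:
        raise InvalidSpecError("level0_scale must be positive")
    base = build_hierarchy(n_levels, constituents, fractions, alpha, dissipation)
    scaled_props = replace(
        constituents,
        mineral_fracture_energy=constituents.mineral_fracture_energy * level0_scale,
        mineral_strength=constituents.mineral_strength * level0_scale,
    )
    scaled = build_hierarchy(n_levels, scaled_props, fractions, alpha, dissipation)
    return scaled.overall_toughness / base.overall_toughness


def sweep_lowest_level(
    constituents: ConstituentProps,
    scale_grid: list[float],
    n_levels: int = 3,
    fractions: list[float] | None = None,
    alpha: float = FLAW_TOLERANCE_ALPHA,
    dissipation: str = "pullout",
) -> pd.DataFrame:
    """Amplification table across a grid of level-0 enhancement factors."""
    if not scale_grid:
        raise InvalidSpecError("scale grid must be non-empty")
    base = build_hierarchy(n_levels, constituents, fractions, alpha, dissipation)
    rows = []
    for c in scale_grid:
        props = replace(
            constituents,
            mineral_fracture_energy=constituents.mineral_fracture_energy * c,
            mineral_strength=constituents.mineral_strength * c,
        )
        design = build_hierarchy(n_levels, props, fractions, alpha, dissipation)
        rows.append(
            {
                "scale": c,
                "overall_toughness_J_per_m2": design.overall_toughness,
                "amplification": design.overall_toughness / base.overall_toughness,
            }
        )
    return pd.DataFrame(rows)


def invert_level0_fracture_energy(
    target_overall_toughness: float,
    constituents: ConstituentProps,
    n_levels: int = 3,
    fractions: list[float] | None = None,
    alpha: float = FLAW_TOLERANCE_ALPHA,
    dissipation: str = "pullout",
    bracket: tuple[float, float] = (1e-6, 1e6),
    tol: float = 1e-10,
) -> float:
    """Recover the level-0 fracture energy that yields a given overall one.

    The overall toughness is strictly increasing in the level-0 fracture
    energy (all other inputs fixed), so a 1D bracketed root find suffices.
    """

    def f(g0: float) -> float:
        props = replace(constituents, mineral_fracture_energy=g0)
        d = build_hierarchy(n_levels, props, fractions, alpha, dissipation)
        return d.overall_toughness - target_overall_toughness

    return float(brentq(f, *bracket, xtol=tol, rtol=8.9e-16))
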