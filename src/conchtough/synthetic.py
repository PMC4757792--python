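"""Synthetic inputs: CTOD curves, nanocrack pattern grids, fixture lattices.

All study data are in-situ TEM images and curves, so every pipeline input is
generated here: monotone CTOD-vs-crack-extension curves with the qualitative
contrast between nanotwinned and single-crystalline aragonite (the
nanotwinned curve saturates at a much larger opening), periodic nanocrack
pattern families over a grid of periods, and small deterministic lattices
for tests.  Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .lattice import LatticeGraph, LatticeSpec, NanocrackPattern, build_triangular_lattice, carve_cracks


@dataclass(frozen=True)
class SyntheticCtodSpec:
    """Parameters of a synthetic delta-5 CTOD curve.

    ``material_class`` selects the parametric mean shape: ``nanotwinned`` is
    concave-saturating (crack-tip blunting by local plasticity),
    ``single_crystal`` is shallow and near-linear (sharp brittle tip).  Noise
    is additive Gaussian, clipped at zero.
    """

    material_class: str = "nanotwinned"
    max_extension: float = 400.0   # nm
    n_points: int = 21
    noise_sd: float = 0.0          # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.material_class not in ("nanotwinned", "single_crystal"):
            raise InvalidSpecError(f"unknown material_class {self.material_class!r}")
        if self.n_points < 2:
            raise InvalidSpecError("n_points must be >= 2")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")


#: parametric mean-curve constants (nm); the nanotwinned curve saturates at
#: an opening an order of magnitude above the single-crystal slope line
_CTOD_FORMS = {
    "nanotwinned": dict(amplitude=50.0, length_scale=150.0),
    "single_crystal": dict(slope=0.012),
}


def ctod_mean(material_class: str, extension: np.ndarray) -> np.ndarray:
    """Noise-free parametric delta-5 mean curve (nm)."""
    x = np.asarray(extension, dtype=float)
    if material_class == "nanotwinned":
        p = _CTOD_FORMS["nanotwinned"]
        return p["amplitude"] * (1.0 - np.exp(-x / p["length_scale"]))
    return _CTOD_FORMS["single_crystal"]["slope"] * x


def gen_ctod_curve(spec: SyntheticCtodSpec) -> pd.DataFrame:
    """Synthetic CTOD table with columns ``crack_extension_nm, delta5_nm``."""
    x = np.linspace(0.0, spec.max_extension, spec.n_points)
    mean = ctod_mean(spec.material_class, x)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        mean = np.clip(mean + rng.normal(0.0, spec.noise_sd, size=mean.shape), 0.0, None)
    return pd.DataFrame({"crack_extension_nm": x, "delta5_nm": mean})


def gen_nanocrack_patterns(
    s_grid: list[float],
    half_length_a: float = 100.0,
    spacing_d: float = 200.0,
    orientation: str = "y",
    jitter: float = 0.0,
    seed: int = 0,
) -> list[NanocrackPattern]:
    """One pattern per period; the observed geometry is 2a = d = 200 nm."""
    if not s_grid:
        raise InvalidSpecError("s_grid must be non-empty")
    del seed  # jitter noise is drawn at carve time from the run's generator
    return [
        NanocrackPattern(
            orientation=orientation,
            half_length_a=half_length_a,
            spacing_d=spacing_d,
            period_s=float(s),
            jitter=jitter,
        )
        for s in s_grid
    ]


def default_s_grid() -> list[float]:
    """Period grid 300..1000 nm in 100 nm steps (s/2a from 1.5 to 5.0)."""
    return [float(s) for s in range(300, 1001, 100)]


def gen_fixture_lattice(kind: str, seed: int = 0) -> tuple[LatticeGraph, LatticeSpec]:
    """Small deterministic lattices for the test suite (<= 20x20 nodes).

    ``tiny``: 6x6 intact; ``notched``: 16x12 with a half-width edge crack;
    ``patterned``: notched plus a single column of y-nanocracks.
    """
    del seed  # fixtures are fully deterministic
    if kind == "tiny":
        spec = LatticeSpec(nx=6, ny=6, spacing=25.0)
        return build_triangular_lattice(spec), spec
    if kind == "notched":
        spec = LatticeSpec(nx=16, ny=12, spacing=25.0)
        lat = build_triangular_lattice(spec)
        lat, _ = carve_cracks(lat, spec, primary_crack_length=8 * spec.spacing)
        return lat, spec
    if kind == "patterned":
        spec = LatticeSpec(nx=20, ny=20, spacing=25.0)
        lat = build_triangular_lattice(spec)
        pat = NanocrackPattern(orientation="y", half_length_a=50.0,
                               spacing_d=100.0, period_s=100.0)
        lat, _ = carve_cracks(lat, spec, 5 * spec.spacing, pat, margin=2.0)
        return lat, spec
    raise InvalidSpecError(f"unknown fixture kind {kind!r}")
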