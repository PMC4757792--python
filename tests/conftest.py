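"""Shared fixtures: small deterministic lattices and FEM problems."""

import numpy as np
import pytest

from conchtough import LatticeSpec, build_triangular_lattice, carve_cracks


@pytest.fixture(scope="session")
def tiny_spec():
    return LatticeSpec(nx=6, ny=6, spacing=25.0)


@pytest.fixture(scope="session")
def tiny_lattice(tiny_spec):
    return build_triangular_lattice(tiny_spec)


@pytest.fixture(scope="session")
def notched_small():
    """12x10 lattice with a 4-bond edge crack — fast fracture runs."""
    spec = LatticeSpec(nx=12, ny=10, spacing=25.0)
    lat = build_triangular_lattice(spec)
    lat, _ = carve_cracks(lat, spec, primary_crack_length=4 * spec.spacing)
    return lat, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
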