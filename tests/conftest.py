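import numpy as np
import pytest

from refecho import FieldConfig, generate_bath
from refecho.constants import TWO_PI
from refecho.couplings import CouplingSet, build_coupling_set


@pytest.fixture(scope="session")
def field() -> FieldConfig:
    """W-band field configuration (3.38 T, z along the lab field)."""
    return FieldConfig()


def make_pair_couplings(
    field: FieldConfig,
    w_hz: float,
    b_hz: float,
    pseudo_hz: float = 0.0,
) -> CouplingSet:
    """Hand-built two-proton coupling set with hyperfine difference
    (A1 - A2)/2 = 2*pi*w_hz and pair coupling b = 2*pi*b_hz."""
    A = np.array([w_hz, -w_hz]) * TWO_PI
    b = np.array([[0.0, b_hz], [b_hz, 0.0]]) * TWO_PI
    return CouplingSet(
        A_zz=A,
        A_zx=np.full(2, pseudo_hz * TWO_PI),
        A_zy=np.zeros(2),
        b=b,
        field=field,
    )


def tight_cluster_couplings(field: FieldConfig, n: int, seed: int) -> CouplingSet:
    """Coupling set of n protons drawn close to the electron so that both
    hyperfine and pair couplings are significant."""
    rng = np.random.default_rng(seed)
    bath = generate_bath(
        density=0.02, cutoff=6.0, exclusion_e=2.5, min_hh=1.5, seed=int(rng.integers(2**31))
    )
    while bath.n_protons < n:
        bath = generate_bath(
            density=0.02, cutoff=6.0, exclusion_e=2.5, min_hh=1.5,
            seed=int(rng.integers(2**31)),
        )
    bath.proton_positions = bath.proton_positions[:n]
    return build_coupling_set(bath, field)
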