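import numpy as np
import pytest

from actomyosim import ParameterSet
from actomyosim.model import build_filament, build_motor
from actomyosim.state import Domain, SystemAssembler


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_two_filament_state(params, seed=0, length=2500.0, n_acp=2,
                            with_motor=True, box_z_um=4.0):
    """Small clamped antiparallel pair used across unit tests."""
    from actomyosim.kinetics import init_crosslinks

    dom = Domain.from_um((5.0, 5.0, box_z_um), (1, 1, 0))
    asm = SystemAssembler(params, dom)
    cx, cy, lz = 2500.0, 2500.0, box_z_um * 1000.0
    asm.add_filament(build_filament(length, origin=(cx - 13.5, cy, 0),
                                    direction=(0, 0, 1), params=params),
                     clamp_barbed=True)
    asm.add_filament(build_filament(length, origin=(cx + 13.5, cy, lz),
                                    direction=(0, 0, -1), params=params),
                     clamp_barbed=True)
    if with_motor:
        asm.add_motor(build_motor(8, 42.0, 42.0, center=(cx, cy, lz / 2),
                                  direction=(0, 0, 1), params=params))
    if n_acp:
        init_crosslinks(asm, n_acp, np.random.default_rng(seed),
                        z_range=(lz - length, length))
    return asm.build(seed=seed)


@pytest.fixture()
def small_state(params):
    return make_two_filament_state(params)
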