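import numpy as np
import pytest

from cortnet import (AmplitudeFlowModel, ColumnSpec, KernelSpec, NetworkSpec,
                     PopulationSpec)

OMEGA = 2.0 * np.pi  # period-1 oscillators throughout the suite


@pytest.fixture(scope="session")
def kernel() -> KernelSpec:
    return KernelSpec()


@pytest.fixture(scope="session")
def flow(kernel) -> AmplitudeFlowModel:
    return AmplitudeFlowModel(kernel=kernel, omega=OMEGA, p_scale=0.05)


def single_population_net(p_scale: float = 0.0, p_self: float = 1.0,
                          omega: float = OMEGA) -> NetworkSpec:
    col = ColumnSpec(populations=(PopulationSpec(omega),),
                     s_mat=np.zeros((1, 1)), p_mat=np.array([[p_self]]),
                     p_scale=p_scale)
    return NetworkSpec(columns=(col,))


def two_column_net(h_forward: float, h_back: float = 0.0,
                   p_scale_a: float = 0.05, p_scale_b: float = 0.05,
                   omega: float = OMEGA) -> NetworkSpec:
    def col(ps):
        return ColumnSpec(populations=(PopulationSpec(omega),),
                          s_mat=np.zeros((1, 1)), p_mat=np.ones((1, 1)),
                          p_scale=ps)
    H = np.zeros((1, 2, 2))
    H[0, 1, 0] = h_forward
    H[0, 0, 1] = h_back
    return NetworkSpec(columns=(col(p_scale_a), col(p_scale_b)), h=H)
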