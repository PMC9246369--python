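import numpy as np
import pytest

from crystagg import RateParams, TurbidityTrace, WellCondition, default_params


@pytest.fixture(scope="session")
def params() -> RateParams:
    return default_params()


@pytest.fixture
def make_logistic_trace():
    """Factory for logistic turbidity traces τ(t) = b + L/(1+exp(-k(t-t0)))."""

    def _make(L=1.0, k=0.02, t0=6000.0, baseline=0.0, duration=16200.0,
              interval=90.0, well="w"):
        t = np.arange(0.0, duration + 0.5 * interval, interval)
        tau = baseline + L / (1.0 + np.exp(-k * (t - t0)))
        return TurbidityTrace(well=well, condition=WellCondition(),
                              times=t, turbidity=tau)

    return _make


@pytest.fixture
def fullox_condition():
    """40 μM protein triggered with 0.5 mM GSSG and no GSH."""

    def _make(inositol_mM=0.0, protein_uM=40.0):
        return WellCondition(protein_uM=protein_uM, inositol_mM=inositol_mM,
                             oxd=1.0, total_glutathione_mM=1.0)

    return _make


@pytest.fixture
def redox_condition():
    """50 μM protein in a glutathione redox buffer at 2 mM total."""

    def _make(oxd, inositol_mM=0.0, protein_uM=50.0):
        return WellCondition(protein_uM=protein_uM, inositol_mM=inositol_mM,
                             oxd=oxd, total_glutathione_mM=2.0)

    return _make
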