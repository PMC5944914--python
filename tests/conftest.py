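import pytest

from antcargo.params import RescaledParams


@pytest.fixture(scope="session")
def red_marker() -> RescaledParams:
    """The reference bistable point of the reduced model: (g, f_ind) = (0.1, 0.23)."""
    return RescaledParams(n=0.8, g=0.1, f_ind=0.23, eps=0.0, k_c=1.0)


@pytest.fixture(scope="session")
def critical_values():
    """Homoclinic and saddle-node thresholds at (n, g) = (0.8, 0.1), computed once."""
    from antcargo.bifurcation import homoclinic_threshold, saddle_node_threshold

    f_c2 = homoclinic_threshold(0.8, 0.1)
    f_c3 = saddle_node_threshold(0.8, 0.1)
    return f_c2, f_c3
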