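import numpy as np
import pytest

from uffclamp import InstrumentConfig, Trace
from uffclamp.kinetics import KineticScheme, KineticState, Transition
from uffclamp.simulate import MechanicsConfig


@pytest.fixture
def quiet_instrument():
    """Noise-free instrument at 3 pN for exact-identity checks."""
    return InstrumentConfig(
        applied_force=3.0, noise_sd=0.0, ou_noise_sd=0.0, force_noise_sd=0.0
    )


@pytest.fixture
def quiet_mechanics():
    return MechanicsConfig(position_jitter_sd=0.0)


@pytest.fixture
def default_mechanics():
    return MechanicsConfig()


def single_exit_scheme(rate: float = 100.0) -> KineticScheme:
    """One attached state with one exit at the given rate."""
    return KineticScheme(
        [KineticState("A", True, 0.0), KineticState("D", False, 0.0)],
        [Transition("A", "D", rate, 0.0, "detach_fast")],
    )


def two_exit_scheme(k1: float = 300.0, k2: float = 700.0) -> KineticScheme:
    return KineticScheme(
        [
            KineticState("A", True, 0.0),
            KineticState("B", True, 6.0),
            KineticState("D", False, 0.0),
        ],
        [
            Transition("A", "B", k1, 0.0, "stroke"),
            Transition("A", "D", k2, 0.0, "detach_fast"),
            Transition("B", "D", 50.0, 0.0, "adp_release"),
        ],
    )


def stroke_plateau_scheme(k_stroke: float = 2000.0, k_exit: float = 30.0) -> KineticScheme:
    """Binding state at 0, stroked state at +6 nm, slow exit: long events show
    an arrest followed by a +6 nm plateau."""
    return KineticScheme(
        [
            KineticState("pre", True, 0.0),
            KineticState("post", True, 6.0),
            KineticState("D", False, 0.0),
        ],
        [
            Transition("pre", "post", k_stroke, 0.0, "stroke"),
            Transition("post", "D", k_exit, 0.0, "atp_binding"),
        ],
    )


def flat_trace(n: int = 5000, dt: float = 4e-6, value: float = 0.0, **kw) -> Trace:
    x = np.full(n, value)
    return Trace(
        dt=dt,
        trap_pos_lead=x,
        trap_pos_trail=x - 500.0,
        force_lead=np.zeros(n),
        force_trail=np.zeros(n),
        pause_flag=np.zeros(n, dtype=bool),
        **kw,
    )
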