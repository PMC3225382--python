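import numpy as np
import pytest

from bondkin import IntrinsicRates, apparent_from_intrinsic


def draw_feasible_rates(rng: np.random.Generator) -> IntrinsicRates:
    """Random intrinsic rates from the identifiable (feasible) regime:
    states ordered short- to long-lived (natural eigen-rate ordering with
    clear gaps) and a proper mixture representation (all weights in
    [0, 1]), matching the physical regime the scheme describes."""
    while True:
        r = IntrinsicRates(
            k12=rng.uniform(0.1, 3.0),
            k23=rng.uniform(0.05, 1.0),
            kr1=rng.uniform(1.0, 5.0),
            kr2=rng.uniform(0.2, 1.0),
            kr3=rng.uniform(0.01, 0.19),
        )
        K1, K2, K3 = r.k12 + r.kr1, r.k23 + r.kr2, r.kr3
        if not (K1 > 1.2 * K2 > 1.2 * K3):
            continue
        try:
            p = apparent_from_intrinsic(r)
        except Exception:
            continue
        if p.permutation == (0, 1, 2) and np.all(p.weights >= 0):
            return r


@pytest.fixture
def example_rates() -> IntrinsicRates:
    """The worked instance used throughout: k12=2, k23=1, kr=(3, 1, 0.5),
    whose apparent parameters are k=(5, 2, 0.5), w=(13/27, 6/27, 8/27)."""
    return IntrinsicRates(2.0, 1.0, 3.0, 1.0, 0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
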