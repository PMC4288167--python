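import numpy as np
import pytest

from tfocc import synthetic as syn


@pytest.fixture(scope="session")
def default_pwm():
    return syn.default_pwm()


@pytest.fixture(scope="session")
def small_fixture():
    """10-kb synthetic data set, reused by model-level tests."""
    spec = syn.SyntheticSpec(
        genome_length=10_000, n_planted_sites=3, accessible_fraction=0.3, seed=11
    )
    return syn.make_fixture(spec)


@pytest.fixture(scope="session")
def default_fixture():
    """Full-scale (200-kb) fixture at the default study conditions."""
    return syn.make_fixture(syn.SyntheticSpec(seed=1))


def scalar_eq1(N, lam, L, n, scores, access):
    """Independent scalar evaluation of the occupancy equation.

    Written in pure Python, separately from the vectorised code path: the
    genomic average is a plain loop over all sites, and each probability a
    direct transcription of the formula.
    """
    import math

    total = 0.0
    for w, a in zip(scores, access):
        total += a * math.exp(w / lam)
    avg = total / L
    out = []
    for w, a in zip(scores, access):
        x = N * a * math.exp(w / lam)
        out.append(x / (x + L * n * avg))
    return out
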