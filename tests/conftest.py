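import numpy as np
import pytest

from gbion import build_bdna, build_system, load_preset, place_ions
from gbion.params import PairClassTable


def make_random_system(rng, n, spread=12.0, classes=("solute", "cation", "anion"),
                       charged=True):
    """Random well-separated particle cluster for property tests."""
    recs = []
    for _ in range(n):
        recs.append({
            "position": spread * rng.standard_normal(3),
            "charge": float(rng.choice([-1.0, 1.0]) * (1.0 if charged else 0.0)),
            "topo_class": str(rng.choice(list(classes))),
            "rho": float(1.0 + rng.random()),
            "sigma": float(2.5 + rng.random()),
            "eps": 0.1,
            "mobility": "free",
        })
    return build_system(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def nacl_table():
    return load_preset("NaCl-DNA")


@pytest.fixture
def canonical_table():
    return PairClassTable()


@pytest.fixture
def dodecamer_with_ions():
    """12-bp phosphate duplex (charge -22e) plus its SLTCAP salt load."""
    dna = build_bdna(12)
    return place_ions(dna, {"NA": 36, "CL": 14}, radius=40.0, seed=42)
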