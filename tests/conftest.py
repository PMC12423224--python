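import numpy as np
import pytest
from hypothesis import settings

from nreclass import load_reference

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

VARIABLES = ["age_at_diagnosis", "bmi", "hba1c", "homa2_b", "homa2_ir"]
CLUSTERS = ["SIDD", "SIRD", "MOD", "MARD"]


def make_reference(centroids_by_cluster, *, transforms=None, scaling=None):
    """Build a two-sex reference model with identical per-sex blocks."""
    if scaling is None:
        scaling = {v: {"mean": 50.0, "sd": 10.0} for v in VARIABLES}
    block = {"scaling": scaling, "centroids": centroids_by_cluster}
    data = {
        "variables": VARIABLES,
        "clusters": list(centroids_by_cluster),
        "sexes": {"male": block, "female": block},
    }
    if transforms:
        data["transforms"] = transforms
    return load_reference(data)


@pytest.fixture(scope="session")
def demo_model():
    """The package's synthetic demo reference (realistic geometry)."""
    from nreclass.cli import _load_model

    return _load_model("demo")


@pytest.fixture(scope="session")
def separated_model():
    """Four centroids ~28 standardised units apart: unambiguous geometry
    in which near-prototypical individuals reach NRE close to 1."""
    sep = 20.0
    return make_reference(
        {
            "SIDD": [sep, sep, 0.0, 0.0, 0.0],
            "SIRD": [-sep, sep, 0.0, 0.0, 0.0],
            "MOD": [sep, -sep, 0.0, 0.0, 0.0],
            "MARD": [-sep, -sep, 0.0, 0.0, 0.0],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
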