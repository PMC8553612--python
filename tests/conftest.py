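import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from vepbench.constants import DEL, TOL
from vepbench.truthset import TruthSet

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


def make_truthset(labels, genes=None, provenance="functional"):
    """TruthSet from a list of DEL/TOL labels with autogenerated keys."""
    keys = [f"v{i}" for i in range(len(labels))]
    if genes is None:
        genes = ["G1"] * len(labels)
    return TruthSet(
        labels=pd.Series(list(labels), index=keys),
        genes=pd.Series(list(genes), index=keys),
        provenance=provenance,
    )


def make_calls(calls):
    return pd.Series(list(calls), index=[f"v{i}" for i in range(len(calls))], dtype=object)


def make_scores(values):
    return pd.Series(list(values), index=[f"v{i}" for i in range(len(values))], dtype=float)


@pytest.fixture
def small_truthset():
    return make_truthset([DEL, TOL, TOL, DEL])


@pytest.fixture
def demo_config_path():
    from pathlib import Path
    import vepbench

    return Path(vepbench.__file__).parent / "data" / "demo_config.yaml"
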