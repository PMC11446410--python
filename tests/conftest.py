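import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hcrkit import (
    DesignConfig,
    FixtureSpec,
    OfftargetConfig,
    ThermoConfig,
    default_initiators,
    make_target,
)


def random_dna(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


@pytest.fixture(scope="session")
def initiators():
    return default_initiators()


@pytest.fixture()
def permissive_cfg():
    """Design config whose thermo windows accept nearly everything, so
    selection/geometry behavior can be tested in isolation."""
    return DesignConfig(
        thermo=ThermoConfig(tm_min_c=-100.0, tm_max_c=200.0, gc_min=0.0,
                            gc_max=1.0, max_run=60),
    )


@pytest.fixture(scope="session")
def fixture_gene(tmp_path_factory):
    """A 3-exon synthetic gene written in both junction conventions."""
    outdir = tmp_path_factory.mktemp("gene")
    spec = FixtureSpec(seed=11)
    single, multi, target = make_target(spec, outdir)
    return {"single": single, "multi": multi, "target": target, "spec": spec}
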