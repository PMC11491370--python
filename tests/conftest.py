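import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from strepniche import ExperimentDesign, ResourceProfile
from strepniche.synthetic import default_config, generate, null_config

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        rooting="default-rooted",
    )


def make_profile(isolate_id, od, threshold=0.01):
    od = np.asarray(od, dtype=float)
    return ResourceProfile(
        isolate_id=isolate_id,
        substrates=tuple(f"s{i}" for i in range(len(od))),
        od=od,
        threshold=threshold,
    )


def make_design(isolate_plants: dict[str, tuple[str, str, str]],
                sample_plants: dict[str, tuple[str, str, str]] | None = None):
    """Design from id -> (richness, fungicide, plant) mappings."""
    isolates = pd.DataFrame(
        [
            {"id": i, "richness": r, "fungicide": f, "plant": p}
            for i, (r, f, p) in isolate_plants.items()
        ]
    ).set_index("id")
    if sample_plants:
        samples = pd.DataFrame(
            [
                {"id": i, "richness": r, "fungicide": f, "plant": p}
                for i, (r, f, p) in sample_plants.items()
            ]
        ).set_index("id")
    else:
        samples = pd.DataFrame(
            columns=["richness", "fungicide", "plant"],
            index=pd.Index([], name="id"),
        )
    return ExperimentDesign(samples, isolates)


@pytest.fixture(scope="session")
def default_experiment():
    return generate(default_config(seed=7))


@pytest.fixture(scope="session")
def null_experiment():
    return generate(null_config(seed=11))


@pytest.fixture(scope="session")
def experiment_dir(tmp_path_factory, default_experiment):
    outdir = tmp_path_factory.mktemp("experiment")
    default_experiment.write(outdir)
    return outdir
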