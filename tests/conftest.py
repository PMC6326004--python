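import pytest

from berrymet.pipeline import RunConfig, run_pipeline
from berrymet.simulate import DesignSpec, simulate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated experiment shared by read-only tests."""
    return simulate_experiment(DesignSpec(rng_seed=7), n_compounds=25)


@pytest.fixture(scope="session")
def standin_run(tmp_path_factory):
    """One full pipeline run on the 469-feature synthetic study stand-in."""
    out = tmp_path_factory.mktemp("standin")
    return run_pipeline(RunConfig(seed=0, standin=True, out_dir=str(out)))


@pytest.fixture()
def truth_feature_map(standin_run):
    """Retained feature_id -> (compound name, effect class) from ground truth."""
    truth = standin_run.simulation.truth
    ions = truth.ions.set_index("feature_id")
    effects = truth.compounds.set_index("name")["effect_class"]
    ann = standin_run.annotation.set_index("feature_id")
    mapped = ions.loc[ions.index.intersection(ann.index)]
    return {
        fid: (row["name"], effects.get(row["name"], "contaminant"))
        for fid, row in mapped.iterrows()
    }
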