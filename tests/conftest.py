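import numpy as np
import pandas as pd
import pytest

from phenomet import SynthConfig, generate_ground_truth, generate_metabolome, generate_phenotyping
from phenomet.datatypes import FeatureTable


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(crop="lettuce", seed=11, n_reps=4, n_compounds=60)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    truth = generate_ground_truth(small_config)
    obs = generate_phenotyping(small_config, truth)
    features = generate_metabolome(small_config, truth, obs)
    return truth, obs, features


def make_feature_table(values, groups, compounds=None, replicate=None):
    """FeatureTable from a raw matrix and per-sample treatment labels.

    ``groups`` are "SUBSTANCE_condition" strings.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    sample_ids = [f"s{i:03d}" for i in range(n)]
    if compounds is None:
        compounds = [f"c{j:02d}" for j in range(values.shape[1])]
    subs = [g.rsplit("_", 1)[0] for g in groups]
    conds = [g.rsplit("_", 1)[1] for g in groups]
    if replicate is None:
        seen: dict[str, int] = {}
        replicate = []
        for g in groups:
            seen[g] = seen.get(g, 0) + 1
            replicate.append(seen[g])
    samples = pd.DataFrame(
        {"substance": subs, "condition": conds, "replicate": replicate},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    ab = pd.DataFrame(values, index=samples.index, columns=compounds)
    return FeatureTable(ab, samples)
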