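import numpy as np
import pytest

import upfburden as ub
from upfburden.features import build_feature_matrix, default_feature_dictionary


@pytest.fixture(scope="session")
def paper_cfg():
    """Study-condition generative config at a size that keeps tests fast."""
    return ub.paper_like_config(n_respondents=8000, seed=11)


@pytest.fixture(scope="session")
def cohort(paper_cfg):
    df, truth = ub.generate_cohort(paper_cfg)
    return df, truth


@pytest.fixture(scope="session")
def scored_cohort(paper_cfg, cohort):
    df, _ = cohort
    return ub.score_cohort(df, paper_cfg.item_is_problem)


@pytest.fixture(scope="session")
def feature_matrix(paper_cfg, scored_cohort):
    return build_feature_matrix(scored_cohort, default_feature_dictionary(paper_cfg))


@pytest.fixture(scope="session")
def gbt_bundle(feature_matrix):
    return ub.fit_classifier(feature_matrix, algorithm="gradient_boosted_trees", seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
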