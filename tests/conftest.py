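"""Shared fixtures: synthetic studies at the default and reduced scales."""

import numpy as np
import pandas as pd
import pytest

from streamisd.pipeline import PipelineConfig, run_pipeline
from streamisd.synthetic import SyntheticConfig, simulate


def study_tables(study):
    return {
        "individuals": study.individuals,
        "species_traits": study.species_traits,
        "flow_records": study.flow_records,
        "sites": study.sites,
        "gages": study.gages,
        "site_gage_candidates": study.site_gage_candidates,
    }


@pytest.fixture(scope="session")
def default_study():
    """The full default synthetic study (500 sites, 500 individuals each)."""
    return simulate(seed=11)


@pytest.fixture(scope="session")
def default_pipeline(default_study):
    """Pipeline result on the default study."""
    return run_pipeline(PipelineConfig(seed=11), tables=study_tables(default_study))


@pytest.fixture(scope="session")
def small_study():
    """A cheap study for structural/IO tests."""
    cfg = SyntheticConfig(n_sites=40, n_species=60, individuals_per_site=120)
    return simulate(seed=3, config=cfg)


@pytest.fixture()
def small_tables(small_study):
    return {k: v.copy() for k, v in study_tables(small_study).items()}


@pytest.fixture(scope="session")
def species_pool_60():
    """Species as noisy convex mixtures of three planted trait archetypes.

    60 species, noise SD = 10% of each trait's archetype range.
    """
    rng = np.random.default_rng(7)
    arch = pd.DataFrame(
        {
            "equilibrium": [4.0, 2.3, 4.0, 4.0],
            "periodic": [8.0, 5.0, 2.0, 1.0],
            "opportunistic": [1.0, 3.0, 9.0, 1.0],
        },
        index=["age_maturity", "log10_fecundity", "spawning_season", "parental_care"],
    )
    mix = rng.dirichlet([0.5, 0.5, 0.5], size=60)
    ranges = (arch.max(axis=1) - arch.min(axis=1)).to_numpy()
    vals = mix @ arch.T.to_numpy() + rng.normal(size=(60, 4)) * (0.10 * ranges)
    traits = pd.DataFrame(vals, columns=arch.index)
    traits["age_maturity"] = traits["age_maturity"].clip(lower=0.3)
    traits["spawning_season"] = traits["spawning_season"].clip(1, 12)
    traits["parental_care"] = traits["parental_care"].clip(1, 4)
    traits["fecundity"] = 10.0 ** traits.pop("log10_fecundity")
    traits.insert(0, "species", [f"Sp{i:02d}" for i in range(60)])
    return traits, mix
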