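from __future__ import annotations

import pytest

from oculovar.engine import FilterConfig
from oculovar.simulate import make_cohort, make_panel
from oculovar.variants import read_inclusion_lists


@pytest.fixture(scope="session")
def panel_fixture():
    return make_panel(n_genes=10, seed=7)


@pytest.fixture(scope="session")
def cohort(panel_fixture, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    return make_cohort(panel_fixture, n_individuals=10, noise_rate=5.0, seed=7, out_dir=out)


@pytest.fixture(scope="session")
def cohort_lists(cohort):
    return read_inclusion_lists(
        cohort.known_pathogenic, cohort.splice_flagged, cohort.hypomorphic
    )


@pytest.fixture()
def default_config():
    return FilterConfig()
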