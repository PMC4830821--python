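import numpy as np
import pytest

import panelroc as pr


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def domain_map_15():
    return pr.default_domain_map(15)


@pytest.fixture(scope="session")
def calibrated_cohort():
    """One imputed 15-marker cohort at the default study size (67 + 67)."""
    table = pr.generate_cohort(pr.default_panel_config(15, seed=42))
    completed, _ = pr.impute_missing(table)
    return completed


def two_group_values(rng, n1=20, n2=20, shift=0.0, ties=False):
    """Random case/control values (optionally integer-valued to force ties)."""
    cases = rng.standard_normal(n1) + shift
    controls = rng.standard_normal(n2)
    if ties:
        cases = np.round(cases * 2) / 2
        controls = np.round(controls * 2) / 2
    values = np.concatenate([cases, controls])
    labels = np.concatenate([np.ones(n1, dtype=int), np.zeros(n2, dtype=int)])
    return values, labels
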