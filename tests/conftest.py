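"""Shared fixtures: tiny synthetic cohorts generated at test time."""

from __future__ import annotations

import warnings

import pytest

from pcgscreen.io_formats import scan_dataset
from pcgscreen.synthetic import CohortConfig, SimConfig, generate_cohort

# short recordings, one or two sites: enough structure for unit tests
TINY_SIM = SimConfig(duration_range_s=(5.0, 7.0), n_locations=(1, 2), murmur_snr_db=10.0)


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory):
    root = tmp_path_factory.mktemp("tiny_cohort")
    generate_cohort(CohortConfig(n_patients=12, seed=7), TINY_SIM, root, force=True)
    return root


@pytest.fixture(scope="session")
def tiny_catalog(tiny_cohort_dir):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return scan_dataset(tiny_cohort_dir, schema="synthetic")
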