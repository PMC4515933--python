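import shutil
import warnings
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from varcurate.fixtures import (
    SimulationSpec,
    generate_batch,
    generate_population_store,
)
from varcurate.profiles import AnalysisProfile

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture()
def profile() -> AnalysisProfile:
    """A small validated profile used across unit tests."""
    return AnalysisProfile(
        name="TEST",
        target_genes=frozenset({"BRCA1", "MYH7", "TTN", "SCN1A", "BAD1"}),
        known_causal_genes=frozenset({"MYH7"}),
        insilico_genes=frozenset({"TTN"}),
        clinician_genes=frozenset({"SCN1A"}),
        excluded_genes=frozenset({"BAD1"}),
        min_variant_coverage=15,
        min_variant_qual=50,
        median_coverage_min=50,
        fragment_size_range=(150, 250),
        max_duplicate_rate=0.25,
    )


@pytest.fixture(scope="session")
def study_spec() -> SimulationSpec:
    """Study-scale simulation conditions: 12 samples, ~2000 background
    variants each, 20-sample historical store."""
    return SimulationSpec(seed=20260923)


@pytest.fixture(scope="session")
def study_batch(tmp_path_factory, study_spec) -> Path:
    """One generated study-scale batch, shared read-only by tests."""
    out = tmp_path_factory.mktemp("study") / "batch"
    generate_batch(study_spec, out)
    return out


@pytest.fixture(scope="session")
def study_store_template(tmp_path_factory, study_spec) -> Path:
    """Pristine population store; tests copy it before mutating."""
    path = tmp_path_factory.mktemp("store") / "population.db"
    generate_population_store(study_spec, path)
    return path


@pytest.fixture()
def fresh_store(tmp_path, study_store_template) -> Path:
    dest = tmp_path / "population.db"
    shutil.copy(study_store_template, dest)
    return dest


@pytest.fixture()
def fresh_batch(tmp_path, study_batch) -> Path:
    """A private mutable copy of the study batch."""
    dest = tmp_path / "batch"
    shutil.copytree(study_batch, dest)
    return dest


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Tests exercise degenerate inputs that legitimately warn."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
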