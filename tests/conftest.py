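import numpy as np
import pandas as pd
import pytest

import myocounter as mc
from myocounter.simulate import SimulationConfig


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort with the study-shaped default configuration."""
    config = mc.default_cohort_config(seed=11)
    records, sheet, truth = mc.simulate_cohort(config)
    return records, sheet, truth


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    records, sheet, _ = default_cohort
    return mc.rcc.assemble_count_matrix(records, sheet)


@pytest.fixture(scope="session")
def default_run(default_cohort, default_matrix):
    """Full pipeline result on the default cohort (computed once)."""
    _, sheet, _ = default_cohort
    return mc.run_dge(default_matrix, sheet)


@pytest.fixture()
def small_config():
    """A light two-subtype configuration for fast unit tests."""
    return SimulationConfig(
        n_per_subtype={"NDC": 4, "Mi2": 4},
        n_genes=120,
        n_housekeeping=10,
        baseline_log2_mean_range=(4.0, 10.0),
        block_min_baseline=0.0,
        n_cartridges=2,
        seed=7,
    )


@pytest.fixture()
def small_cohort(small_config):
    return mc.simulate_cohort(small_config)


def make_matrix(counts: dict[str, list[int]], classes: list[str], sheet: pd.DataFrame | None = None):
    """Hand-build a CountMatrix from a probe -> per-sample counts mapping."""
    names = list(counts)
    n_samples = len(next(iter(counts.values())))
    if sheet is None:
        sheet = pd.DataFrame(
            {
                "sample_id": [f"S{i + 1}" for i in range(n_samples)],
                "subtype": ["NDC"] * n_samples,
                "cartridge": ["C1"] * n_samples,
                "fov": [555] * n_samples,
                "conservation": ["Cryopreserved"] * n_samples,
                "patient_id": [f"P{i + 1}" for i in range(n_samples)],
            }
        )
    values = pd.DataFrame(
        np.array([counts[n] for n in names]),
        index=pd.Index(names, name="probe"),
        columns=sheet["sample_id"],
    )
    ann = pd.DataFrame({"name": names, "code_class": classes, "accession": [""] * len(names)})
    return mc.rcc.CountMatrix(values=values, probe_annotations=ann, sample_annotations=sheet, scale="raw")
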