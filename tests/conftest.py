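import numpy as np
import pandas as pd
import pytest

from pairedspc.io import validate_design
from pairedspc.simulate import SimulationConfig, simulate_spc_experiment


@pytest.fixture(scope="session")
def small_study():
    """A compact paired study shared by read-only tests."""
    return simulate_spc_experiment(SimulationConfig(n_proteins=80, seed=42))


@pytest.fixture(scope="session")
def small_design(small_study):
    return validate_design(small_study.spc, small_study.samples)


def make_paired_counts(control_rows, treated_rows, age="adult", treatment="MPLA"):
    """Build (spc, samples) for explicit per-subject control/treated counts.

    ``control_rows``/``treated_rows`` are proteins x subjects arrays.
    """
    control_rows = np.asarray(control_rows, dtype=float)
    treated_rows = np.asarray(treated_rows, dtype=float)
    n_prot, n_subj = control_rows.shape
    proteins = [f"P{i}" for i in range(n_prot)]
    cols, rows = {}, []
    for s in range(n_subj):
        for cond, data in (("control", control_rows), (treatment, treated_rows)):
            sid = f"S{s}_{cond}"
            cols[sid] = data[:, s]
            rows.append(
                {
                    "id": sid,
                    "age_group": age,
                    "treatment": cond,
                    "subject_id": f"S{s}",
                    "replicate": 1,
                }
            )
    spc = pd.DataFrame(cols, index=pd.Index(proteins, name="id"))
    samples = pd.DataFrame(rows).set_index("id")
    return spc, samples


@pytest.fixture
def toy_pair():
    """4 subjects, one protein, control 2 vs treated 8 in every pair."""
    return make_paired_counts([[2, 2, 2, 2]], [[8, 8, 8, 8]])
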