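import numpy as np
import pandas as pd
import pytest

from tempomir.datasets import CONTROL, TREATED, ExpressionDataset
from tempomir.simulate import SimulationConfig, detection_p_from_values


def make_dataset(values, region="AMY", time_h=0, n_treated=None, probes=None, detection_p=None):
    """Wrap a plain array into an ExpressionDataset for one (region, time)."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    if n_treated is None:
        n_treated = n_samples // 2
    sample_ids = [f"{region}_{time_h}h_s{i:02d}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {
            "region": region,
            "time_h": time_h,
            "condition": [TREATED] * n_treated + [CONTROL] * (n_samples - n_treated),
            "animal_id": [f"a{i}" for i in range(n_samples)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if probes is None:
        probes = pd.DataFrame(
            {
                "species": "mouse",
                "maturity": "mature",
                "annotation": [f"mol{i:04d}" for i in range(n_probes)],
            },
            index=pd.Index([f"probe{i:04d}" for i in range(n_probes)], name="probe_id"),
        )
    vals = pd.DataFrame(values, index=probes.index, columns=sample_ids)
    if detection_p is None:
        detp = pd.DataFrame(
            detection_p_from_values(values), index=probes.index, columns=sample_ids
        )
    else:
        detp = pd.DataFrame(np.asarray(detection_p, float), index=probes.index, columns=sample_ids)
    return ExpressionDataset(values=vals, detection_p=detp, samples=samples, probes=probes)


@pytest.fixture(scope="session")
def small_config():
    """A fast single-region study used by integration-style tests."""
    return SimulationConfig(
        seed=42,
        regions=("AMY",),
        n_mirna_probes=150,
        n_mrna_probes=500,
        n_de_mirna_per_time=6,
        n_targets_per_mirna=3,
        kb_n_molecules=900,
        n_outlier_samples=1,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    from tempomir.simulate import simulate_expression, simulate_interactions, simulate_knowledgebase

    ds_mirna, ds_mrna, truth = simulate_expression(small_config)
    records = simulate_interactions(small_config, truth)
    kb, cell_lists = simulate_knowledgebase(small_config, truth)
    return dict(
        config=small_config,
        ds_mirna=ds_mirna,
        ds_mrna=ds_mrna,
        truth=truth,
        records=records,
        kb=kb,
        cell_lists=cell_lists,
    )
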