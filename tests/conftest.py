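import numpy as np
import pandas as pd
import pytest

from masticnet.pipeline import PipelineConfig, run_pipeline
from masticnet.preprocess import default_preprocess
from masticnet import network as net
from masticnet.io import phenotypes_to_frame
from masticnet.synthetic import CohortSpec, generate_cohort


def cohort_tables(spec: CohortSpec):
    """Phenotype frame plus subjects x nodes DC and subjects x edges weight
    tables, computed through the default preprocessing chain."""
    phenos, series, motion, gt = generate_cohort(spec)
    dc_rows, w_rows, edge_cols = [], [], None
    for sid, s in series.items():
        cm = net.compute_connectivity(default_preprocess(s), clip=True)
        dc_rows.append(net.degree_centrality(cm).dc)
        edges = net.flatten_edges(cm)
        w_rows.append([e.weight for e in edges])
        if edge_cols is None:
            edge_cols = [f"{e.node_i}--{e.node_j}" for e in edges]
    ids = list(series)
    return (
        phenotypes_to_frame(phenos),
        pd.DataFrame(dc_rows, index=ids, columns=spec.node_labels),
        pd.DataFrame(w_rows, index=ids, columns=edge_cols),
        gt,
    )


@pytest.fixture(scope="session")
def null_cohort():
    """No planted structure at all: identity inter-node design, no coupling.

    Under this cohort every node/edge association with MPI is a true null,
    so significance rates estimate the type-I error."""
    spec = CohortSpec(
        n_subjects=200, seed=13, covariance_design=np.eye(24), coupling_plan=()
    )
    return cohort_tables(spec)


@pytest.fixture(scope="session")
def planted_hub_cohort():
    """Single planted hub coupling (CAnt_L degree centrality) over an
    identity design, so all other nodes are as close to null as the shared
    incident edge permits."""
    spec = CohortSpec(
        n_subjects=200, seed=0, covariance_design=np.eye(24),
        coupling_plan=(("CAnt_L", 0.8),), behavior_noise_sd=1.0,
    )
    return cohort_tables(spec)


@pytest.fixture(scope="session")
def planted_edge_cohort():
    """Single planted edge coupling (M1_L--CPost8_R weight)."""
    spec = CohortSpec(
        n_subjects=200, seed=0, covariance_design=np.eye(24),
        coupling_plan=((("M1_L", "CPost8_R"), 8.0),), behavior_noise_sd=1.0,
    )
    return cohort_tables(spec)


@pytest.fixture(scope="session")
def demo_report(tmp_path_factory):
    """The bundled synthetic demo: 52 subjects, seed 7, default spec."""
    out = tmp_path_factory.mktemp("demo_run")
    config = PipelineConfig(out_dir=str(out), synthetic=CohortSpec(n_subjects=52, seed=7))
    return config, run_pipeline(config)
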