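import numpy as np
import pandas as pd
import pytest

from imprintscreen import MethylationDataset, SimulationConfig, simulate_dataset


def make_dataset(beta, groups, chrom=None, pos=None, cgi=None, feature=None,
                 detection_p=None):
    """Assemble a small in-memory dataset from plain arrays.

    ``beta``: 2-D array probes x samples; ``groups``: one group name per
    sample column.  Annotation defaults: all probes on chr1 spaced 100 bp.
    """
    beta = np.asarray(beta, dtype=float)
    n_probes, n_samples = beta.shape
    probe_ids = [f"cg{i:04d}" for i in range(n_probes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    ann = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["chr1"] * n_probes,
        "pos": pos if pos is not None else [100 * (i + 1) for i in range(n_probes)],
        "cgi": cgi if cgi is not None else [True] * n_probes,
        "feature": feature if feature is not None else ["promoter"] * n_probes,
    }, index=pd.Index(probe_ids, name="probe_id"))
    samples = pd.DataFrame({"group": list(groups)},
                           index=pd.Index(sample_ids, name="sample_id"))
    det = None
    if detection_p is not None:
        det = pd.DataFrame(np.asarray(detection_p, dtype=float),
                           index=ann.index, columns=sample_ids)
    return MethylationDataset(
        annotation=ann,
        beta=pd.DataFrame(beta, index=ann.index, columns=sample_ids),
        samples=samples,
        detection_p=det,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across tests (seed fixed)."""
    cfg = SimulationConfig(seed=7, n_islands=200)
    ds, truth = simulate_dataset(cfg)
    return cfg, ds, truth
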