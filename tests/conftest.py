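"""Shared fixtures: one planted ground truth with strong modules
(|rho| ~ 0.63-0.73) and datasets/networks derived from it, session-scoped so
the expensive inference runs once."""

import numpy as np
import pandas as pd
import pytest

import metabnet as mn
from metabnet.matrix import TRANSCRIPT, OmicsMatrix


@pytest.fixture(scope="session")
def gt_strong():
    """20 metabolites x 20 disjoint targets, no latent coupling, planted
    |rho| in ~0.63-0.73, 400 background transcripts."""
    return mn.build_ground_truth(
        n_metabolites=20,
        targets_per_metabolite=20,
        beta_range=(1.0, 1.4),
        coupling=None,
        n_background=400,
        sigma_m=0.5,
        seed=42,
    )


@pytest.fixture(scope="session")
def sim_a(gt_strong):
    """Training dataset: n = 300 samples."""
    return mn.simulate_dataset(gt_strong, 300, seed=43)


@pytest.fixture(scope="session")
def sim_b(gt_strong):
    """Held-out dataset from the same ground truth: n = 57 samples."""
    return mn.simulate_dataset(gt_strong, 57, seed=99)


@pytest.fixture(scope="session")
def combined_a(sim_a):
    return mn.combine_matrices(sim_a.metabolites, sim_a.transcripts)


@pytest.fixture(scope="session")
def net_a(combined_a):
    """Network inferred from dataset A at the default gate, B = 100."""
    cfg = mn.InferenceConfig(p_threshold=0.001, n_bootstraps=100, seed=7)
    return mn.infer_network(combined_a, cfg)


@pytest.fixture(scope="session")
def gt_coupled():
    """Consecutive metabolite pairs coupled at 0.9: every target of one
    metabolite induces an indirect candidate edge to its partner."""
    return mn.build_ground_truth(
        n_metabolites=20,
        targets_per_metabolite=20,
        beta_range=(1.0, 1.4),
        coupling=0.9,
        n_background=400,
        sigma_m=0.5,
        seed=1,
    )


@pytest.fixture(scope="session")
def sim_coupled(gt_coupled):
    return mn.simulate_dataset(gt_coupled, 300, seed=2)


@pytest.fixture(scope="session")
def combined_coupled(sim_coupled):
    return mn.combine_matrices(sim_coupled.metabolites, sim_coupled.transcripts)


def noise_expression(gene_ids, n_samples, seed):
    """Structure-free expression: iid standard-normal genes."""
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal((len(gene_ids), n_samples))
    cols = [f"s{i:03d}" for i in range(n_samples)]
    return OmicsMatrix.from_frame(
        pd.DataFrame(vals, index=list(gene_ids), columns=cols), TRANSCRIPT
    )
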