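import numpy as np
import pandas as pd
import pytest

from rejuvseq import DesignSpec, SurvivalParams, simulate_experiment, simulate_survival


@pytest.fixture(scope="session")
def reversal_dataset():
    """Planted three-group aging/treatment dataset at the default conditions."""
    spec = DesignSpec.aging_reversal(
        n_per_group=5, n_genes=2000, frac_aging=0.1, frac_reverted=0.5,
        effect_size=2.0, dispersion=0.05, seed=11,
    )
    counts, annotation, sheet, truth = simulate_experiment(spec)
    return dict(spec=spec, counts=counts, annotation=annotation, sheet=sheet, truth=truth)


@pytest.fixture(scope="session")
def factorial_dataset():
    """WT/knockout x Veh/treated dataset with 80% knockout-dependent responses."""
    spec = DesignSpec.factorial(
        n_per_group=5, n_genes=2000, frac_responsive=0.1, frac_dependent=0.8,
        effect_size=2.0, dispersion=0.05, seed=12,
    )
    counts, annotation, sheet, truth = simulate_experiment(spec)
    return dict(spec=spec, counts=counts, annotation=annotation, sheet=sheet, truth=truth)


@pytest.fixture(scope="session")
def survival_dataset():
    return simulate_survival(50, 50, SurvivalParams(seed=21))


def make_contrast_table(gene_ids, log2_fc, p_raw, q_bh=None):
    """Hand-built ContrastTable for classifier unit tests."""
    p = np.asarray(p_raw, dtype=float)
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "log2_fc": np.asarray(log2_fc, dtype=float),
            "p_raw": p,
            "q_bh": p if q_bh is None else np.asarray(q_bh, dtype=float),
        }
    )
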