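import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort reused across integration tests."""
    from neoprior import synthetic

    cfg = synthetic.SimulationConfig(
        n_patients=6,
        mutations_per_patient_mean=25.0,
        mutation_count_range=(5, 80),
        n_expression_genes=300,
        n_expression_samples=60,
        seed=7,
    )
    return synthetic.generate_cohort(cfg)


def make_candidates(n_i_only, n_ii_only, n_both, n_expressed=None):
    """Candidate frame with prescribed class-label category counts."""
    labels = (["I-only"] * n_i_only + ["II-only"] * n_ii_only
              + ["both"] * n_both)
    n = len(labels)
    df = pd.DataFrame({
        "mutation_id": [f"M{i:04d}" for i in range(n)],
        "patient": ["P01"] * n,
        "gene": [f"G{i:04d}" for i in range(n)],
        "is_cgc": [False] * n,
        "vaf": np.linspace(0.05, 0.6, n) if n else [],
        "class_label": labels,
        "best_nm": np.linspace(20, 140, n) if n else [],
        "best_diff": np.full(n, 300.0),
        "gene_rpkm": np.full(n, 5.0),
    })
    if n_expressed is not None:
        df["expressed"] = [i < n_expressed for i in range(n)]
    return df
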