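import pandas as pd
import pytest

from tfdep import SimulationParams, simulate_experiment, test_induction, to_unit


@pytest.fixture(scope="session")
def perfect_dependence_data():
    """Noise-free simulation where every induced gene loses its induction
    in background 2 (delta = 0), so the dependence plot is exactly y = x."""
    params = SimulationParams(
        n_genes=2000,
        frac_induced=0.25,
        frac_dependent_impaired=1.0,
        frac_dependent_enhanced=0.0,
        dependence_factor=0.0,
        dispersion=0.0,
        seed=1,
    )
    matrix, design, truth = simulate_experiment(params)
    cpm = to_unit(matrix, "cpm")
    de_wt = test_induction(cpm, "WT")
    de_ko = test_induction(cpm, "KO")
    return params, matrix, truth, de_wt, de_ko


@pytest.fixture(scope="session")
def recovery_data():
    """Noisy simulation (phi = 0.05) with 80% of induced genes impaired,
    used for end-to-end parameter-recovery checks."""
    params = SimulationParams(
        n_genes=2000,
        frac_induced=0.25,
        frac_dependent_impaired=0.8,
        frac_dependent_enhanced=0.0,
        dependence_factor=0.0,
        dispersion=0.05,
        n_replicates=4,
        seed=11,
    )
    matrix, design, truth = simulate_experiment(params)
    cpm = to_unit(matrix, "cpm")
    de_wt = test_induction(cpm, "WT")
    de_ko = test_induction(cpm, "KO")
    truth_frame = pd.DataFrame(
        [(t.gene_id, t.induced, t.dependence_class) for t in truth],
        columns=["gene_id", "induced", "dependence_class"],
    ).set_index("gene_id")
    return params, truth_frame, de_wt, de_ko
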