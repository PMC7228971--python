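import pandas as pd
import pytest

from ewskit import contrasts, matrix
from ewskit.simulate import SimulationConfig, simulate_knockdown_experiment


@pytest.fixture(scope="session")
def knockdown_default():
    """Default knockdown simulation (seed 0) shared across tests."""
    cfg = SimulationConfig(seed=0)
    gene_m, psr_m, design, psr_map, truth = simulate_knockdown_experiment(cfg)
    return {
        "cfg": cfg,
        "gene": gene_m,
        "psr": psr_m,
        "design": design,
        "psr_map": psr_map,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def knockdown_noisefree():
    """Noise-free simulation: every statistic equals its construction value."""
    cfg = SimulationConfig(noise_sd=0.0, seed=0)
    gene_m, psr_m, design, psr_map, truth = simulate_knockdown_experiment(cfg)
    return {
        "cfg": cfg,
        "gene": gene_m,
        "psr": psr_m,
        "design": design,
        "psr_map": psr_map,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def gene_contrasts_default(knockdown_default):
    kd = knockdown_default
    kept = matrix.expression_floor_filter(kd["gene"], kd["design"])
    return kept, contrasts.build_contrast_table(kd["gene"], kd["design"], features=kept)


@pytest.fixture
def tiny_matrix():
    """4 genes x 12 samples, 1 cell line x {ctrl, target} x dox x 3 reps."""
    rows = []
    for construct in ("shCtrl", "shT1"):
        for dox in ("minus", "plus"):
            for rep in (1, 2, 3):
                rows.append(
                    {
                        "sample_id": f"CL1_{construct}_{dox}_r{rep}",
                        "cell_line": "CL1",
                        "construct": construct,
                        "dox": dox,
                        "replicate": rep,
                    }
                )
    design = matrix.DesignSheet(pd.DataFrame(rows), control="shCtrl")
    values = pd.DataFrame(
        8.0, index=[f"g{i}" for i in range(4)], columns=[r["sample_id"] for r in rows]
    )
    return matrix.ExpressionMatrix(values, scale=matrix.LOG2), design
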