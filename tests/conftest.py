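import numpy as np
import pandas as pd
import pytest

from symsel.simulate import (AssayEffects, SimConfig, simulate_experiment,
                             simulate_fitness_assays, simulate_study)


@pytest.fixture(scope="session")
def study():
    """One simulated three-regime study at the design defaults."""
    cfg = SimConfig(seed=42)
    snp, counts, panel, exps = simulate_study(cfg, n_noise_snps=40)
    return {"config": cfg, "snp": snp, "counts": counts, "panel": panel,
            "experiments": exps}


@pytest.fixture(scope="session")
def assay_tables():
    """Simulated survival/fecundity/titer assays (non-factorial)."""
    surv, fec, tit = simulate_fitness_assays(AssayEffects(), seed=7)
    return surv, fec, tit


@pytest.fixture(scope="session")
def factorial_tables():
    """Smaller factorial (cytotype x presence) assay simulation."""
    eff = AssayEffects(factorial=True, n_crosses=6, vials_per_group=5,
                       females_per_group=12)
    return simulate_fitness_assays(eff, seed=19)
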