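import numpy as np
import pandas as pd
import pytest

from coexqtl.simulate import (
    EqtlSpec,
    ModuleSpec,
    SimConfig,
    simulate_annotation,
    simulate_expression,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with planted local/distant eQTLs shared by cheap tests."""
    config = SimConfig(
        n_snps=600,
        n_genes=40,
        n_chromosomes=3,
        seed=11,
        h2_target=0.8,
        eqtl_plan=(
            [EqtlSpec(placement="local", ve=v) for v in np.linspace(0.35, 0.55, 8)]
            + [EqtlSpec(placement="distant", ve=0.45), EqtlSpec(placement="distant", ve=0.5)]
        ),
    )
    genotypes = simulate_genotypes(config)
    annotation = simulate_annotation(config)
    expression, truth = simulate_expression(genotypes, annotation, config)
    return config, genotypes, annotation, expression, truth


@pytest.fixture(scope="session")
def module_cohort():
    """Three planted co-expression modules with hub cores."""
    config = SimConfig(
        n_snps=10,
        n_genes=130,
        seed=21,
        h2_target=0.85,
        module_plan=[
            ModuleSpec(50, 5, 0.9, 0.5),
            ModuleSpec(40, 4, 0.9, 0.5),
            ModuleSpec(30, 3, 0.9, 0.5),
        ],
    )
    genotypes = simulate_genotypes(config)
    annotation = simulate_annotation(config)
    expression, truth = simulate_expression(genotypes, annotation, config)
    return config, genotypes, annotation, expression, truth
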