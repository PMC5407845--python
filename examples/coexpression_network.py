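"""Build the co-expression network, detect modules, flag cores/periphery
and test a gene attribute against the topology by label permutation.

Adjacency is unsigned (|r|^5) so strong negative co-regulation is kept;
the topological overlap matrix is the signed variant, whose shared-
neighbour sum respects correlation signs. Module cores are the top decile
of normalised intra/inter connectivity difference with intra-modular
connectivity above 1.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from coexqtl import network
from coexqtl.quantgen import genotype_means
from coexqtl.simulate import (
    ModuleSpec, SimConfig, simulate_annotation, simulate_expression,
    simulate_genotypes,
)

config = SimConfig(
    n_snps=10, n_genes=130, seed=23, h2_target=0.85,
    module_plan=[ModuleSpec(50, 5, 0.9, 0.5),
                 ModuleSpec(40, 4, 0.9, 0.5),
                 ModuleSpec(30, 3, 0.9, 0.5)],
)
genotypes = simulate_genotypes(config)
annotation = simulate_annotation(config)
expression, truth = simulate_expression(genotypes, annotation, config)
means = genotype_means(expression, genotypes.samples)

model = network.build_network(means.sub(means.mean(axis=1), axis=0), beta=5)
labels = network.detect_modules(model.dissimilarity, min_module_size=20)
stats = network.node_statistics(model, labels)
flags = network.define_cores_and_periphery(model, labels, stats)

ari = adjusted_rand_score(truth.module_membership.to_numpy(), labels)
print(f"modules detected: {labels.max()} "
      f"(sizes {[int((labels == m).sum()) for m in range(1, labels.max() + 1)]})")
print(f"adjusted Rand index vs planted membership: {ari:.3f}")
hub_core = flags["core"].to_numpy()[truth.hub_flags.to_numpy()]
print(f"planted hubs flagged as module cores: {hub_core.mean():.0%}")
print(f"peripheral genes (degree 1 at |r| > 0.4): "
      f"{int(flags['peripheral'].sum())}")

# permutation test: are hub-planted genes enriched in detected cores?
core = flags["core"].to_numpy()
attr = truth.hub_flags.to_numpy().astype(float)
res = network.label_permutation_test(
    attr, lambda a: float(a[core].sum()), n_perm=2000, rng=24,
    alternative="greater",
)
print(f"hub-in-core enrichment: observed {res.observed:.0f}, "
      f"permutation p = {res.p:.4f} ({res.n_perm} shuffles)")
# A small p confirms that the detected cores coincide with the planted
# hubs far beyond what random gene labelling produces.
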