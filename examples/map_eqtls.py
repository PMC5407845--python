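"""Map eQTLs with a permutation empirical FDR and score recovery.

Simulates 86 genotypes x 150 genes x 1,500 SNPs with 30 planted local
eQTLs (30-50% of genotype-mean variance), then runs the full mapping stack:
MAF/MGF variant filters, LD-pruned population-structure covariate, per-pair
additive linear models, gene-wise max-|t| permutation null (500 shuffles
here; the study design uses 1,000) and Storey q-values.
"""

import numpy as np

from coexqtl import eqtl
from coexqtl.quantgen import genotype_means
from coexqtl.simulate import (
    EqtlSpec, SimConfig, simulate_annotation, simulate_expression,
    simulate_genotypes,
)

config = SimConfig(
    n_snps=1500, n_genes=150, seed=11, h2_target=0.8,
    eqtl_plan=[EqtlSpec(placement="local", ve=v)
               for v in np.linspace(0.3, 0.5, 30)],
)
genotypes = simulate_genotypes(config)
annotation = simulate_annotation(config)
expression, truth = simulate_expression(genotypes, annotation, config)
means = genotype_means(expression, genotypes.samples)

vstats, filtered = eqtl.filter_variants(genotypes)
print(f"variants: {genotypes.n_variants} -> {filtered.n_variants} "
      f"after MAF >= 0.1 and MGF <= 0.9")

covariate = eqtl.structure_covariate(filtered)
scan = eqtl.map_associations(means, filtered, covariate)
records = eqtl.empirical_fdr(scan, means, filtered, covariate,
                             n_perm=500, rng=np.random.default_rng(12))
records = eqtl.classify_local_distant(records, annotation, filtered.variants)

sig = records[records["significant"]]
found = set(sig["gene"])
planted = set(truth.planted_eqtls["gene"])
print(f"significant associations (q <= 0.05): {len(sig)}")
print(f"eGenes found: {len(found)}; planted eGenes recovered: "
      f"{len(found & planted)}/{len(planted)}; false eGenes: "
      f"{len(found - planted)}")
print(f"local/distant split of significant eQTLs: "
      f"{(sig['class'] == 'local').sum()}/{(sig['class'] == 'distant').sum()}")
# Recovery near 100% with no false eGenes is expected at these effect
# sizes; each planted SNP (and its LD copies) should surface as local.
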