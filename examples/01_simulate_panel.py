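"""Simulate a structured inbred breeding panel and write it to disk.

The default configuration mirrors a spring-wheat genomic-selection panel:
383 fully homozygous lines in three pedigree clusters (176/89/118), 21
chromosomes with 100 mapped markers each, strong adjacent-marker LD, and
two traits at entry-mean heritabilities 0.3 (yield-like) and 0.7
(protein-like) measured in two trials on a 20x20 field grid.
"""

from haplogs import (SimConfig, apply_field_layout, simulate_phenotypes,
                     simulate_population, write_dataset)

cfg = SimConfig(seed=1)
pop = simulate_population(cfg)
pheno = apply_field_layout(simulate_phenotypes(pop, cfg), cfg)
paths = write_dataset(pop, pheno, "example_panel")

g = pop.genotypes
print(f"panel: {g.n_lines} lines x {g.n_markers} markers, "
      f"clusters {pop.true_cluster_labels.value_counts().sort_index().to_dict()}")
print(f"phenotype rows: {len(pheno)} (lines x trials), "
      f"traits: {list(cfg.heritability_targets)}")
print("files:", paths)
# The HapMap file round-trips through haplogs.genio.read_hapmap; the truth
# (cluster labels, QTL effects, additive values) stays on the SimPopulation.
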