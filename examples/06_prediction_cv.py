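"""Single-SNP vs multi-allelic haplotype GBLUP under two CV designs.

Fits both models on a panel whose QTL effects act on local 5-marker
haplotype combinations — the architecture where haplotype alleles carry
signal that single-SNP additive coding can only partly represent — and
compares k-fold cross validation with stratified sampling that draws 75%
of every cluster into the calibration set.
"""

from haplogs import (SimConfig, build_hap_design, build_snp_design,
                     combine_trials, cross_validate, ibs_distance,
                     kmeans_cluster, make_kfold, make_stratified,
                     paired_comparison, build_blocks, simulate_phenotypes,
                     simulate_population)

cfg = SimConfig(seed=8, qtl_mode="haplotype", n_qtl=60, hap_qtl_span=5,
                heritability_targets={"yield": 0.5},
                spatial_trend_amplitude=0.0)
pop = simulate_population(cfg)
y = combine_trials(simulate_phenotypes(pop, cfg), "yield")
g, gmap = pop.genotypes, pop.gmap

designs = {"single_snp": build_snp_design(g),
           "haploblock_5": build_hap_design(build_blocks(g, gmap, 5))}
assign = kmeans_cluster(ibs_distance(g), K=3, restarts=50, seed=0)
schemes = {
    "kfold": make_kfold(list(y.index), k=4, repetitions=2, seed=0),
    "stratified": make_stratified(list(y.index), assign.labels, 0.75,
                                  repetitions=8, seed=0),
}

results = {}
for sname, scheme in schemes.items():
    for mname, W in designs.items():
        r = cross_validate(y, W, scheme, model_name=mname)["r"]
        results[(sname, mname)] = r
        print(f"{sname:>11} {mname:<13} mean r = {r.mean():.3f}")

pct, p = paired_comparison(results[("kfold", "single_snp")],
                           results[("kfold", "haploblock_5")])
print(f"haplotype vs SNP under k-fold: {pct:+.1f}% change in mean r "
      f"(paired t on Fisher-Z, p = {p:.3g})")
# The 5-marker haplotype alleles capture local allele combinations the
# SNP coding cannot, so their mean r tends to sit above the SNP model's;
# on any single panel the gap is small relative to replicate noise, which
# is why the comparison is run over many replicates and paired by split.
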