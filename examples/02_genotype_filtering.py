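"""Genotype stage: polymorphism filter, redundancy collapse, hybrid
genotypes and pathway SNP selection.

Loads the parent panels back from the VCFs written by the generator, to
show the file-based entry point a real study would use.
"""

from pathlib import Path

from hybridgs import (
    SimConfig, collapse_redundant, filter_polymorphic, infer_hybrid_genotypes,
    read_design_csv, read_parents_vcf, read_pathway_bed, select_pathway_snps,
    simulate_study, write_study,
)

outdir = Path("scratch/example_study")
cfg = SimConfig(n_females=12, n_males=12, n_loci=400, n_chromosomes=4,
                n_crosses=70, n_envs=3, duplicate_fraction=0.08, seed=11)
paths = write_study(simulate_study(cfg), outdir)

females = read_parents_vcf(str(paths["females_vcf"]), "female")
males = read_parents_vcf(str(paths["males_vcf"]), "male")
design = read_design_csv(str(paths["design_csv"]))
pathway = read_pathway_bed(str(paths["pathway_bed"]), window=1000)

keep = filter_polymorphic(females, males)  # drop loci monomorphic in BOTH pools
f1, m1 = females.subset_loci(keep), males.subset_loci(keep)
referent, groups = collapse_redundant(f1, m1)  # one referent per complete-LD group
f2, m2 = f1.subset_loci(referent), m1.subset_loci(referent)
print(f"{females.n_loci} loci -> {keep.sum()} polymorphic -> {f2.n_loci} non-redundant")

hybrids = infer_hybrid_genotypes(design, f2, m2)
hid, arr = next(iter(hybrids.items()))
het = (arr[:, 0] != arr[:, 1]).mean()
print(f"hybrid {hid}: {het:.0%} heterozygous loci (= parental Hamming distance)")

mask = select_pathway_snps(f2.loci, pathway)
print(f"pathway SNPs within {pathway.window} bp of {len(pathway.genes)} genes: {mask.sum()}")
# Redundant SNPs carry no extra kinship information; the referent mask and
# group map let any locus-level result be traced back to its LD group.
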