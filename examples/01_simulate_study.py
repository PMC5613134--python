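"""Generate a complete synthetic hybrid-breeding study and write its files.

Produces the inputs every later stage consumes: parent VCFs (inbred
maintainer/B and restorer/R lines), the incomplete factorial cross table
with per-environment observation flags, raw field plots, a pathway BED, and
a truth JSON with the generative variance components.
"""

from hybridgs import SimConfig, simulate_study, write_study

cfg = SimConfig(
    n_females=12, n_males=12, n_loci=400, n_chromosomes=4,
    n_crosses=70, n_envs=3, seed=11,
)
study = simulate_study(cfg)
paths = write_study(study, "scratch/example_study")

print(f"parents: {study.females.n_parents} female x {study.males.n_parents} male, "
      f"{study.females.n_loci} SNP loci")
print(f"design: {study.design.n_crosses} crosses, connected = {study.design.is_connected()}")
counts = study.design.crosses["female_id"].value_counts()
print(f"descendants per female: {counts.min()}-{counts.max()}")
print(f"plots: {len(study.plots)} across {cfg.n_envs} environments, "
      f"oil {study.plots['oil'].min():.1f}-{study.plots['oil'].max():.1f}%")
print("generative variance components (per environment):")
print(study.truth.variance_components[["sigma2_f", "sigma2_m", "sigma2_fm", "sigma2_e"]].round(2))
print("files written:", ", ".join(p.name for p in paths.values()))
# The per-environment components are what the REML stage should recover;
# sigma2_f : sigma2_m is ~3:2, mirroring the stronger maternal contribution.
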