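"""Seeded generator of a complete synthetic hybrid-breeding study.

Emulates the structure of a sunflower hybrid trial so that every stage of
the pipeline (genotype filtering, kinship building, REML, cross-validation,
stability screening) is testable without external data: 36 maintainer
(female) x 36 restorer (male) inbred parents, ~490 crosses in a connected,
near-balanced incomplete factorial, 9 environments whose genetic
correlations fall in a configured range (default 0.47-0.77), a female:male
genetic variance ratio near 3:2, an optional female-by-male interaction in
designated environments, and raw field plots with row/column effects and
check varieties around a ~45% oil grand mean.

Ground truth (variance components, per-environment marker effects, genetic
values, the model-scale hybrid phenotypes) is retained for parameter- and
ranking-recovery tests.  All randomness flows from one seed; outputs are
bitwise reproducible for a fixed configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import FactorialDesign, ParentPanel, PathwayAnnotation, select_pathway_snps
from .kinship import center_transmitted

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimStudy",
    "simulate_parents",
    "simulate_design",
    "simulate_pathway",
    "simulate_phenotypes",
    "simulate_study",
    "write_study",
]

_CHROM_SPAN = 1_000_000  # synthetic coordinate span per chromosome


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Variance components are per environment, on the scale of the
    1/L-standardized kernels; ``sigma2_f`` etc. of ``None`` are drawn per
    environment from ranges typical of oil-content trials (female 1.2-3.5,
    residual 1.0-2.0 squared oil %), keeping the female:male ratio at
    ``fm_ratio``.  One environment (by default the fourth) carries a
    female-by-male interaction; the others have none.
    """

    n_females: int = 36
    n_males: int = 36
    n_loci: int = 2000
    n_chromosomes: int = 17
    n_crosses: int = 490
    n_envs: int = 9
    sigma2_f: float | None = None
    sigma2_m: float | None = None
    sigma2_fm: float = 0.7
    sigma2_e: float | None = None
    fm_ratio: float = 1.5
    env_corr_range: tuple[float, float] = (0.47, 0.77)
    interaction_envs: tuple[int, ...] = (3,)
    duplicate_fraction: float = 0.05
    male_divergence: float = 0.05
    n_female_founders: int = 10
    n_male_founders: int = 6
    founder_switch: float = 0.02
    mutation_rate: float = 0.01
    n_pathway_genes: int = 40
    window: int = 1000
    pathway_share: float | None = None
    min_descendants: int | None = None
    max_descendants: int | None = None
    unobserved_rate: float = 0.01
    mean_oil: float = 45.0
    env_mean_sd: float = 2.5
    n_reps: int = 1
    field_cols: int = 20
    row_sd: float = 0.5
    col_sd: float = 0.5
    rep_sd: float = 0.3
    plot_noise_sd: float = 0.5
    n_checks: int = 3
    check_every: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_females, self.n_males, self.n_loci, self.n_envs) < 2:
            raise ValueError("all counts must be >= 2")
        lo, hi = self.env_corr_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("env_corr_range must lie inside (0, 1)")
        for v in (self.sigma2_f, self.sigma2_m, self.sigma2_e):
            if v is not None and v < 0:
                raise ValueError("variance components must be >= 0")
        if self.sigma2_fm < 0:
            raise ValueError("variance components must be >= 0")


@dataclass
class SimTruth:
    """Ground truth retained for recovery tests."""

    variance_components: pd.DataFrame  # per env: sigma2_f/m/fm/e, rho, env_mean
    female_effects: dict[str, np.ndarray]  # env -> per-locus transmitted-allele effects
    male_effects: dict[str, np.ndarray]
    genetic_values: pd.DataFrame  # environment, hybrid_id, value
    hybrid_phenotypes: pd.DataFrame  # environment, hybrid_id, value (model scale)
    pathway_mask: np.ndarray | None
    check_values: dict[str, float]


@dataclass
class SimStudy:
    """A full simulated study: inputs for the pipeline plus the truth."""

    config: SimConfig
    females: ParentPanel
    males: ParentPanel
    design: FactorialDesign
    pathway: PathwayAnnotation
    plots: pd.DataFrame
    truth: SimTruth


def _locus_table(n_loci: int, n_chromosomes: int, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(n_chromosomes, n_loci // n_chromosomes)
    per_chrom[: n_loci % n_chromosomes] += 1
    chroms, poss = [], []
    for c in range(n_chromosomes):
        pos = np.sort(rng.choice(np.arange(1, _CHROM_SPAN), size=per_chrom[c], replace=False))
        chroms.extend([f"Chr{c + 1:02d}"] * per_chrom[c])
        poss.extend(pos.tolist())
    ids = [f"snp_{c}_{p}" for c, p in zip(chroms, poss)]
    return pd.DataFrame({"chrom": chroms, "pos": poss, "id": ids})


def _mosaic_pool(
    n_parents: int,
    founders: np.ndarray,
    founder_groups: np.ndarray,
    parent_groups: np.ndarray,
    chrom_codes: np.ndarray,
    switch: float,
    mutation: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inbred lines as founder mosaics: a Markov founder path along each chromosome."""
    n_founders, L = founders.shape
    out = np.empty((n_parents, L), dtype=np.int8)
    for i in range(n_parents):
        allowed = np.flatnonzero(founder_groups == parent_groups[i])
        path = np.empty(L, dtype=np.intp)
        switches = rng.random(L) < switch
        draws = rng.integers(0, len(allowed), size=L)
        cur = allowed[draws[0]]
        prev_chrom = chrom_codes[0]
        for j in range(L):
            if chrom_codes[j] != prev_chrom or (j > 0 and switches[j]):
                cur = allowed[draws[j]]
                prev_chrom = chrom_codes[j]
            path[j] = cur
        row = founders[path, np.arange(L)]
        flip = rng.random(L) < mutation
        out[i] = np.where(flip, 1 - row, row)
    return out


def simulate_parents(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ParentPanel, ParentPanel]:
    """Draw the two inbred parent pools as founder mosaics.

    Each pool descends from a small set of founder haplotypes (allele
    frequencies uniform on (0.1, 0.9)); every parent is a Markov mosaic of
    its pool's founders with a per-locus switch probability, plus rare
    private mutations.  This produces the within-pool relatedness of an
    elite breeding pool, which is what lets genomic kinship carry
    information to parents without phenotyped descendants.  The male pool
    has fewer founders, split into two subgroups with Balding-Nichols
    frequency divergence ``male_divergence``, so males come out more
    structured and related than females.  A configured fraction of loci are
    exact duplicates or complements of other loci, to exercise redundancy
    collapse downstream.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 1])
    L = cfg.n_loci
    n_dup = int(round(cfg.duplicate_fraction * L))
    n_base = L - n_dup
    loci = _locus_table(n_base, cfg.n_chromosomes, rng)
    chrom_codes = pd.factorize(loci["chrom"])[0]
    p = rng.uniform(0.1, 0.9, size=n_base)

    f_founders = (rng.random((cfg.n_female_founders, n_base)) < p).astype(np.int8)
    females = _mosaic_pool(
        cfg.n_females,
        f_founders,
        np.zeros(cfg.n_female_founders, dtype=int),
        np.zeros(cfg.n_females, dtype=int),
        chrom_codes,
        cfg.founder_switch,
        cfg.mutation_rate,
        rng,
    )

    # male founders: two diverged subgroups (Balding-Nichols around p)
    d = cfg.male_divergence
    m_founders = np.empty((cfg.n_male_founders, n_base), dtype=np.int8)
    m_groups = np.arange(cfg.n_male_founders) % 2
    for grp in (0, 1):
        q = rng.beta(p * (1 - d) / d, (1 - p) * (1 - d) / d) if d > 0 else p
        rows = np.flatnonzero(m_groups == grp)
        m_founders[rows] = (rng.random((len(rows), n_base)) < q).astype(np.int8)
    males = _mosaic_pool(
        cfg.n_males,
        m_founders,
        m_groups,
        np.arange(cfg.n_males) % 2,
        chrom_codes,
        cfg.founder_switch,
        cfg.mutation_rate,
        rng,
    )

    if n_dup > 0:
        src = rng.integers(0, n_base, size=n_dup)
        flip = rng.random(n_dup) < 0.5
        dup_f = females[:, src]
        dup_m = males[:, src]
        dup_f[:, flip] = 1 - dup_f[:, flip]
        dup_m[:, flip] = 1 - dup_m[:, flip]
        females = np.hstack([females, dup_f])
        males = np.hstack([males, dup_m])
        # duplicate loci get fresh coordinates; ParentPanel re-sorts by position
        extra = _locus_table(n_dup, min(cfg.n_chromosomes, n_dup), rng)
        extra["id"] = [f"dup_{i}_{r}" for i, r in enumerate(extra["id"])]
        loci = pd.concat([loci, extra], ignore_index=True)

    order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy()))
    loci = loci.iloc[order].reset_index(drop=True)
    females = females[:, order]
    males = males[:, order]
    f_ids = [f"B{i + 1:02d}" for i in range(cfg.n_females)]
    m_ids = [f"R{i + 1:02d}" for i in range(cfg.n_males)]
    return (
        ParentPanel(f_ids, "female", females, loci.copy()),
        ParentPanel(m_ids, "male", males, loci.copy()),
    )


def simulate_design(
    cfg: SimConfig,
    females: ParentPanel,
    males: ParentPanel,
    rng: np.random.Generator | None = None,
) -> FactorialDesign:
    """Greedy near-balanced connected incomplete factorial.

    Crosses are assigned one at a time to the currently least-used female
    and least-used compatible male (random tie-breaks), which keeps
    per-parent descendant counts within one of each other.  The default
    acceptance window for per-parent counts is the target mean +/- ~1.5
    (12-15 at full size); a configured window that the greedy assignment
    cannot satisfy raises.  About ``unobserved_rate`` of the crosses are
    flagged unobserved per environment.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 2])
    nf, nm = females.n_parents, males.n_parents
    if cfg.n_crosses > nf * nm:
        raise ValueError("more crosses requested than the factorial grid allows")
    for attempt in range(20):
        counts_f = np.zeros(nf, dtype=int)
        counts_m = np.zeros(nm, dtype=int)
        used: set[tuple[int, int]] = set()
        pairs: list[tuple[int, int]] = []
        ok = True
        for _ in range(cfg.n_crosses):
            forder = np.lexsort((rng.random(nf), counts_f))
            placed = False
            for fi in forder:
                morder = np.lexsort((rng.random(nm), counts_m))
                for mi in morder:
                    if (fi, mi) not in used:
                        used.add((fi, mi))
                        pairs.append((fi, mi))
                        counts_f[fi] += 1
                        counts_m[mi] += 1
                        placed = True
                        break
                if placed:
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        mean_f = cfg.n_crosses / nf
        mean_m = cfg.n_crosses / nm
        lo_f = cfg.min_descendants if cfg.min_descendants is not None else math.floor(mean_f) - 1
        hi_f = cfg.max_descendants if cfg.max_descendants is not None else math.ceil(mean_f) + 1
        lo_m = cfg.min_descendants if cfg.min_descendants is not None else math.floor(mean_m) - 1
        hi_m = cfg.max_descendants if cfg.max_descendants is not None else math.ceil(mean_m) + 1
        if not (
            (counts_f >= lo_f).all()
            and (counts_f <= hi_f).all()
            and (counts_m >= lo_m).all()
            and (counts_m <= hi_m).all()
        ):
            if cfg.min_descendants is not None or cfg.max_descendants is not None:
                raise ValueError("greedy assignment cannot satisfy the descendant-count window")
            continue
        crosses = pd.DataFrame(
            {
                "hybrid_id": [f"{females.parent_ids[f]}x{males.parent_ids[m]}" for f, m in pairs],
                "female_id": [females.parent_ids[f] for f, _ in pairs],
                "male_id": [males.parent_ids[m] for _, m in pairs],
            }
        )
        env_names = [f"E{i + 1:02d}" for i in range(cfg.n_envs)]
        obs = pd.DataFrame(
            rng.random((cfg.n_crosses, cfg.n_envs)) >= cfg.unobserved_rate, columns=env_names
        )
        design = FactorialDesign(crosses=crosses, observed=obs)
        if design.is_connected():
            return design
    raise RuntimeError("could not generate a connected balanced design")


def simulate_pathway(
    cfg: SimConfig, loci: pd.DataFrame, rng: np.random.Generator | None = None
) -> PathwayAnnotation:
    """Gene intervals centered on randomly chosen SNPs (so the mask is non-empty)."""
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 4])
    n_genes = min(cfg.n_pathway_genes, len(loci))
    centers = rng.choice(len(loci), size=n_genes, replace=False)
    half_len = rng.integers(500, 2500, size=n_genes)
    genes = pd.DataFrame(
        {
            "chrom": loci["chrom"].to_numpy()[centers],
            "start": np.maximum(1, loci["pos"].to_numpy()[centers] - half_len),
            "end": loci["pos"].to_numpy()[centers] + half_len,
            "id": [f"gene_{i + 1:03d}" for i in range(n_genes)],
        }
    )
    return PathwayAnnotation(genes=genes, window=cfg.window)


def _draw_components(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    envs = [f"E{i + 1:02d}" for i in range(cfg.n_envs)]
    s2f = (
        np.full(cfg.n_envs, cfg.sigma2_f)
        if cfg.sigma2_f is not None
        else rng.uniform(1.2, 3.5, cfg.n_envs)
    )
    s2m = np.full(cfg.n_envs, cfg.sigma2_m) if cfg.sigma2_m is not None else s2f / cfg.fm_ratio
    s2e = (
        np.full(cfg.n_envs, cfg.sigma2_e)
        if cfg.sigma2_e is not None
        else rng.uniform(1.0, 2.0, cfg.n_envs)
    )
    s2fm = np.zeros(cfg.n_envs)
    for j in cfg.interaction_envs:
        if 0 <= j < cfg.n_envs:
            s2fm[j] = cfg.sigma2_fm
    rho = rng.uniform(*cfg.env_corr_range, cfg.n_envs)
    mu = cfg.mean_oil + rng.normal(0.0, cfg.env_mean_sd, cfg.n_envs)
    return pd.DataFrame(
        {"sigma2_f": s2f, "sigma2_m": s2m, "sigma2_fm": s2fm, "sigma2_e": s2e, "rho": rho, "env_mean": mu},
        index=pd.Index(envs, name="environment"),
    )


def _effect_scale(
    sigma2: float, col_var: np.ndarray, mask: np.ndarray | None, share: float | None
) -> np.ndarray:
    """Per-locus effect SDs so the realized parental variance is sigma2.

    ``col_var`` are the per-locus variances of the centered transmitted
    alleles; with iid effects of variance w_l the parental genetic variance
    is sum_l w_l var_l, so uniform w = sigma2 / sum(var_l).  With a pathway
    share s, the pathway loci carry s of the variance and the rest 1 - s.
    """
    total = float(col_var.sum())
    if total == 0:
        raise ValueError("all loci monomorphic; no genetic variance possible")
    sd = np.full(len(col_var), math.sqrt(sigma2 / total))
    if mask is not None and share is not None:
        in_path = float(col_var[mask].sum())
        out_path = total - in_path
        if in_path > 0 and out_path > 0:
            sd = np.where(
                mask,
                math.sqrt(sigma2 * share / in_path),
                math.sqrt(sigma2 * (1.0 - share) / out_path),
            )
    return sd


def simulate_phenotypes(
    cfg: SimConfig,
    females: ParentPanel,
    males: ParentPanel,
    design: FactorialDesign,
    pathway_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate field plots plus the retained truth.

    Per-locus transmitted-allele effects are drawn with a common-factor
    construction, effect_e = sqrt(rho_e) * shared + sqrt(1 - rho_e) *
    specific_e, so pairwise genetic correlations between environments land
    in the configured range.  Female effect variances exceed male ones by
    ``fm_ratio``.  The model-scale hybrid phenotype (mean + female + male
    [+ interaction] + residual) is retained in the truth; plots add
    row/column/repetition factor effects, interleaved check varieties and
    plot noise on top of it.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 3])
    comp = _draw_components(cfg, rng)
    X = center_transmitted(females).values
    Z = center_transmitted(males).values
    L = X.shape[1]
    envs = list(comp.index)

    f_shared = rng.normal(size=L)
    m_shared = rng.normal(size=L)
    fidx = {p: i for i, p in enumerate(females.parent_ids)}
    midx = {p: i for i, p in enumerate(males.parent_ids)}
    crosses = design.crosses
    fi = np.array([fidx[f] for f in crosses["female_id"]])
    mi = np.array([midx[m] for m in crosses["male_id"]])

    var_f = X.var(axis=0)
    var_m = Z.var(axis=0)
    svar_f, svar_m = float(var_f.sum()), float(var_m.sum())
    # equivalent components on the 1/L-kernel scale (what REML on K estimates)
    comp["sigma2_f_kernel"] = comp["sigma2_f"] * L / svar_f
    comp["sigma2_m_kernel"] = comp["sigma2_m"] * L / svar_m
    comp["sigma2_fm_kernel"] = comp["sigma2_fm"] * L**2 / (svar_f * svar_m)

    female_effects: dict[str, np.ndarray] = {}
    male_effects: dict[str, np.ndarray] = {}
    genetic_rows = []
    pheno_rows = []
    for e, env in enumerate(envs):
        row = comp.loc[env]
        rho = float(row["rho"])
        a = math.sqrt(rho) * f_shared + math.sqrt(1 - rho) * rng.normal(size=L)
        b = math.sqrt(rho) * m_shared + math.sqrt(1 - rho) * rng.normal(size=L)
        a = a * _effect_scale(float(row["sigma2_f"]), var_f, pathway_mask, cfg.pathway_share)
        b = b * _effect_scale(float(row["sigma2_m"]), var_m, pathway_mask, cfg.pathway_share)
        female_effects[env] = a
        male_effects[env] = b
        uf = X @ a
        um = Z @ b
        g = uf[fi] + um[mi]
        if float(row["sigma2_fm"]) > 0:
            tau = math.sqrt(float(row["sigma2_fm"]) / (svar_f * svar_m))
            C = rng.normal(size=(L, L)) * tau
            inter_grid = X @ C @ Z.T
            g = g + inter_grid[fi, mi]
        eps = rng.normal(0.0, math.sqrt(float(row["sigma2_e"])), size=len(crosses))
        y = float(row["env_mean"]) + g + eps
        genetic_rows.append(
            pd.DataFrame({"environment": env, "hybrid_id": crosses["hybrid_id"], "value": g})
        )
        pheno_rows.append(
            pd.DataFrame({"environment": env, "hybrid_id": crosses["hybrid_id"], "value": y})
        )
    genetic_values = pd.concat(genetic_rows, ignore_index=True)
    hybrid_phenotypes = pd.concat(pheno_rows, ignore_index=True)

    check_values = {
        f"CHK{i + 1}": float(cfg.mean_oil + rng.normal(0.0, 2.0)) for i in range(cfg.n_checks)
    }
    plots = _lay_out_plots(cfg, design, hybrid_phenotypes, check_values, rng)
    truth = SimTruth(
        variance_components=comp,
        female_effects=female_effects,
        male_effects=male_effects,
        genetic_values=genetic_values,
        hybrid_phenotypes=hybrid_phenotypes,
        pathway_mask=None if pathway_mask is None else np.asarray(pathway_mask, bool),
        check_values=check_values,
    )
    return plots, truth


def _lay_out_plots(
    cfg: SimConfig,
    design: FactorialDesign,
    hybrid_phenotypes: pd.DataFrame,
    check_values: dict[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    records = []
    checks = list(check_values)
    pheno = hybrid_phenotypes.set_index(["environment", "hybrid_id"])["value"]
    for env in design.environments:
        observed = design.crosses.loc[design.observed[env].to_numpy(), "hybrid_id"].tolist()
        entries: list[tuple[str, str]] = []
        for rep in range(cfg.n_reps):
            order = rng.permutation(len(observed))
            entries.extend((f"rep{rep + 1}", observed[j]) for j in order)
        if checks and cfg.check_every > 0:
            # check plots at random field positions (about one per
            # check_every plots), cycling through the check varieties
            n_check_plots = max(1, len(entries) // cfg.check_every)
            for i in range(n_check_plots):
                pos = int(rng.integers(0, len(entries) + 1))
                entries.insert(pos, ("check", checks[i % len(checks)]))
        n_rows = math.ceil(len(entries) / cfg.field_cols)
        row_eff = rng.normal(0.0, cfg.row_sd, n_rows)
        col_eff = rng.normal(0.0, cfg.col_sd, cfg.field_cols)
        rep_eff = rng.normal(0.0, cfg.rep_sd, cfg.n_reps) if cfg.n_reps > 1 else np.zeros(cfg.n_reps)
        for idx, (tag, geno) in enumerate(entries):
            r, c = divmod(idx, cfg.field_cols)
            if tag == "check":
                base = check_values[geno]
                status, rep_id = "check", "rep1"
                rep_add = 0.0
            else:
                base = float(pheno.loc[(env, geno)])
                status, rep_id = "hybrid", tag
                rep_add = float(rep_eff[int(tag[3:]) - 1])
            oil = base + row_eff[r] + col_eff[c] + rep_add + rng.normal(0.0, cfg.plot_noise_sd)
            records.append(
                {
                    "environment": env,
                    "row": r + 1,
                    "column": c + 1,
                    "repetition": rep_id,
                    "genotype": geno,
                    "status": status,
                    "oil": float(np.clip(oil, 1.0, 99.0)),
                }
            )
    return pd.DataFrame.from_records(records)


def simulate_study(cfg: SimConfig) -> SimStudy:
    """Generate parents, design, pathway annotation, plots and truth from one seed."""
    females, males = simulate_parents(cfg)
    design = simulate_design(cfg, females, males)
    pathway = simulate_pathway(cfg, females.loci)
    mask = select_pathway_snps(females.loci, pathway)
    plots, truth = simulate_phenotypes(cfg, females, males, design, pathway_mask=mask)
    return SimStudy(
        config=cfg, females=females, males=males, design=design, pathway=pathway,
        plots=plots, truth=truth,
    )


def _write_vcf(panel: ParentPanel, path: Path) -> None:
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for chrom in panel.loci["chrom"].unique():
        lines.append(f"##contig=<ID={chrom},length={_CHROM_SPAN + 10_000}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.parent_ids))
    for j in range(panel.n_loci):
        chrom = panel.loci["chrom"].iat[j]
        pos = panel.loci["pos"].iat[j]
        sid = panel.loci["id"].iat[j]
        gts = "\t".join("1/1" if a else "0/0" for a in panel.alleles[:, j])
        lines.append(f"{chrom}\t{pos}\t{sid}\tA\tT\t.\tPASS\t.\tGT\t{gts}")
    path.write_text("\n".join(lines) + "\n")


def write_study(study: SimStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the study as plain-text pipeline inputs plus a truth JSON.

    females.vcf / males.vcf, design.csv (cross table + per-environment
    observation flags), plots.csv, pathway.bed (0-based half-open) and
    truth.json (config + per-environment variance components).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "females_vcf": outdir / "females.vcf",
        "males_vcf": outdir / "males.vcf",
        "design_csv": outdir / "design.csv",
        "plots_csv": outdir / "plots.csv",
        "pathway_bed": outdir / "pathway.bed",
        "truth_json": outdir / "truth.json",
    }
    _write_vcf(study.females, paths["females_vcf"])
    _write_vcf(study.males, paths["males_vcf"])
    pd.concat([study.design.crosses, study.design.observed], axis=1).to_csv(
        paths["design_csv"], index=False
    )
    study.plots.to_csv(paths["plots_csv"], index=False)
    bed = study.pathway.genes.copy()
    bed["start"] = bed["start"] - 1  # back to BED 0-based half-open
    bed[["chrom", "start", "end", "id"]].to_csv(paths["pathway_bed"], sep="\t", header=False, index=False)
    truth = {
        "config": asdict(study.config),
        "variance_components": study.truth.variance_components.reset_index().to_dict(orient="records"),
        "check_values": study.truth.check_values,
    }
    paths["truth_json"].write_text(json.dumps(truth, indent=2, default=float))
    return paths
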