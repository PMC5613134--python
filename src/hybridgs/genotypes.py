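"""Parental genotype panels, factorial-design bookkeeping and SNP set selection.

The study system is a hybrid breeding program: two pools of fully inbred
parental lines (maintainer/female B-lines and restorer/male R-lines) are
crossed in an incomplete factorial design, and each hybrid's genotype is
entirely determined by its two homozygous parents.  This module loads the
parental variant calls, applies the marker filters (polymorphism, redundancy
collapse), deduces hybrid genotypes and selects SNPs lying in or near a set
of annotated genes (e.g. an oil-metabolism pathway).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ParentPanel",
    "FactorialDesign",
    "PathwayAnnotation",
    "read_parents_vcf",
    "read_design_csv",
    "read_pathway_bed",
    "filter_polymorphic",
    "collapse_redundant",
    "infer_hybrid_genotypes",
    "select_pathway_snps",
]

Role = Literal["female", "male"]


@dataclass
class ParentPanel:
    """Inbred parents of one role with homozygous 0/1 calls per SNP locus.

    ``alleles[i, l]`` is 1 if parent ``i`` is homozygous for the alternate
    allele at locus ``l`` and 0 for the reference homozygote.  Missing calls
    are rejected at load time: imputation is an upstream concern.
    """

    parent_ids: list[str]
    role: Role
    alleles: np.ndarray  # (n_parents, n_loci) int8, entries in {0, 1}
    loci: pd.DataFrame  # columns: chrom, pos (1-based), id

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a parents x loci matrix")
        if self.alleles.shape[0] != len(self.parent_ids):
            raise ValueError("row count does not match parent_ids")
        if self.alleles.shape[1] != len(self.loci):
            raise ValueError("column count does not match loci table")
        bad = ~np.isin(self.alleles, (0, 1))
        if bad.any():
            raise ValueError(
                "alleles must be 0/1 homozygous codes; found other values "
                f"(first offending locus index {int(np.argwhere(bad)[0][1])})"
            )
        order = self.loci.sort_values(["chrom", "pos"], kind="stable").index
        if not np.array_equal(order.to_numpy(), np.arange(len(self.loci))):
            perm = order.to_numpy()
            self.loci = self.loci.iloc[perm].reset_index(drop=True)
            self.alleles = self.alleles[:, perm]

    @property
    def n_parents(self) -> int:
        return len(self.parent_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset_loci(self, mask: np.ndarray) -> "ParentPanel":
        mask = np.asarray(mask, dtype=bool)
        return ParentPanel(
            parent_ids=list(self.parent_ids),
            role=self.role,
            alleles=self.alleles[:, mask],
            loci=self.loci.loc[mask].reset_index(drop=True),
        )


@dataclass
class FactorialDesign:
    """Set of female x male crosses plus per-environment observation flags.

    ``observed`` has one boolean column per environment, indexed like
    ``crosses`` (columns hybrid_id, female_id, male_id).
    """

    crosses: pd.DataFrame
    observed: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"hybrid_id", "female_id", "male_id"}
        if not required.issubset(self.crosses.columns):
            raise ValueError(f"crosses must have columns {sorted(required)}")
        if len(self.observed) != len(self.crosses):
            raise ValueError("observed flags must align with crosses")

    @property
    def environments(self) -> list[str]:
        return list(self.observed.columns)

    @property
    def n_crosses(self) -> int:
        return len(self.crosses)

    def validate_parents(self, females: ParentPanel, males: ParentPanel) -> None:
        fset, mset = set(females.parent_ids), set(males.parent_ids)
        unknown_f = set(self.crosses["female_id"]) - fset
        unknown_m = set(self.crosses["male_id"]) - mset
        if unknown_f or unknown_m:
            raise KeyError(
                f"design references unknown parents: females {sorted(unknown_f)}, "
                f"males {sorted(unknown_m)}"
            )

    def is_connected(self) -> bool:
        """True iff the bipartite parent graph has a single component."""
        females = self.crosses["female_id"].to_numpy()
        males = self.crosses["male_id"].to_numpy()
        nodes = {("f", f) for f in females} | {("m", m) for m in males}
        adj: dict[tuple, list[tuple]] = {n: [] for n in nodes}
        for f, m in zip(females, males):
            adj[("f", f)].append(("m", m))
            adj[("m", m)].append(("f", f))
        if not nodes:
            return True
        seen = set()
        stack = [next(iter(nodes))]
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            stack.extend(adj[n])
        return len(seen) == len(nodes)


@dataclass
class PathwayAnnotation:
    """Gene intervals (1-based inclusive) plus a flanking window in bases."""

    genes: pd.DataFrame  # columns: chrom, start, end, id
    window: int = 1000

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        required = {"chrom", "start", "end", "id"}
        if not required.issubset(self.genes.columns):
            raise ValueError(f"genes must have columns {sorted(required)}")


# ---------------------------------------------------------------------------
# readers


def read_parents_vcf(path: str, role: Role) -> ParentPanel:
    """Load an inbred parent panel from a VCF of homozygous biallelic calls.

    Accepts diploid homozygous genotypes (0/0, 1/1, phased or not) and
    haploid calls (0, 1).  Heterozygous or missing calls raise, as do
    multi-allelic records: both indicate upstream processing this pipeline
    does not perform.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    chroms: list[str] = []
    poss: list[int] = []
    ids: list[str] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS}")
        gt = var.gt_types  # 0=hom-ref, 1=het, 2=hom-alt, 3=unknown (gts012)
        if np.any(gt == 3):
            raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}")
        if np.any(gt == 1):
            raise ValueError(f"heterozygous parent call at {var.CHROM}:{var.POS}")
        rows.append((gt == 2).astype(np.int8))
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
    if not rows:
        raise ValueError(f"no variants in {path}")
    loci = pd.DataFrame({"chrom": chroms, "pos": poss, "id": ids})
    return ParentPanel(
        parent_ids=samples,
        role=role,
        alleles=np.array(rows, dtype=np.int8).T,
        loci=loci,
    )


def read_design_csv(path: str) -> FactorialDesign:
    """Read a cross table CSV: hybrid_id, female_id, male_id, one bool column per environment."""
    df = pd.read_csv(path)
    key = ["hybrid_id", "female_id", "male_id"]
    env_cols = [c for c in df.columns if c not in key]
    observed = df[env_cols].astype(bool)
    return FactorialDesign(crosses=df[key].copy(), observed=observed)


def read_pathway_bed(path: str, window: int = 1000) -> PathwayAnnotation:
    """Read gene intervals from BED (0-based half-open) into 1-based inclusive coordinates."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "id"],
        dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int) + 1  # BED start is 0-based
    df["end"] = df["end"].astype(int)  # half-open end == 1-based inclusive end
    return PathwayAnnotation(genes=df, window=window)


# ---------------------------------------------------------------------------
# marker operations


def _check_shared_loci(females: ParentPanel, males: ParentPanel) -> None:
    a, b = females.loci, males.loci
    if len(a) != len(b) or not (
        a["chrom"].equals(b["chrom"]) and a["pos"].equals(b["pos"])
    ):
        n = min(len(a), len(b))
        for i in range(n):
            if (a["chrom"].iat[i] != b["chrom"].iat[i]) or (a["pos"].iat[i] != b["pos"].iat[i]):
                raise ValueError(
                    f"panels disagree at locus index {i}: "
                    f"{a['chrom'].iat[i]}:{a['pos'].iat[i]} vs {b['chrom'].iat[i]}:{b['pos'].iat[i]}"
                )
        raise ValueError(f"panels have different locus counts ({len(a)} vs {len(b)})")


def filter_polymorphic(
    females: ParentPanel,
    males: ParentPanel,
    mode: Literal["either", "both"] = "either",
) -> np.ndarray:
    """Mask of loci to keep, based on within-panel polymorphism.

    ``mode='either'`` (default) keeps a locus if it segregates in at least one
    parental pool, i.e. discards loci monomorphic in both pools.
    ``mode='both'`` requires segregation in both pools.
    """
    _check_shared_loci(females, males)
    poly_f = females.alleles.min(axis=0) != females.alleles.max(axis=0)
    poly_m = males.alleles.min(axis=0) != males.alleles.max(axis=0)
    if mode == "either":
        return poly_f | poly_m
    if mode == "both":
        return poly_f & poly_m
    raise ValueError(f"unknown mode {mode!r}")


def collapse_redundant(
    females: ParentPanel, males: ParentPanel
) -> tuple[np.ndarray, dict[str, str]]:
    """Group loci in complete LD across the pooled parents; keep one referent each.

    Two loci are redundant when their pooled 0/1 columns over all parents are
    identical or exact complements (|r| = 1 in the combined panel).  The
    referent of each group is the locus with the smallest (chromosome,
    position), ties broken by lexicographic id.  Returns the boolean referent
    mask and a map member_id -> referent_id (referents map to themselves).
    """
    _check_shared_loci(females, males)
    combined = np.vstack([females.alleles, males.alleles])  # (72, L) at full size
    if combined.shape[1] == 0:
        raise ValueError("empty locus set")
    # canonical form: flip columns whose first entry is 1 so a column and its
    # complement hash identically
    canon = np.where(combined[0] == 1, 1 - combined, combined)
    loci = females.loci
    groups: dict[bytes, list[int]] = {}
    for j in range(canon.shape[1]):
        groups.setdefault(canon[:, j].tobytes(), []).append(j)
    referent_mask = np.zeros(combined.shape[1], dtype=bool)
    group_map: dict[str, str] = {}
    chrom = loci["chrom"].to_numpy()
    pos = loci["pos"].to_numpy()
    ids = loci["id"].to_numpy()
    for members in groups.values():
        ref = min(members, key=lambda j: (str(chrom[j]), int(pos[j]), str(ids[j])))
        referent_mask[ref] = True
        for j in members:
            group_map[str(ids[j])] = str(ids[ref])
    return referent_mask, group_map


def infer_hybrid_genotypes(
    design: FactorialDesign, females: ParentPanel, males: ParentPanel
) -> dict[str, np.ndarray]:
    """Deduce each hybrid's genotype from its homozygous parents.

    Returns hybrid_id -> (n_loci, 2) array of (female allele, male allele);
    the hybrid is heterozygous exactly where the parents differ.
    """
    _check_shared_loci(females, males)
    design.validate_parents(females, males)
    fidx = {p: i for i, p in enumerate(females.parent_ids)}
    midx = {p: i for i, p in enumerate(males.parent_ids)}
    out: dict[str, np.ndarray] = {}
    for hid, f, m in design.crosses[["hybrid_id", "female_id", "male_id"]].itertuples(index=False):
        out[str(hid)] = np.stack(
            [females.alleles[fidx[f]], males.alleles[midx[m]]], axis=1
        )
    return out


def select_pathway_snps(loci: pd.DataFrame, annotation: PathwayAnnotation) -> np.ndarray:
    """Mask of loci within ``window`` bases of any annotated gene.

    A locus is kept iff its position lies in [start - window, end + window]
    (1-based inclusive) for at least one gene on the same chromosome.
    """
    mask = np.zeros(len(loci), dtype=bool)
    chrom = loci["chrom"].to_numpy()
    pos = loci["pos"].to_numpy()
    w = annotation.window
    for g_chrom, g_start, g_end in annotation.genes[["chrom", "start", "end"]].itertuples(index=False):
        mask |= (chrom == g_chrom) & (pos >= g_start - w) & (pos <= g_end + w)
    if not mask.any():
        warnings.warn("pathway selection matched no SNPs", stacklevel=2)
    return mask
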