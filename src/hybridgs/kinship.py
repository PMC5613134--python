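"""Marker-derived kinship kernels for hybrid prediction.

Every genomic model in the pipeline is a Gaussian mixed model whose random
effects are structured by a kernel built here:

* additive parental kernels K_f = X_f X_f' and K_m = Z_m Z_m', where X_f and
  Z_m hold the centered 0/1 alleles each inbred parent transmits to its
  hybrids;
* the female-by-male interaction (SCA) kernel over hybrid combinations,
  whose entries factorize as K_fm[(f,m),(f',m')] = K_f[f,f'] * K_m[m,m'] —
  the Gram matrix of the row-wise Khatri-Rao product of X_f and Z_m;
* additive-by-additive epistasis kernels, the element-wise squares
  K_f (.) K_f and K_m (.) K_m (Schur products, hence still PSD);
* restriction of any of the above to a SNP subset (e.g. a metabolic
  pathway);
* VanRaden's genomic relationship matrix, used only to order parents for
  design heat maps / dendrograms.

Kernels default to a 1/L scale so variance components are comparable across
SNP subsets of different sizes; scale 1 recovers the plain cross-products.
Predictions are invariant to the scale choice (the mixed model absorbs it
into the variance component).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .genotypes import ParentPanel

__all__ = [
    "TransmittedAlleleMatrix",
    "KinshipMatrix",
    "center_transmitted",
    "additive_kinship",
    "interaction_kinship",
    "epistasis_kinship",
    "vanraden_kinship",
    "build_model_kernels",
]


@dataclass
class TransmittedAlleleMatrix:
    """Centered transmitted-allele matrix for one parental role.

    ``values[i, l]`` = allele transmitted by parent i at locus l minus the
    per-locus mean over this role's own parents, so columns sum to zero.
    """

    role: str
    entities: list[str]
    values: np.ndarray  # (n_parents, n_loci) float
    centering: np.ndarray  # per-locus constants subtracted

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]


@dataclass
class KinshipMatrix:
    """Symmetric PSD similarity over an ordered entity set.

    ``entities`` are parent ids for parental kernels or (female, male)
    tuples for the interaction kernel; ``provenance`` records how the kernel
    was built (construction, locus-set id, scaling constant).
    """

    entities: list
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entities)
        if self.values.shape != (n, n):
            raise ValueError("kinship must be square over its entities")

    def max_asymmetry(self) -> float:
        return float(np.abs(self.values - self.values.T).max(initial=0.0))

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def index_of(self, entity) -> int:
        try:
            return self.entities.index(entity)
        except ValueError:
            raise KeyError(f"entity {entity!r} not in kinship") from None


def center_transmitted(panel: ParentPanel, mask: np.ndarray | None = None) -> TransmittedAlleleMatrix:
    """Center the 0/1 transmitted alleles by the per-locus mean of the panel.

    Centering within the role's own pool (females by female frequencies,
    males by male frequencies) makes the resulting Gram matrix measure
    within-role relatedness.  A monomorphic locus centers to an all-zero
    column.
    """
    if mask is None:
        mask = np.ones(panel.n_loci, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("locus mask selects no loci")
    sub = panel.alleles[:, mask].astype(float)
    means = sub.mean(axis=0)
    return TransmittedAlleleMatrix(
        role=panel.role,
        entities=list(panel.parent_ids),
        values=sub - means,
        centering=means,
    )


def _resolve_scale(scale: float | Literal["1/L"] | None, n_loci: int) -> float:
    if scale is None or scale == "1/L":
        return 1.0 / n_loci
    return float(scale)


def additive_kinship(
    X: TransmittedAlleleMatrix, scale: float | Literal["1/L"] | None = "1/L"
) -> KinshipMatrix:
    """Additive kernel K = scale * X X' over the role's parents."""
    if X.values.size == 0:
        raise ValueError("empty transmitted-allele matrix")
    s = _resolve_scale(scale, X.n_loci)
    K = s * (X.values @ X.values.T)
    K = (K + K.T) / 2.0
    return KinshipMatrix(
        entities=list(X.entities),
        values=K,
        provenance={"construction": "additive", "role": X.role, "scale": s, "n_loci": X.n_loci},
    )


def interaction_kinship(
    Xf: TransmittedAlleleMatrix,
    Zm: TransmittedAlleleMatrix,
    crosses: Sequence[tuple[str, str]],
    scale: float | Literal["1/L"] | None = "1/L",
) -> KinshipMatrix:
    """Female-by-male interaction (SCA) kernel over hybrid combinations.

    Row (f, m) of the underlying design matrix is the outer product of the
    female's and the male's centered transmitted alleles (row-wise
    Khatri-Rao product, L^2 columns), so the Gram matrix factorizes exactly:

        K_fm[(f,m),(f',m')] = K_f[f,f'] * K_m[m,m']

    and is computed entrywise from the parental kernels rather than by
    materializing the L^2-column matrix.  The entity set is the supplied
    crosses (observed or not), not the full factorial grid.  The per-locus
    scale applies to each parental factor, matching the additive convention.
    """
    if Xf.n_loci != Zm.n_loci:
        raise ValueError(
            f"female and male matrices disagree on locus count ({Xf.n_loci} vs {Zm.n_loci})"
        )
    crosses = [tuple(c) for c in crosses]
    Kf = additive_kinship(Xf, scale=scale)
    Km = additive_kinship(Zm, scale=scale)
    fi = np.array([Kf.index_of(f) for f, _ in crosses])
    mi = np.array([Km.index_of(m) for _, m in crosses])
    K = Kf.values[np.ix_(fi, fi)] * Km.values[np.ix_(mi, mi)]
    return KinshipMatrix(
        entities=crosses,
        values=K,
        provenance={
            "construction": "interaction",
            "scale": Kf.provenance["scale"] * Km.provenance["scale"],
            "n_loci": Xf.n_loci,
        },
    )


def epistasis_kinship(K: KinshipMatrix) -> KinshipMatrix:
    """Additive-by-additive epistasis kernel: the element-wise square of K.

    PSD by the Schur product theorem.
    """
    prov = dict(K.provenance)
    prov["construction"] = f"epistasis({prov.get('construction', '?')})"
    return KinshipMatrix(entities=list(K.entities), values=K.values * K.values, provenance=prov)


def vanraden_kinship(panels: ParentPanel | Sequence[ParentPanel]) -> KinshipMatrix:
    """VanRaden method-1 genomic relationship matrix over one or more panels.

    G = M M' / sum_l p_l (1 - p_l), with M the 0/1 allele matrix centered by
    the per-locus mean p_l estimated from the supplied parents.  This is the
    inbred (haploid-coded) analogue of the diploid formula
    Z Z' / (2 sum 2 p (1-p)) with Z = dosage - 2p.  Used for ordering
    dendrograms of the factorial design, not for prediction.
    """
    if isinstance(panels, ParentPanel):
        panels = [panels]
    allele_blocks = [p.alleles for p in panels]
    ids = [pid for p in panels for pid in p.parent_ids]
    A = np.vstack(allele_blocks).astype(float)
    p = A.mean(axis=0)
    het = p * (1 - p)
    denom = float(het.sum())
    if denom == 0.0:
        raise ValueError("all loci monomorphic in the supplied parents")
    M = A - p
    G = (M @ M.T) / denom
    return KinshipMatrix(
        entities=ids,
        values=G,
        provenance={"construction": "vanraden", "denominator": denom, "n_loci": A.shape[1]},
    )


def build_model_kernels(
    females: ParentPanel,
    males: ParentPanel,
    crosses: Sequence[tuple[str, str]] | None = None,
    pathway_mask: np.ndarray | None = None,
    scale: float | Literal["1/L"] | None = "1/L",
) -> dict[str, KinshipMatrix]:
    """Every kernel the model families need, built once from the two panels.

    Returns Kf/Km always, Kfm when ``crosses`` is given (the full design,
    observed crosses included), and Kf_oil/Km_oil/Kf_rest/Km_rest when a
    pathway locus mask is given.  Epistasis squares are derived on demand by
    model assembly.
    """
    Xf = center_transmitted(females)
    Zm = center_transmitted(males)
    kernels = {"Kf": additive_kinship(Xf, scale), "Km": additive_kinship(Zm, scale)}
    if crosses is not None:
        kernels["Kfm"] = interaction_kinship(Xf, Zm, crosses, scale)
    if pathway_mask is not None:
        pathway_mask = np.asarray(pathway_mask, dtype=bool)
        for key_suffix, mask in (("oil", pathway_mask), ("rest", ~pathway_mask)):
            if mask.sum() == 0:
                continue
            kernels[f"Kf_{key_suffix}"] = additive_kinship(center_transmitted(females, mask), scale)
            kernels[f"Km_{key_suffix}"] = additive_kinship(center_transmitted(males, mask), scale)
    return kernels
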