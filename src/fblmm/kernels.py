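"""Variance-component ingredients: variant weights, region kernels,
kinship and shared-environment kernels, and their eigen-designs.

Every random effect in the model is expressed through a positive
semi-definite similarity kernel K.  For fitting, each kernel is
reparameterised through its eigendecomposition K = Q diag(L) Q^T as a
design matrix Z = Q diag(L)^(1/2) with Z Z^T = K and Z^T Z = diag(L);
the diagonal Gram matrix is what makes the coordinate-ascent updates
cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import linalg
from scipy.stats import beta as beta_dist

from .io import GenotypeMatrix, Pedigree, RegionMap

__all__ = [
    "WeightScheme",
    "RegionKernel",
    "FamilialKernels",
    "compute_maf",
    "variant_weights",
    "mean_impute",
    "build_region_kernel",
    "build_region_kernels",
    "kernel_to_design",
    "pedigree_kinship",
    "env_kernel",
    "build_familial_kernels",
]

DEFAULT_REL_TOL = 1e-8


@dataclass(frozen=True)
class WeightScheme:
    """Per-variant weighting of a region kernel.

    - ``uniform``: w_j = 1 (infinitesimal model over common variants).
    - ``wss``: w_j = 1 / sqrt(MAF_j (1 - MAF_j)), the weighted-sum-statistic
      up-weighting of rare variants.
    - ``beta``: w_j = Beta(shape1, shape2) density at MAF_j, squared when
      ``squared`` is set (default), following the usual dbeta(MAF, 1, 25)^2
      rare-variant weighting.
    """

    kind: str = "uniform"
    shape1: float = 1.0
    shape2: float = 25.0
    squared: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "wss", "beta"):
            raise ValueError(f"unknown weight scheme {self.kind!r}")


def compute_maf(
    genotypes: GenotypeMatrix,
    reference: str = "all",
    pedigree: Optional[Pedigree] = None,
    clamp_for_weights: bool = False,
) -> np.ndarray:
    """Per-variant minor allele frequency over a reference sample.

    With ``reference="founders"`` only pedigree founders count, which
    avoids the allele-frequency distortion induced by large families.
    With ``clamp_for_weights`` the result is floored at 1/(2 n_ref) so a
    downstream weight function never sees maf = 0.
    """
    if reference == "all":
        dos = genotypes.dosages
    elif reference == "founders":
        if pedigree is None:
            raise ValueError("founders reference requires a pedigree")
        keep = set(pedigree.founders)
        rows = [i for i, s in enumerate(genotypes.samples) if s in keep]
        if not rows:
            raise ValueError("no pedigree founders present in the genotype matrix")
        dos = genotypes.dosages[rows]
    else:
        raise ValueError(f"unknown maf reference {reference!r}")
    with np.errstate(invalid="ignore"):
        maf = np.nanmean(dos, axis=0) / 2.0
    maf = np.where(np.isnan(maf), 0.0, maf)
    maf = np.minimum(maf, 1.0 - maf)
    if clamp_for_weights:
        maf = np.maximum(maf, 1.0 / (2.0 * dos.shape[0]))
    return maf


def variant_weights(maf: np.ndarray, scheme: WeightScheme) -> np.ndarray:
    """Weight vector w for a region kernel K = G diag(w) G^T / p."""
    maf = np.asarray(maf, dtype=float)
    if scheme.kind == "uniform":
        return np.ones_like(maf)
    if np.any(maf <= 0.0):
        raise ValueError(
            f"{scheme.kind} weights undefined at maf = 0; exclude monomorphic "
            "variants before weighting"
        )
    if np.any(maf > 0.5):
        raise ValueError("maf above 0.5: dosages are not minor-allele oriented")
    if scheme.kind == "wss":
        return 1.0 / np.sqrt(maf * (1.0 - maf))
    w = beta_dist.pdf(maf, scheme.shape1, scheme.shape2)
    return w**2 if scheme.squared else w


def mean_impute(dosages: np.ndarray, means: Optional[np.ndarray] = None) -> np.ndarray:
    """Replace missing dosages by the per-variant mean (or given means)."""
    out = np.array(dosages, dtype=float, copy=True)
    if means is None:
        with np.errstate(invalid="ignore"):
            means = np.nanmean(out, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
    mask = np.isnan(out)
    if mask.any():
        out[mask] = np.broadcast_to(means, out.shape)[mask]
    return out


@dataclass
class RegionKernel:
    """One region's kernel K = A diag(w) A^T / p plus its eigen-design."""

    name: str
    K: np.ndarray
    Q: np.ndarray
    eigenvalues: np.ndarray
    weights: np.ndarray
    p_m: int
    variant_ids: list[str]
    column_means: np.ndarray  # training means used for centering/imputation
    centered: bool
    A: np.ndarray  # transformed training dosages; K = A diag(w) A^T / p_m

    @property
    def Z(self) -> np.ndarray:
        return self.Q * np.sqrt(self.eigenvalues)

    @property
    def rank(self) -> int:
        return len(self.eigenvalues)


def kernel_to_design(
    K: np.ndarray, rel_tol: float = DEFAULT_REL_TOL
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Truncated eigendecomposition (Q, L, Z) of a p.s.d. kernel.

    Eigenpairs with eigenvalue > rel_tol * max eigenvalue are retained, so Z
    has full column rank; Z Z^T reconstructs K up to the discarded mass.
    A zero kernel yields an empty (k = 0) design.
    """
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kernel is not symmetric")
    vals, vecs = linalg.eigh((K + K.T) / 2.0)
    lam_max = float(vals[-1]) if vals.size else 0.0
    if lam_max <= 0.0:
        n = K.shape[0]
        empty = np.empty((n, 0))
        return empty, np.empty(0), empty
    keep = vals > rel_tol * lam_max
    vals, vecs = vals[keep], vecs[:, keep]
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    return vecs, vals, vecs * np.sqrt(vals)


def build_region_kernel(
    genotypes: GenotypeMatrix,
    name: str,
    variant_ids: Sequence[str],
    scheme: WeightScheme = WeightScheme(),
    center: bool = True,
    maf: Optional[np.ndarray] = None,
    rel_tol: float = DEFAULT_REL_TOL,
) -> RegionKernel:
    """Region similarity kernel K_m = A diag(w) A^T / p_m.

    A is the region dosage matrix after mean imputation and (by default)
    per-variant mean centering.  Monomorphic variants are excluded; a
    region left with none is rejected as unusable.
    """
    vidx = genotypes.variant_indexer()
    cols = [vidx[v] for v in variant_ids]
    dos = mean_impute(genotypes.dosages[:, cols])
    if maf is None:
        maf_region = np.minimum(dos.mean(axis=0) / 2.0, 1.0 - dos.mean(axis=0) / 2.0)
    else:
        maf_region = np.asarray(maf, dtype=float)[cols]
    poly = maf_region > 0.0
    if not poly.any():
        raise ValueError(f"region {name!r}: all variants monomorphic, kernel unusable")
    dos = dos[:, poly]
    kept_ids = [v for v, keep in zip(variant_ids, poly) if keep]
    maf_region = maf_region[poly]
    p_m = dos.shape[1]
    means = dos.mean(axis=0)
    A = dos - means if center else dos
    w = variant_weights(maf_region, scheme)
    K = (A * w) @ A.T / p_m
    Q, lam, _ = kernel_to_design(K, rel_tol)
    return RegionKernel(
        name=name,
        K=K,
        Q=Q,
        eigenvalues=lam,
        weights=w,
        p_m=p_m,
        variant_ids=kept_ids,
        column_means=means,
        centered=center,
        A=A,
    )


def build_region_kernels(
    genotypes: GenotypeMatrix,
    region_map: RegionMap,
    scheme: WeightScheme = WeightScheme(),
    center: bool = True,
    maf: Optional[np.ndarray] = None,
    rel_tol: float = DEFAULT_REL_TOL,
) -> list[RegionKernel]:
    kernels = []
    for name, members in region_map.regions.items():
        kernels.append(
            build_region_kernel(
                genotypes, name, members, scheme=scheme, center=center,
                maf=maf, rel_tol=rel_tol,
            )
        )
    return kernels


# ---------------------------------------------------------------------------
# pedigree-derived kernels

def pedigree_kinship(ped: Pedigree, scale: str = "relationship") -> np.ndarray:
    """Expected-relatedness matrix from pedigree structure alone.

    Computed by the standard kinship recursion over a topological order:
    phi(i,i) = (1 + phi(father_i, mother_i)) / 2 and
    phi(i,j) = (phi(father_i, j) + phi(mother_i, j)) / 2 for j already
    processed, with founders mutually unrelated and non-inbred.  Members of
    an MZ group are then made genetically identical (off-diagonal set to the
    diagonal value).  Returned on the additive-relationship scale 2*phi
    (diagonal 1 for non-inbred individuals) unless ``scale="phi"``.
    """
    if scale not in ("relationship", "phi"):
        raise ValueError(f"unknown kinship scale {scale!r}")
    ids = ped.individuals
    idx = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))
    # records are topologically sorted, so every index before i is a
    # non-descendant of i and the recursion closes over the prefix
    for i, r in enumerate(ped.records):
        if r.is_founder:
            phi[i, i] = 0.5
        else:
            f, m = idx[r.father], idx[r.mother]
            phi[i, i] = 0.5 * (1.0 + phi[f, m])
            phi[i, :i] = 0.5 * (phi[f, :i] + phi[m, :i])
            phi[:i, i] = phi[i, :i]
    # MZ groups: genetically identical members
    groups: dict[str, list[int]] = {}
    for r in ped.records:
        if r.mz_group is not None:
            groups.setdefault(r.mz_group, []).append(idx[r.individual])
    for members in groups.values():
        for a in members:
            for b in members:
                if a != b:
                    phi[a, b] = phi[a, a]
    return 2.0 * phi if scale == "relationship" else phi


def env_kernel(ped: Pedigree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared-environment kernel: block of ones per family.

    Returns (K_ef, Z_ef, eigenvalues).  Each family contributes exactly one
    nonzero eigenvalue equal to the family size; the corresponding Z column
    is the family-membership indicator (eigenvector / sqrt(size) scaled by
    sqrt(size)), so Z Z^T = K exactly with one column per family.
    """
    ids = ped.individuals
    idx = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    fams = ped.families
    K = np.zeros((n, n))
    Z = np.zeros((n, len(fams)))
    lam = np.zeros(len(fams))
    for c, (fam, members) in enumerate(fams.items()):
        rows = [idx[m] for m in members]
        K[np.ix_(rows, rows)] = 1.0
        Z[rows, c] = 1.0
        lam[c] = len(rows)
    return K, Z, lam


@dataclass
class FamilialKernels:
    """The two family-design surrogates and their eigen-designs.

    K_gf (expected genetic relatedness) stands in for unmeasured genetic
    factors; K_ef (all-ones family blocks) for unmeasured shared
    environment.  Both are block diagonal by family, so the
    eigendecomposition is assembled family by family rather than on the
    full n x n matrix.
    """

    sample_ids: list[str]
    K_gf: np.ndarray
    Q_gf: np.ndarray
    lam_gf: np.ndarray
    K_ef: np.ndarray
    Z_ef: np.ndarray
    lam_ef: np.ndarray
    kinship_scale: str = "relationship"

    @property
    def Z_gf(self) -> np.ndarray:
        return self.Q_gf * np.sqrt(self.lam_gf)


def build_familial_kernels(
    ped: Pedigree,
    sample_ids: Optional[Sequence[str]] = None,
    kinship_scale: str = "relationship",
    rel_tol: float = DEFAULT_REL_TOL,
) -> FamilialKernels:
    """Build K_gf and K_ef restricted (and ordered) to ``sample_ids``.

    Kinship is computed on the full pedigree (so ancestors excluded from
    the sample still induce relatedness) and then subset.  The kinship
    eigendecomposition is done per family block.
    """
    K_full = pedigree_kinship(ped, scale=kinship_scale)
    all_ids = ped.individuals
    if sample_ids is None:
        sample_ids = all_ids
    sample_ids = list(sample_ids)
    pos = {s: i for i, s in enumerate(all_ids)}
    rows = [pos[s] for s in sample_ids]
    K_gf = K_full[np.ix_(rows, rows)]

    fam_of = {r.individual: r.family for r in ped.records}
    n = len(sample_ids)
    sidx = {s: i for i, s in enumerate(sample_ids)}
    fams: dict[str, list[int]] = {}
    for s in sample_ids:
        fams.setdefault(fam_of[s], []).append(sidx[s])

    # per-family eigendecomposition of the block-diagonal kinship
    q_cols: list[np.ndarray] = []
    lams: list[float] = []
    for members in fams.values():
        block = K_gf[np.ix_(members, members)]
        vals, vecs = linalg.eigh(block)
        lam_max = float(vals[-1]) if vals.size else 0.0
        for v, vec in zip(vals, vecs.T):
            if lam_max > 0 and v > rel_tol * lam_max:
                col = np.zeros(n)
                col[members] = vec
                q_cols.append(col)
                lams.append(float(v))
    if lams:
        order = np.argsort(lams)[::-1]
        Q_gf = np.column_stack([q_cols[i] for i in order])
        lam_gf = np.array([lams[i] for i in order])
    else:
        Q_gf = np.empty((n, 0))
        lam_gf = np.empty(0)

    K_ef = np.zeros((n, n))
    Z_ef = np.zeros((n, len(fams)))
    lam_ef = np.zeros(len(fams))
    for c, members in enumerate(fams.values()):
        K_ef[np.ix_(members, members)] = 1.0
        Z_ef[members, c] = 1.0
        lam_ef[c] = len(members)
    return FamilialKernels(
        sample_ids=sample_ids,
        K_gf=K_gf,
        Q_gf=Q_gf,
        lam_gf=lam_gf,
        K_ef=K_ef,
        Z_ef=Z_ef,
        lam_ef=lam_ef,
        kinship_scale=kinship_scale,
    )
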