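"""Out-of-sample prediction.

A fitted model predicts a new individual's outcome as the sum of the
training phenotype mean, the spike-and-slab fixed effects, the
Gaussian-process conditional mean of every region effect, and — only when
the individual belongs to a family represented in the training set — the
conditional means of the kinship and shared-environment effects.  For
subjects unrelated to the training families the two familial terms are
exactly zero, so prediction degrades gracefully to genotype-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, Pedigree, PedigreeRecord, ValidationError
from .kernels import mean_impute, pedigree_kinship
from .vb import FitResult

__all__ = [
    "PredictionRequest",
    "make_request",
    "cross_region_effect",
    "familial_effect",
    "predict",
]


@dataclass
class PredictionRequest:
    """Inputs for predicting a batch of new individuals.

    X and the region blocks are aligned to the training variant order;
    variants unseen in training are dropped (recorded in ``report``) and
    training variants missing from the request are imputed at the training
    mean, which contributes zero after centring.
    """

    ids: list[str]
    X: np.ndarray  # n_new x p_train, already training-mean-imputed (raw dosage scale)
    region_blocks: dict[str, np.ndarray]  # raw dosages aligned to kernel variant order
    pedigree: Optional[Pedigree] = None  # pedigree covering training + new subjects
    extra_records: Optional[list[PedigreeRecord]] = None
    report: dict = field(default_factory=dict)


def make_request(
    fit: FitResult,
    genotypes: GenotypeMatrix,
    pedigree: Optional[Pedigree] = None,
    extra_records: Optional[list[PedigreeRecord]] = None,
) -> PredictionRequest:
    """Align a new-sample genotype matrix to the training variant sets."""
    vidx = genotypes.variant_indexer()
    n_new = genotypes.n_samples
    report: dict = {}
    known_train = set(fit.x_variant_ids) | {
        v for rk in fit.region_kernels for v in rk.variant_ids
    }
    unseen = [v for v in genotypes.variants.index if v not in known_train]
    if unseen:
        report["dropped_unseen_variants"] = unseen

    def block(variant_ids: Sequence[str], train_means: np.ndarray) -> np.ndarray:
        out = np.empty((n_new, len(variant_ids)))
        missing = []
        for c, v in enumerate(variant_ids):
            if v in vidx:
                out[:, c] = genotypes.dosages[:, vidx[v]]
            else:
                out[:, c] = train_means[c]
                missing.append(v)
        if missing:
            report.setdefault("imputed_training_variants", []).extend(missing)
        return mean_impute(out, means=train_means)

    X = block(fit.x_variant_ids, fit.x_means) if fit.x_variant_ids else np.zeros((n_new, 0))
    blocks = {
        rk.name: block(rk.variant_ids, rk.column_means) for rk in fit.region_kernels
    }
    return PredictionRequest(
        ids=list(genotypes.samples),
        X=X,
        region_blocks=blocks,
        pedigree=pedigree,
        extra_records=extra_records,
        report=report,
    )


def cross_region_effect(
    G_new_region: np.ndarray, fit: FitResult, region: str
) -> np.ndarray:
    """Conditional mean of region effect g_m for new samples.

    g*_m = phi_m K*_m Q_m lam_m^{-1/2} M_m, with the train-test
    cross-kernel K*_m = A_new diag(w) A_train^T / p_m computed under the
    training transforms (mean imputation / centring at training means).
    """
    names = [rk.name for rk in fit.region_kernels]
    if region not in names:
        raise KeyError(f"region {region!r} not in the fitted model")
    m = names.index(region)
    rk = fit.region_kernels[m]
    A_new = np.asarray(G_new_region, dtype=float)
    if A_new.ndim == 1:
        A_new = A_new[None, :]
    if A_new.shape[1] != len(rk.variant_ids):
        raise ValidationError(
            f"region {region!r}: expected {len(rk.variant_ids)} variant columns, "
            f"got {A_new.shape[1]}"
        )
    A_new = mean_impute(A_new, means=rk.column_means)
    if rk.centered:
        A_new = A_new - rk.column_means
    K_star = (A_new * rk.weights) @ rk.A.T / rk.p_m
    phi_m = float(fit.state.phi[m])
    if rk.rank == 0:
        return np.zeros(A_new.shape[0])
    proj = rk.Q / np.sqrt(rk.eigenvalues)  # Q lam^{-1/2}
    return phi_m * (K_star @ (proj @ fit.state.regions[m].mean))


def familial_effect(
    fit: FitResult,
    pedigree: Optional[Pedigree],
    new_ids: Sequence[str],
    extra_records: Optional[list[PedigreeRecord]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional means of the kinship and shared-environment effects.

    For a new subject in a training family, the kinship term is the
    expected-relatedness row against the training subjects (computed on
    the merged pedigree) projected through the fitted factor, and the
    environment term is the family's common fitted environmental effect.
    Both are exactly zero for subjects unrelated to every training family.
    """
    n_new = len(new_ids)
    g_star = np.zeros(n_new)
    e_star = np.zeros(n_new)
    if fit.familial is None or pedigree is None:
        return g_star, e_star
    fam = fit.familial
    ped = pedigree.merged_with(extra_records) if extra_records else pedigree
    in_ped = set(ped.individuals)
    linked = [i for i, s in enumerate(new_ids) if s in in_ped]
    if not linked:
        return g_star, e_star

    K_full = pedigree_kinship(ped, scale=fam.kinship_scale)
    pos = {s: i for i, s in enumerate(ped.individuals)}
    train_rows = [pos[s] for s in fam.sample_ids]
    if fam.lam_gf.size:
        proj_g = fam.Q_gf / np.sqrt(fam.lam_gf)
        coeff = proj_g @ fit.state.gf.mean  # per-training-sample weights
        for i in linked:
            k_row = K_full[pos[new_ids[i]], train_rows]
            g_star[i] = float(k_row @ coeff)

    fam_of = {r.individual: r.family for r in ped.records}
    train_families = [fam_of.get(s) for s in fam.sample_ids]
    family_order: list[str] = []
    for f in train_families:
        if f not in family_order:
            family_order.append(f)
    for i in linked:
        f = fam_of[new_ids[i]]
        if f in family_order:
            e_star[i] = float(fit.state.ef.mean[family_order.index(f)])
    return g_star, e_star


def predict(
    fit: FitResult, request: PredictionRequest, components: bool = False
) -> pd.DataFrame:
    """Predicted outcomes (and optional per-component breakdown).

    Y* = training mean + X*(diag(psi) M_beta) + sum_m g*_m + g_f* + e_f*.
    """
    n_new = len(request.ids)
    out = pd.DataFrame(index=pd.Index(request.ids, name="individual"))
    if fit.x_variant_ids:
        if request.X.shape != (n_new, len(fit.x_variant_ids)):
            raise ValidationError(
                f"fixed-effect block has shape {request.X.shape}, expected "
                f"({n_new}, {len(fit.x_variant_ids)})"
            )
        Xc = request.X - fit.x_means
        fixed = Xc @ (fit.state.psi * fit.state.M_beta)
    else:
        fixed = np.zeros(n_new)
    out["fixed"] = fixed
    region_total = np.zeros(n_new)
    for rk in fit.region_kernels:
        if rk.name not in request.region_blocks:
            raise ValidationError(f"request lacks genotypes for region {rk.name!r}")
        g = cross_region_effect(request.region_blocks[rk.name], fit, rk.name)
        region_total += g
        if components:
            out[f"region:{rk.name}"] = g
    g_star, e_star = familial_effect(
        fit, request.pedigree, request.ids, request.extra_records
    )
    out["genetic_familial"] = g_star
    out["environmental"] = e_star
    out.insert(
        0, "prediction", fit.y_mean + fixed + region_total + g_star + e_star
    )
    if not components:
        out = out[["prediction", "fixed", "genetic_familial", "environmental"]]
    return out


def fitted_values(fit: FitResult, X: Optional[np.ndarray] = None) -> np.ndarray:
    """In-sample fitted values (training mean plus all posterior-mean
    component contributions), for self-consistency checks and residuals.

    The raw training X must be passed back in when the model has fixed
    effects, since the fit archive keeps only its column means.
    """
    n = len(fit.sample_ids)
    total = np.zeros(n)
    if fit.x_variant_ids:
        if X is None:
            raise ValueError("model has fixed effects: pass the training X")
        total += (np.asarray(X, dtype=float) - fit.x_means) @ (
            fit.state.psi * fit.state.M_beta
        )
    for m, rk in enumerate(fit.region_kernels):
        total += float(fit.state.phi[m]) * (rk.Z @ fit.state.regions[m].mean)
    if fit.familial is not None:
        total += fit.familial.Z_gf @ fit.state.gf.mean
        total += fit.familial.Z_ef @ fit.state.ef.mean
    return fit.y_mean + total
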