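"""Benchmark loop: train/test splitting, marginal pre-screening,
prediction metrics, a genotype-only ridge (gBLUP-style) baseline, and
multi-replicate experiment orchestration."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import GenotypeMatrix, Pedigree
from .kernels import (
    WeightScheme,
    build_familial_kernels,
    build_region_kernels,
    mean_impute,
)
from .prediction import make_request, predict
from .simulator import SimulatedStudy, run_scenario
from .vb import FitResult, Hyperparameters, fit

__all__ = [
    "SplitPlan",
    "MetricReport",
    "train_test_split",
    "marginal_prescreen",
    "pearson_rmse",
    "fit_study",
    "predict_study",
    "ridge_baseline",
    "replicate_experiment",
]


@dataclass(frozen=True)
class SplitPlan:
    fraction: float
    unit: str  # "individual" | "family"
    seed: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


def train_test_split(
    samples: Sequence[str],
    ped: Optional[Pedigree] = None,
    fraction: float = 0.2,
    unit: str = "individual",
    seed: int = 0,
) -> SplitPlan:
    """Uniformly random train/test split at the individual or whole-family
    level.  Individual unit puts round(fraction * n) samples in test;
    family unit never splits a family."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"test fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    samples = list(samples)
    if unit == "individual":
        n_test = int(round(fraction * len(samples)))
        test_idx = set(rng.choice(len(samples), size=n_test, replace=False).tolist())
        test = [s for i, s in enumerate(samples) if i in test_idx]
        train = [s for i, s in enumerate(samples) if i not in test_idx]
    elif unit == "family":
        if ped is None:
            raise ValueError("family-unit split requires a pedigree")
        fam_of = {r.individual: r.family for r in ped.records}
        fams = []
        for s in samples:
            f = fam_of[s]
            if f not in fams:
                fams.append(f)
        n_test_f = int(round(fraction * len(fams)))
        test_fams = set(
            np.asarray(fams, dtype=object)[
                rng.choice(len(fams), size=n_test_f, replace=False)
            ].tolist()
        )
        test = [s for s in samples if fam_of[s] in test_fams]
        train = [s for s in samples if fam_of[s] not in test_fams]
    else:
        raise ValueError(f"unknown split unit {unit!r}")
    return SplitPlan(
        fraction=fraction, unit=unit, seed=seed,
        train_ids=tuple(train), test_ids=tuple(test),
    )


def _null_variance_components(
    y: np.ndarray, eigvals: np.ndarray, Uy: np.ndarray
) -> tuple[float, float]:
    """ML variance components for y ~ N(0, sg2 K + se2 I) via the rotated
    model, optimizing the variance ratio on a log grid then locally."""
    n = y.shape[0]

    def neg_loglik(log_delta: float) -> float:
        # V = sg2 (K + delta I); profile out sg2
        delta = np.exp(log_delta)
        d = eigvals + delta
        sg2 = float(np.sum(Uy**2 / d)) / n
        sg2 = max(sg2, 1e-12)
        return 0.5 * (n * np.log(sg2) + float(np.sum(np.log(d))) + n)

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(-10.0, 10.0), method="bounded"
    )
    delta = float(np.exp(res.x))
    d = eigvals + delta
    sg2 = max(float(np.sum(Uy**2 / d)) / n, 1e-12)
    return sg2, sg2 * delta


def marginal_prescreen(
    G: GenotypeMatrix,
    y: np.ndarray,
    K_gf: Optional[np.ndarray] = None,
    threshold: float = 0.1,
) -> tuple[list[str], np.ndarray]:
    """Single-marker screen with family correlation handled by GLS.

    The null covariance V = sg2 K_gf + se2 I is estimated once by maximum
    likelihood, the data are whitened by V^{-1/2}, and each variant gets a
    two-sided p-value from a simple linear model (intercept + variant) on
    the whitened scale.  Variants with p <= threshold are retained.  With
    K_gf = I this reduces exactly to per-variant OLS.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    X = mean_impute(G.dosages)
    if K_gf is None:
        K_gf = np.eye(n)
    K = np.asarray(K_gf, dtype=float)
    try:
        eigvals, U = np.linalg.eigh(K)
    except np.linalg.LinAlgError:
        warnings.warn("singular kinship; adding 1e-8 jitter", RuntimeWarning)
        eigvals, U = np.linalg.eigh(K + 1e-8 * np.eye(n))
    eigvals = np.maximum(eigvals, 0.0)
    yc = y - y.mean()
    sg2, se2 = _null_variance_components(yc, eigvals, U.T @ yc)
    d = sg2 * eigvals + se2
    if np.min(d) <= 0:
        warnings.warn("singular null covariance; adding 1e-8 jitter", RuntimeWarning)
        d = d + 1e-8
    w = 1.0 / np.sqrt(d)
    yt = w * (U.T @ y)
    Xt = w[:, None] * (U.T @ X)
    ones_t = w * (U.T @ np.ones(n))

    # per-variant simple regression of yt on [ones_t, xt]
    o2 = float(ones_t @ ones_t)
    proj_y = yt - ones_t * (float(ones_t @ yt) / o2)
    proj_X = Xt - np.outer(ones_t, (ones_t @ Xt) / o2)
    sxx = np.sum(proj_X**2, axis=0)
    valid = sxx > 1e-12
    slope = np.zeros(X.shape[1])
    slope[valid] = (proj_X[:, valid].T @ proj_y) / sxx[valid]
    rss = np.sum((proj_y[:, None] - proj_X * slope) ** 2, axis=0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof / sxx)
        tstat = np.where(valid & (se > 0), slope / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pvals = np.where(valid, pvals, 1.0)
    retained = [v for v, p in zip(G.variants.index, pvals) if p <= threshold]
    return retained, pvals


def pearson_rmse(predicted: np.ndarray, observed: np.ndarray) -> dict[str, float]:
    """Sample Pearson correlation and root-mean-square error."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    rmse = float(np.sqrt(np.mean((predicted - observed) ** 2)))
    if predicted.std() == 0.0 or observed.std() == 0.0:
        warnings.warn("zero variance: Pearson r undefined", RuntimeWarning)
        return {"pearson_r": float("nan"), "rmse": rmse}
    r = float(stats.pearsonr(predicted, observed).statistic)
    return {"pearson_r": r, "rmse": rmse}


def fit_study(
    study: SimulatedStudy,
    train_ids: Sequence[str],
    scheme: WeightScheme = WeightScheme("wss"),
    hyper: Hyperparameters = Hyperparameters(),
    prescreen_threshold: Optional[float] = None,
    common_maf: float = 0.05,
    max_sweeps: int = 300,
    rel_tol: float = 1e-5,
    seed: int = 0,
) -> FitResult:
    """Fit the full model to the training slice of a simulated study.

    Region kernels come from the study's region map under `scheme`;
    common variants outside the regions form the fixed-effect block X
    (optionally pre-screened); the familial surrogates come from the full
    pedigree restricted to the training samples.
    """
    train_ids = list(train_ids)
    G_train = study.genotypes.subset(samples=train_ids)
    y_train = (
        study.phenotypes.table.loc[train_ids, "phenotype"].to_numpy(dtype=float)
    )
    region_variants = {v for vs in study.region_map.regions.values() for v in vs}
    maf_train = G_train.maf
    x_ids = [
        v
        for v, f in zip(G_train.variants.index, maf_train)
        if v not in region_variants and f >= common_maf
    ]
    familial = build_familial_kernels(study.pedigree, sample_ids=train_ids)
    if prescreen_threshold is not None and x_ids:
        Gx = G_train.subset(variants=x_ids)
        x_ids, _ = marginal_prescreen(
            Gx, y_train, familial.K_gf, threshold=prescreen_threshold
        )
    X = (
        mean_impute(G_train.subset(variants=x_ids).dosages) if x_ids else None
    )
    kernels = build_region_kernels(G_train, study.region_map, scheme=scheme)
    return fit(
        y_train,
        X,
        kernels,
        familial,
        hyper=hyper,
        max_sweeps=max_sweeps,
        rel_tol=rel_tol,
        seed=seed,
        sample_ids=train_ids,
        x_variant_ids=x_ids,
    )


def predict_study(
    fit_result: FitResult, study: SimulatedStudy, test_ids: Sequence[str]
) -> pd.DataFrame:
    """Predict the test slice of a simulated study, with family linkage."""
    G_test = study.genotypes.subset(samples=list(test_ids))
    request = make_request(fit_result, G_test, pedigree=study.pedigree)
    return predict(fit_result, request)


def ridge_baseline(
    G_train: GenotypeMatrix,
    y_train: np.ndarray,
    G_test: GenotypeMatrix,
) -> np.ndarray:
    """Genotype-only kernel ridge (gBLUP): one overall genomic relationship
    matrix, variance components by maximum likelihood, BLUP prediction.
    Deliberately ignores pedigree and family structure."""
    y = np.asarray(y_train, dtype=float)
    mu = float(y.mean())
    yc = y - mu
    A_tr = mean_impute(G_train.dosages)
    means = A_tr.mean(axis=0)
    A_tr = A_tr - means
    p = max(A_tr.shape[1], 1)
    K = A_tr @ A_tr.T / p
    eigvals, U = np.linalg.eigh(K)
    eigvals = np.maximum(eigvals, 0.0)
    sg2, se2 = _null_variance_components(yc, eigvals, U.T @ yc)
    alpha = U @ ((U.T @ yc) / (sg2 * eigvals + se2)) * sg2
    A_te = mean_impute(
        G_test.subset(variants=list(G_train.variants.index)).dosages, means=means
    )
    A_te = A_te - means
    K_star = A_te @ A_tr.T / p
    return mu + K_star @ alpha


@dataclass
class MetricReport:
    """Per-replicate metrics plus their aggregation across replicates."""

    rows: pd.DataFrame  # columns: replicate, seed, method, pearson_r, rmse
    failures: int = 0

    def aggregate(self) -> pd.DataFrame:
        return (
            self.rows.groupby("method")[["pearson_r", "rmse"]]
            .describe(percentiles=[0.25, 0.5, 0.75])
            .loc[:, (slice(None), ["25%", "50%", "75%"])]
        )

    def median(self, method: str, metric: str = "pearson_r") -> float:
        sel = self.rows[self.rows["method"] == method]
        return float(sel[metric].median())


def replicate_experiment(
    preset: str,
    n_replicates: int = 100,
    methods: Sequence[str] = ("fblmm", "ridge-baseline"),
    seed: int = 0,
    overrides: Optional[dict] = None,
    scheme: WeightScheme = WeightScheme("wss"),
    hyper: Hyperparameters = Hyperparameters(),
    split_fraction: float = 0.2,
    split_unit: str = "individual",
    prescreen_threshold: Optional[float] = None,
    max_sweeps: int = 300,
) -> MetricReport:
    """simulate -> split -> fit -> predict -> metrics, replicated.

    Replicate k uses seed = base seed + k for the simulation and the
    split.  Failed replicates are skipped and counted.
    """
    unknown = set(methods) - {"fblmm", "ridge-baseline"}
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    records: list[dict] = []
    failures = 0
    for k in range(n_replicates):
        rep_seed = seed + k
        try:
            study = run_scenario(preset, overrides=overrides, seed=rep_seed)
            plan = train_test_split(
                study.genotypes.samples,
                ped=study.pedigree,
                fraction=split_fraction,
                unit=split_unit,
                seed=rep_seed,
            )
            y_all = study.phenotypes.table["phenotype"]
            y_test = y_all.loc[list(plan.test_ids)].to_numpy(dtype=float)
            if "fblmm" in methods:
                fr = fit_study(
                    study, plan.train_ids, scheme=scheme, hyper=hyper,
                    prescreen_threshold=prescreen_threshold,
                    max_sweeps=max_sweeps, seed=rep_seed,
                )
                preds = predict_study(fr, study, plan.test_ids)
                m = pearson_rmse(preds["prediction"].to_numpy(), y_test)
                records.append(
                    {"replicate": k, "seed": rep_seed, "method": "fblmm", **m}
                )
            if "ridge-baseline" in methods:
                G_tr = study.genotypes.subset(samples=list(plan.train_ids))
                G_te = study.genotypes.subset(samples=list(plan.test_ids))
                y_tr = y_all.loc[list(plan.train_ids)].to_numpy(dtype=float)
                yhat = ridge_baseline(G_tr, y_tr, G_te)
                m = pearson_rmse(yhat, y_test)
                records.append(
                    {"replicate": k, "seed": rep_seed, "method": "ridge-baseline", **m}
                )
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            warnings.warn(f"replicate {k} failed: {exc}", RuntimeWarning)
            failures += 1
    return MetricReport(rows=pd.DataFrame.from_records(records), failures=failures)
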