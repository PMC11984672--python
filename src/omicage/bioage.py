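"""Reference-anchored biological age (BioAge) per omic layer.

A sample's BioAge in a layer is its Mahalanobis distance from the mean
profile of a young reference group (yWD), divided by the square root of
the layer's feature count so scores are comparable across layers of very
different dimensionality.  A score near 0 means "indistinguishable from
the average young reference subject"; larger scores mean older omic
profiles.  With a handful of reference subjects the sample covariance is
singular for all but the smallest layers, so the default covariance mode
is diagonal (standardized Euclidean distance); a shrinkage mode
Σλ = (1−λ)·S + λ·diag(S) is available for low-dimensional layers.

Also here: per-layer variance-stabilizing preprocessing, a generic linear
epigenetic-clock applier, age-acceleration residuals, and the epigenetic
mutation load (EML).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

BIOAGE_COLUMN = {
    "pheno": "phenoBioAge",
    "microbiome": "microbiomeBioAge",
    "metabolome": "metabolomeBioAge",
    "hormones": "hormoneBioAge",
    "dnam": "DNAmBioAge",
    "mrna": "transcriptomeBioAge",
}


# ---------------------------------------------------------------------------
# per-layer preprocessing
# ---------------------------------------------------------------------------


def clr_transform(matrix: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """Centered log-ratio transform for compositional rows.

    ``pseudocount`` defaults to half the smallest positive value in the
    matrix, added everywhere before closure so zeros are representable.
    """
    X = matrix.to_numpy(dtype=float)
    if pseudocount is None:
        pos = X[X > 0]
        if pos.size == 0:
            raise ValueError("matrix has no positive entries")
        pseudocount = pos.min() / 2.0
    X = X + pseudocount
    X = X / X.sum(axis=1, keepdims=True)
    logX = np.log(X)
    out = logX - logX.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def mvalue_transform(beta: pd.DataFrame, eps: float = 1e-6) -> pd.DataFrame:
    """Methylation beta -> M-value: log2(beta / (1 - beta)), beta clipped
    away from {0, 1} by ``eps``."""
    B = np.clip(beta.to_numpy(dtype=float), eps, 1.0 - eps)
    return pd.DataFrame(np.log2(B / (1.0 - B)), index=beta.index, columns=beta.columns)


def log_counts_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Total-sum scale each sample to the cohort median depth, then log2(x+1)."""
    X = counts.to_numpy(dtype=float)
    depth = X.sum(axis=1)
    if np.any(depth <= 0):
        raise ValueError("sample with zero total count")
    scaled = X * (np.median(depth) / depth)[:, None]
    return pd.DataFrame(np.log2(scaled + 1.0), index=counts.index, columns=counts.columns)


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Natural log with a half-minimum pseudocount if zeros are present."""
    X = matrix.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("log transform needs non-negative values")
    if np.any(X == 0):
        X = X + X[X > 0].min() / 2.0
    return pd.DataFrame(np.log(X), index=matrix.index, columns=matrix.columns)


#: conventional variance-stabilizing transform per layer family
LAYER_TRANSFORMS = {
    "microbiome": clr_transform,
    "dnam": mvalue_transform,
    "mrna": log_counts_transform,
    "metabolome": log_transform,
    "hormones": log_transform,
    "pheno": lambda m: m.astype(float),
}


def preprocess_layer(matrix: pd.DataFrame, layer: str) -> pd.DataFrame:
    """Apply the layer's conventional transform (CLR, M-value, log-CPM-style,
    log, or identity for the blood biomarkers)."""
    try:
        fn = LAYER_TRANSFORMS[layer]
    except KeyError:
        raise ValueError(f"no preprocessing registered for layer {layer!r}") from None
    return fn(matrix)


# ---------------------------------------------------------------------------
# reference model and distances
# ---------------------------------------------------------------------------


@dataclass
class ReferenceModel:
    """Young-reference location/scale (and optionally covariance) for one layer."""

    layer: str
    reference_ids: list[str]
    mu: pd.Series
    sigma: pd.Series
    mode: str = "diagonal"  # or "shrinkage"
    shrinkage_lambda: float = 0.5
    cho_factor: np.ndarray | None = None
    dropped_features: list[str] = field(default_factory=list)

    @property
    def n_ref(self) -> int:
        return len(self.reference_ids)

    @property
    def p(self) -> int:
        return len(self.mu)

    @property
    def features(self) -> pd.Index:
        return self.mu.index


def fit_reference(
    layer_matrix: pd.DataFrame,
    reference_ids,
    mode: str = "diagonal",
    shrinkage_lambda: float = 0.5,
    layer: str = "",
) -> ReferenceModel:
    """Fit per-feature mean/SD (and shrunk covariance) on reference samples.

    Zero-variance features are dropped and recorded.  In shrinkage mode the
    covariance Σλ = (1−λ)·S + λ·diag(S) must be positive definite.
    """
    reference_ids = list(reference_ids)
    missing = [r for r in reference_ids if r not in layer_matrix.index]
    if missing:
        raise ValueError(f"reference IDs absent from matrix: {missing[:5]}")
    if len(reference_ids) < 2:
        raise ValueError("need at least 2 reference samples")
    R = layer_matrix.loc[reference_ids].astype(float)
    mu = R.mean(axis=0)
    sigma = R.std(axis=0, ddof=1)
    keep = sigma > 0
    dropped = list(sigma.index[~keep])
    if not keep.any():
        raise ValueError("all features have zero variance in the reference set")
    if dropped:
        logger.info("dropping %d zero-variance features in layer %r", len(dropped), layer)
    mu, sigma = mu[keep], sigma[keep]

    cho = None
    if mode == "shrinkage":
        if not 0.0 <= shrinkage_lambda <= 1.0:
            raise ValueError("shrinkage lambda must be in [0, 1]")
        S = np.cov(R.loc[:, keep].to_numpy(), rowvar=False, ddof=1)
        S = np.atleast_2d(S)
        lam = shrinkage_lambda
        sig = (1.0 - lam) * S + lam * np.diag(np.diag(S))
        try:
            cho = linalg.cholesky(sig, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError(
                "shrunk covariance is not positive definite; increase lambda"
            ) from exc
    elif mode != "diagonal":
        raise ValueError(f"unknown covariance mode {mode!r}")

    return ReferenceModel(
        layer=layer,
        reference_ids=reference_ids,
        mu=mu,
        sigma=sigma,
        mode=mode,
        shrinkage_lambda=shrinkage_lambda,
        cho_factor=cho,
        dropped_features=dropped,
    )


def _aligned_deviation(model: ReferenceModel, x, impute_missing: bool) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        X = x
    else:
        X = pd.DataFrame([pd.Series(x)])
    missing = model.features.difference(X.columns)
    if len(missing):
        if not impute_missing:
            raise ValueError(f"sample is missing features: {list(missing[:5])}")
        X = X.reindex(columns=X.columns.union(model.features))
        for f in missing:
            X[f] = model.mu[f]
    X = X[model.features].astype(float)
    if X.isna().any().any():
        if not impute_missing:
            raise ValueError("missing values in sample; pass impute_missing=True")
        X = X.fillna(model.mu)
    return X.to_numpy() - model.mu.to_numpy()[None, :]


def mahalanobis_bioage(model: ReferenceModel, x, impute_missing: bool = False):
    """Raw Mahalanobis distance D = sqrt((x−μ)ᵀ Σ⁻¹ (x−μ)) to the reference.

    ``x`` may be a single feature vector (Series/dict -> float) or a
    sample-by-feature DataFrame (-> Series of distances).
    """
    dev = _aligned_deviation(model, x, impute_missing)
    if model.mode == "diagonal":
        z = dev / model.sigma.to_numpy()[None, :]
        D = np.sqrt((z**2).sum(axis=1))
    else:
        y = linalg.solve_triangular(model.cho_factor, dev.T, lower=True)
        D = np.sqrt((y**2).sum(axis=0))
    if isinstance(x, pd.DataFrame):
        return pd.Series(D, index=x.index, name="D")
    return float(D[0])


def standardize_bioage(D, p: int):
    """Per-feature RMS deviation: D / sqrt(p), comparable across layers."""
    if p < 1:
        raise ValueError("feature count must be >= 1")
    return D / np.sqrt(p)


def compute_all_bioages(
    dataset,
    reference_group: str = "yWD",
    mode: str = "diagonal",
    shrinkage_lambda: float = 0.5,
    preprocess: bool = True,
    layers=None,
) -> tuple[pd.DataFrame, dict[str, ReferenceModel]]:
    """Score every sample on every available layer.

    Returns (table, models): one row per sample with one standardized
    BioAge column per layer (named as in the study: phenoBioAge,
    microbiomeBioAge, ...), and the fitted reference models.  Reference
    samples are scored too; their scores sit near the chi/sqrt(p)
    expectation rather than exactly 0.
    """
    ref_ids = dataset.samples_in_group(reference_group)
    if len(ref_ids) < 2:
        raise ValueError(f"reference group {reference_group!r} has < 2 samples")
    wanted = layers if layers is not None else list(dataset.layers)
    table = pd.DataFrame(index=dataset.sample_ids)
    models: dict[str, ReferenceModel] = {}
    for layer in wanted:
        if layer not in dataset.layers:
            warnings.warn(f"layer {layer!r} absent; its BioAge column is skipped")
            continue
        mat = dataset.layers[layer]
        if preprocess:
            mat = preprocess_layer(mat, layer)
        model = fit_reference(
            mat, [r for r in ref_ids if r in mat.index], mode=mode,
            shrinkage_lambda=shrinkage_lambda, layer=layer,
        )
        D = mahalanobis_bioage(model, mat.loc[mat.index])
        col = BIOAGE_COLUMN.get(layer, f"{layer}BioAge")
        table[col] = standardize_bioage(D, model.p).reindex(table.index)
        models[layer] = model
    return table, models


# ---------------------------------------------------------------------------
# linear clocks and age acceleration
# ---------------------------------------------------------------------------


@dataclass
class ClockSpec:
    """A linear biological-age predictor: intercept + Σ wⱼ·xⱼ, optionally
    followed by an affine output transform a·pred + b."""

    name: str
    intercept: float
    coefficients: dict[str, float]
    output_transform: tuple[float, float] = (1.0, 0.0)


def apply_linear_clock(
    clock: ClockSpec, layer_matrix: pd.DataFrame, missing: str = "error"
) -> pd.Series:
    """Predicted age per sample.  ``missing`` policy for clock features not
    in the matrix: 'error' (default) or 'zero' (treat as 0 contribution)."""
    feats = list(clock.coefficients)
    absent = [f for f in feats if f not in layer_matrix.columns]
    if absent:
        if missing == "error":
            raise ValueError(f"clock features missing from matrix: {absent[:5]}")
        if missing != "zero":
            raise ValueError(f"unknown missing policy {missing!r}")
        feats = [f for f in feats if f not in absent]
    w = np.array([clock.coefficients[f] for f in feats])
    pred = clock.intercept + layer_matrix[feats].to_numpy(dtype=float) @ w
    a, b = clock.output_transform
    return pd.Series(a * pred + b, index=layer_matrix.index, name=clock.name)


def fit_linear_clock(
    layer_matrix: pd.DataFrame, age, n_features: int = 50, name: str = "synthetic_clock",
    ridge: float = 1.0,
) -> ClockSpec:
    """Train a simple ridge clock on (matrix, age) — used to round-trip the
    applier on synthetic data; real published clocks are loaded from TSV."""
    from sklearn.linear_model import Ridge

    age = pd.Series(age).loc[layer_matrix.index].to_numpy(dtype=float)
    X = layer_matrix.to_numpy(dtype=float)
    corr = np.abs(np.corrcoef(X, age, rowvar=False)[-1, :-1])
    corr = np.nan_to_num(corr)
    top = np.argsort(-corr)[: min(n_features, X.shape[1])]
    model = Ridge(alpha=ridge).fit(X[:, top], age)
    coefs = {layer_matrix.columns[j]: float(c) for j, c in zip(top, model.coef_)}
    return ClockSpec(name=name, intercept=float(model.intercept_), coefficients=coefs)


def age_acceleration(predicted, chronological) -> pd.Series:
    """Residuals of OLS regression of predicted age on chronological age.

    Residuals have mean 0 and are uncorrelated with chronological age; a
    positive value means biologically older than chronology predicts.
    """
    pred = pd.Series(predicted).astype(float)
    chron = pd.Series(chronological).astype(float)
    chron = chron.loc[pred.index] if pred.index.equals(chron.index) or set(pred.index) <= set(chron.index) else chron
    y = pred.to_numpy()
    x = chron.to_numpy()
    if len(y) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0:
        raise ValueError("chronological age is constant")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return pd.Series(resid, index=pred.index, name="age_acceleration")


# ---------------------------------------------------------------------------
# epigenetic mutation load
# ---------------------------------------------------------------------------


@dataclass
class EMLResult:
    """Per-sample epimutation counts and age-adjusted load."""

    counts: pd.Series
    eml_aa: pd.Series | None
    k: float
    n_zero_iqr: int


def epigenetic_mutation_load(
    beta: pd.DataFrame,
    reference_ids=None,
    k: float = 3.0,
    age=None,
) -> EMLResult:
    """Count CpGs whose methylation lies outside robust reference bounds.

    Per CpG, bounds are Q1 − k·IQR and Q3 + k·IQR over the reference
    samples; a sample's epimutation count is the number of CpGs strictly
    outside its bounds.  Zero-IQR CpGs are excluded (and counted).  With
    ``reference_ids=None`` every sample is scored against all the others
    (leave-one-out), which avoids self-inflation at small n.  If ``age``
    is given, EML_AA = residuals of log1p(count) regressed on age.
    """
    X = beta.to_numpy(dtype=float)
    n = X.shape[0]

    def _count(row: np.ndarray, ref: np.ndarray) -> tuple[int, int]:
        q1 = np.percentile(ref, 25, axis=0)
        q3 = np.percentile(ref, 75, axis=0)
        iqr = q3 - q1
        ok = iqr > 0
        lo, hi = q1 - k * iqr, q3 + k * iqr
        out = (row < lo) | (row > hi)
        return int(np.sum(out & ok)), int(np.sum(~ok))

    counts = np.zeros(n, dtype=int)
    zero_iqr = 0
    if reference_ids is None:
        if n < 5:
            raise ValueError("leave-one-out EML needs at least 5 samples")
        for i in range(n):
            ref = np.delete(X, i, axis=0)
            counts[i], zero_iqr = _count(X[i], ref)
    else:
        reference_ids = list(reference_ids)
        if len(reference_ids) < 4:
            raise ValueError("EML reference needs at least 4 samples (quartiles)")
        ref = beta.loc[reference_ids].to_numpy(dtype=float)
        for i in range(n):
            counts[i], zero_iqr = _count(X[i], ref)

    counts_s = pd.Series(counts, index=beta.index, name="eml")
    eml_aa = None
    if age is not None:
        eml_aa = age_acceleration(np.log1p(counts_s), pd.Series(age).loc[beta.index])
        eml_aa.name = "eml_aa"
    return EMLResult(counts=counts_s, eml_aa=eml_aa, k=k, n_zero_iqr=zero_iqr)
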