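"""Multi-block sparse PLS discriminant analysis (DIABLO-style).

Each omic block contributes a sparse latent component correlated with the
class outcome and (weakly, via the design matrix) with the other blocks'
components.  Sparsity is a per-block "keepX" — how many features keep a
nonzero loading — tuned by stratified cross-validation minimizing the
balanced error rate.  Selected features form per-layer signatures whose
overlap between two contrasts is tested hypergeometrically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioage import LAYER_TRANSFORMS
from .enrichment import edgington_combine, hypergeom_upper_tail

# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _standardize_fit(matrix: pd.DataFrame):
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    keep = sd > 0
    return mean, sd, keep


def _standardize_apply(matrix: pd.DataFrame, mean, sd, keep) -> pd.DataFrame:
    out = (matrix.loc[:, keep.index[keep]] - mean[keep]) / sd[keep]
    return out


def preprocess_block(matrix: pd.DataFrame, layer: str | None = None) -> pd.DataFrame:
    """Layer transform (if ``layer`` given) followed by column standardization.

    Columns end with mean 0 and SD 1; zero-variance columns are dropped
    with a warning.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if matrix.isna().any().any():
        raise ValueError("missing values are not allowed")
    if layer is not None and layer in LAYER_TRANSFORMS:
        matrix = LAYER_TRANSFORMS[layer](matrix)
    mean, sd, keep = _standardize_fit(matrix)
    if not keep.any():
        raise ValueError("all columns have zero variance")
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero-variance columns")
    return _standardize_apply(matrix, mean, sd, keep)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class BlockData:
    """Standardized blocks sharing a sample order, a binary outcome, and the
    block-connection design matrix (outcome block included, diagonal 0)."""

    blocks: dict[str, pd.DataFrame]
    labels: pd.Series
    design: pd.DataFrame | None = None
    positive_class: str | None = None

    def __post_init__(self) -> None:
        idx = self.labels.index
        for name, mat in self.blocks.items():
            if not mat.index.equals(idx):
                raise ValueError(f"block {name!r} sample order differs from labels")
        classes = sorted(self.labels.unique())
        if len(classes) != 2:
            raise ValueError(f"expected a binary outcome, got classes {classes}")
        if self.positive_class is None:
            self.positive_class = classes[0]
        if self.design is None:
            self.design = default_design(list(self.blocks))
        d = self.design
        names = list(self.blocks) + ["outcome"]
        if list(d.index) != names or list(d.columns) != names:
            raise ValueError("design must be indexed by block names + 'outcome'")
        if not np.allclose(np.diag(d.to_numpy()), 0):
            raise ValueError("design diagonal must be 0")
        if ((d.to_numpy() < 0) | (d.to_numpy() > 1)).any():
            raise ValueError("design entries must lie in [0, 1]")

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique())

    @classmethod
    def from_dataset(
        cls,
        dataset,
        contrast: tuple[str, str] = ("CR", "WD"),
        layers=None,
        block_weight: float = 0.1,
    ) -> "BlockData":
        """Two-group block data from a multi-omic dataset: subset samples to
        the contrast, apply per-layer transforms, standardize columns."""
        pos, ref = contrast
        ids = dataset.samples_in_group(pos) + dataset.samples_in_group(ref)
        if not ids:
            raise ValueError(f"no samples in contrast {contrast}")
        wanted = layers if layers is not None else list(dataset.layers)
        blocks = {}
        for layer in wanted:
            if layer not in dataset.layers:
                warnings.warn(f"layer {layer!r} unavailable; proceeding without it")
                continue
            blocks[layer] = preprocess_block(dataset.layers[layer].loc[ids], layer)
        labels = dataset.metadata.loc[ids, "group"]
        return cls(
            blocks=blocks,
            labels=labels,
            design=default_design(list(blocks), block_weight=block_weight),
            positive_class=pos,
        )


def default_design(block_names, outcome_weight: float = 1.0, block_weight: float = 0.1) -> pd.DataFrame:
    """Sparse-connection design: every block fully tied to the outcome,
    weakly (0.1) to the other blocks."""
    names = list(block_names) + ["outcome"]
    d = pd.DataFrame(block_weight, index=names, columns=names)
    d.loc[:, "outcome"] = outcome_weight
    d.loc["outcome", :] = outcome_weight
    np.fill_diagonal(d.to_numpy(), 0.0)
    return d


@dataclass
class SignatureModel:
    """Fitted multi-block sPLS-DA: per-block sparse loadings and scores per
    component, class centroids in score space, convergence diagnostics."""

    block_names: list[str]
    loadings: dict[str, pd.DataFrame]
    scores: dict[str, np.ndarray]
    centroids: dict[str, pd.DataFrame]
    keepX: dict[str, list[int]]
    n_components: int
    classes: list[str]
    positive_class: str
    converged: list[bool]
    n_iter: list[int]
    class_means: dict[str, pd.Series] = field(default_factory=dict)
    ref_means: dict[str, pd.Series] = field(default_factory=dict)


@dataclass
class Signature:
    """Per-layer selected features (nonzero loading on any component) with
    the direction of the intervention-vs-reference mean difference."""

    features: dict[str, list[str]]
    direction: dict[str, dict[str, str]]
    contrast: tuple[str, str] | None = None

    def size(self, layer: str | None = None) -> int:
        if layer is not None:
            return len(self.features.get(layer, []))
        return sum(len(v) for v in self.features.values())


# ---------------------------------------------------------------------------
# sparse loading update
# ---------------------------------------------------------------------------


def soft_threshold_topk(v, k: int) -> np.ndarray:
    """Keep the k largest-|v| entries, soft-thresholded by the (k+1)-th
    largest magnitude, renormalized to unit l2 norm.

    Boundary ties are broken toward the lower index (stable sort).  If
    soft-thresholding annihilates every kept entry (exact magnitude ties at
    the boundary), the kept entries fall back to their raw values so the
    documented tie rule still selects the lower index.
    """
    v = np.asarray(v, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if not np.any(v != 0):
        raise ValueError("cannot threshold a zero vector")
    out = np.zeros_like(v)
    if k >= v.size:
        out = v.copy()
    else:
        order = np.argsort(-np.abs(v), kind="stable")
        kept = order[:k]
        lam = np.abs(v[order[k]])
        shrunk = np.sign(v[kept]) * np.maximum(np.abs(v[kept]) - lam, 0.0)
        if not np.any(shrunk != 0):
            shrunk = v[kept]
        out[kept] = shrunk
    out = out / np.max(np.abs(out))  # rescale first: tiny values underflow in norm
    return out / np.linalg.norm(out)


# ---------------------------------------------------------------------------
# model fit / predict
# ---------------------------------------------------------------------------


def _outcome_matrix(labels: pd.Series, classes: list[str]) -> np.ndarray:
    Y = np.column_stack([(labels == c).to_numpy(float) for c in classes])
    Y = Y - Y.mean(axis=0, keepdims=True)
    sd = Y.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return Y / sd


def fit_multiblock_splsda(
    data: BlockData,
    keepX: dict[str, int | list[int]],
    n_components: int = 1,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> SignatureModel:
    """Fit the multi-block sparse discriminant model.

    Per component, block loadings start from the leading singular direction
    of blockᵀ·outcome and are iterated blockwise: each loading is the
    sparsified (top-keepX, soft-thresholded, renormalized) projection of
    the design-weighted sum of the other blocks' scores; blocks are then
    deflated by their own component scores.  Score vectors are normalized
    inside the design-weighted sum — otherwise spurious sample-space
    variance in high-dimensional blocks (leading sample eigenvalues grow
    like p/n) inflates their scores and lets weak block-block connections
    drown the outcome link.  Non-convergence is recorded, not fatal.
    """
    names = list(data.blocks)
    classes = data.classes
    keep = {
        b: (list(keepX[b]) if isinstance(keepX[b], (list, tuple)) else [int(keepX[b])] * n_components)
        for b in names
    }
    X = {b: data.blocks[b].to_numpy(dtype=float).copy() for b in names}
    Y = _outcome_matrix(data.labels, classes)
    D = data.design.to_numpy()
    di = {b: i for i, b in enumerate(names + ["outcome"])}

    loadings = {b: np.zeros((X[b].shape[1], n_components)) for b in names}
    scores = {b: np.zeros((X[b].shape[0], n_components)) for b in names}
    converged, iters = [], []

    for h in range(n_components):
        def unit(v: np.ndarray) -> np.ndarray:
            nv = np.linalg.norm(v)
            return v / nv if nv > 0 else v

        a = {}
        t = {}
        for b in names:
            M = X[b].T @ Y
            u, _, _ = np.linalg.svd(M, full_matrices=False)
            a[b] = u[:, 0]
            t[b] = X[b] @ a[b]
        c = Y.T @ sum(D[di["outcome"], di[b]] * unit(t[b]) for b in names)
        c /= np.linalg.norm(c) if np.linalg.norm(c) else 1.0
        t_out = Y @ c

        it, ok = 0, False
        for it in range(1, max_iter + 1):
            max_change = 0.0
            for b in names:
                w = X[b].T @ (
                    sum(D[di[b], di[k]] * unit(t[k]) for k in names if k != b)
                    + D[di[b], di["outcome"]] * unit(t_out)
                )
                kb = min(keep[b][h], X[b].shape[1])
                new_a = soft_threshold_topk(w, kb)
                if new_a @ a[b] < 0:  # fix sign for convergence tracking
                    new_a = -new_a
                max_change = max(max_change, float(np.max(np.abs(new_a - a[b]))))
                a[b] = new_a
                t[b] = X[b] @ a[b]
            c = Y.T @ sum(D[di["outcome"], di[b]] * unit(t[b]) for b in names)
            nc = np.linalg.norm(c)
            c = c / nc if nc else c
            t_out = Y @ c
            if max_change < tol:
                ok = True
                break
        converged.append(ok)
        iters.append(it)

        for b in names:
            loadings[b][:, h] = a[b]
            scores[b][:, h] = t[b]
            denom = t[b] @ t[b]
            if denom > 0:
                X[b] = X[b] - np.outer(t[b], (t[b] @ X[b]) / denom)

    if not all(converged):
        warnings.warn("multiblock sPLS-DA did not converge on every component")

    centroids = {}
    for b in names:
        rows = {}
        for cl in classes:
            mask = (data.labels == cl).to_numpy()
            rows[cl] = scores[b][mask].mean(axis=0)
        centroids[b] = pd.DataFrame(rows).T

    pos, neg = data.positive_class, [c for c in classes if c != data.positive_class][0]
    class_means, ref_means = {}, {}
    for b in names:
        mat = data.blocks[b]
        class_means[b] = mat[ (data.labels == pos).to_numpy() ].mean(axis=0)
        ref_means[b] = mat[ (data.labels == neg).to_numpy() ].mean(axis=0)

    return SignatureModel(
        block_names=names,
        loadings={b: pd.DataFrame(loadings[b], index=data.blocks[b].columns) for b in names},
        scores=scores,
        centroids=centroids,
        keepX=keep,
        n_components=n_components,
        classes=classes,
        positive_class=data.positive_class,
        converged=converged,
        n_iter=iters,
        class_means=class_means,
        ref_means=ref_means,
    )


def predict_multiblock(model: SignatureModel, blocks: dict[str, pd.DataFrame]) -> pd.Series:
    """Nearest-centroid label per block, combined by majority vote across
    blocks; ties go to the class with the smallest average centroid
    distance.  Blocks must be preprocessed with training statistics."""
    names = [b for b in model.block_names if b in blocks]
    if not names:
        raise ValueError("no block in common with the trained model")
    index = blocks[names[0]].index
    votes = pd.DataFrame(0, index=index, columns=model.classes, dtype=int)
    dist_sum = pd.DataFrame(0.0, index=index, columns=model.classes)
    for b in names:
        feats = model.loadings[b].index
        mat = blocks[b]
        missing = feats.difference(mat.columns)
        if len(missing):
            raise ValueError(f"block {b!r} lacks training features: {list(missing[:5])}")
        T = mat[feats].to_numpy(dtype=float) @ model.loadings[b].to_numpy()
        for cl in model.classes:
            d = np.linalg.norm(T - model.centroids[b].loc[cl].to_numpy()[None, :], axis=1)
            dist_sum[cl] += d
        nearest = model.centroids[b].index[
            np.argmin(
                np.stack(
                    [np.linalg.norm(T - model.centroids[b].loc[cl].to_numpy()[None, :], axis=1)
                     for cl in model.centroids[b].index],
                    axis=1,
                ),
                axis=1,
            )
        ]
        for i, cl in enumerate(nearest):
            votes.iloc[i, votes.columns.get_loc(cl)] += 1

    top = votes.max(axis=1)
    out = []
    for i, sid in enumerate(index):
        tied = votes.columns[votes.iloc[i] == top.iloc[i]]
        if len(tied) == 1:
            out.append(tied[0])
        else:  # average-distance tie break
            out.append(dist_sum.loc[sid, tied].idxmin())
    return pd.Series(out, index=index, name="predicted")


def balanced_error_rate(y_true, y_pred) -> float:
    """Mean over true classes of the within-class misclassification rate."""
    yt = pd.Series(list(y_true))
    yp = pd.Series(list(y_pred))
    if len(yt) != len(yp):
        raise ValueError("length mismatch")
    rates = []
    for cl in yt.unique():
        mask = yt == cl
        if mask.sum() == 0:
            raise ValueError(f"empty class {cl!r}")
        rates.append(float((yp[mask] != cl).mean()))
    return float(np.mean(rates))


# ---------------------------------------------------------------------------
# cross-validated keepX tuning
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    grid: list[dict[str, int]]
    ber_mean: np.ndarray
    ber_se: np.ndarray
    chosen: dict[str, int]
    folds: int
    repeats: int
    seed: int


def default_keepx_grid(data: BlockData) -> list[dict[str, int]]:
    """A sparse-to-dense ladder: {5, 10, 15, 25, 50, min(100, p)} for
    high-dimensional blocks, aligned across blocks (clipped to each p);
    small blocks (p <= 15) walk 2..p on the same ladder positions."""
    ladder = [5, 10, 15, 25, 50, 100]
    grid = []
    for pos in range(len(ladder)):
        point = {}
        for b, mat in data.blocks.items():
            p = mat.shape[1]
            if p <= 15:
                cands = list(range(2, p + 1))
                point[b] = cands[min(pos * (len(cands) - 1) // (len(ladder) - 1), len(cands) - 1)]
            else:
                point[b] = min(ladder[pos], p)
        if point not in grid:
            grid.append(point)
    return grid


def _stratified_folds(labels: pd.Series, folds: int, rng: np.random.Generator):
    assignments = np.empty(len(labels), dtype=int)
    for cl in labels.unique():
        idx = np.flatnonzero((labels == cl).to_numpy())
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            assignments[i] = j % folds
    return assignments


def tune_keepx_cv(
    data: BlockData,
    grid: list[dict[str, int]] | None = None,
    folds: int = 5,
    repeats: int = 100,
    seed: int = 0,
    n_components: int = 1,
) -> CVResult:
    """Choose keepX by stratified CV minimizing mean balanced error rate.

    Column standardization is re-fit inside each training fold; each repeat
    reshuffles the stratification with a fresh seeded stream.  Ties on mean
    BER go to the grid point retaining the fewest features in total.
    """
    if grid is None:
        grid = default_keepx_grid(data)
    min_class = int(data.labels.value_counts().min())
    if min_class < folds:
        warnings.warn(f"smallest class ({min_class}) < folds ({folds}); reducing folds")
        folds = max(2, min_class)
    rng = np.random.default_rng(seed)
    bers = np.full((len(grid), repeats * folds), np.nan)

    col = 0
    for _ in range(repeats):
        fold_of = _stratified_folds(data.labels, folds, rng)
        for f in range(folds):
            test_mask = fold_of == f
            train_idx = data.labels.index[~test_mask]
            test_idx = data.labels.index[test_mask]
            tr_blocks, te_blocks = {}, {}
            for b, mat in data.blocks.items():
                mean, sd, keep = _standardize_fit(mat.loc[train_idx])
                tr_blocks[b] = _standardize_apply(mat.loc[train_idx], mean, sd, keep)
                te_blocks[b] = _standardize_apply(mat.loc[test_idx], mean, sd, keep)
            tr = BlockData(
                blocks=tr_blocks,
                labels=data.labels.loc[train_idx],
                design=data.design,
                positive_class=data.positive_class,
            )
            for gi, point in enumerate(grid):
                model = fit_multiblock_splsda(tr, point, n_components=n_components)
                pred = predict_multiblock(model, te_blocks)
                bers[gi, col] = balanced_error_rate(data.labels.loc[test_idx], pred)
            col += 1

    mean = bers.mean(axis=1)
    se = bers.std(axis=1, ddof=1) / np.sqrt(bers.shape[1])
    totals = [sum(point.values()) for point in grid]
    best = min(range(len(grid)), key=lambda i: (mean[i], totals[i]))
    return CVResult(
        grid=grid, ber_mean=mean, ber_se=se, chosen=dict(grid[best]),
        folds=folds, repeats=repeats, seed=seed,
    )


# ---------------------------------------------------------------------------
# signatures and overlap
# ---------------------------------------------------------------------------


def extract_signature(model: SignatureModel, data: BlockData | None = None) -> Signature:
    """Union of nonzero-loading features per block, tagged with the sign of
    (intervention mean − reference mean) on the preprocessed scale."""
    features: dict[str, list[str]] = {}
    direction: dict[str, dict[str, str]] = {}
    for b in model.block_names:
        L = model.loadings[b]
        nz = L.index[(L != 0).any(axis=1)]
        features[b] = list(nz)
        diffs = model.class_means[b] - model.ref_means[b]
        direction[b] = {f: ("higher" if diffs[f] > 0 else "lower") for f in nz}
    neg = [c for c in model.classes if c != model.positive_class][0]
    return Signature(features=features, direction=direction,
                     contrast=(model.positive_class, neg))


def signature_overlap_test(
    sig_a: Signature | dict,
    sig_b: Signature | dict,
    universe_sizes: dict[str, int],
) -> dict:
    """Hypergeometric upper-tail test of the per-layer overlap of two
    signatures, Edgington-combined across layers, plus a pooled-universe
    variant (sizes summed over layers, one test)."""
    fa = getattr(sig_a, "features", sig_a)
    fb = getattr(sig_b, "features", sig_b)
    rows = []
    for layer in sorted(set(fa) & set(fb) & set(universe_sizes)):
        A, B = set(fa[layer]), set(fb[layer])
        N = int(universe_sizes[layer])
        K, n, k = len(A), len(B), len(A & B)
        if k > min(K, n) or max(K, n) > N:
            raise ValueError(f"inconsistent counts in layer {layer!r}")
        p = hypergeom_upper_tail(N, K, n, k) if K and n else 1.0
        rows.append({"layer": layer, "N": N, "K": K, "n": n, "k": k, "p": p})
    if not rows:
        raise ValueError("signatures share no layer with a known universe")
    per_layer = pd.DataFrame(rows)
    combined = edgington_combine(per_layer["p"])
    pooled = hypergeom_upper_tail(
        int(per_layer["N"].sum()), int(per_layer["K"].sum()),
        int(per_layer["n"].sum()), int(per_layer["k"].sum()),
    )
    return {"per_layer": per_layer, "p_combined": combined, "p_pooled": pooled}
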