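"""Repertoire-comparison statistics over latent syllable representations.

The central question: does a mouse's vocal repertoire under one condition
(e.g. optogenetically elicited calls) differ from its repertoire under a
reference condition (female-directed calls) by more than the repertoire
drifts within a single reference session?  The tools:

* squared maximum mean discrepancy (MMD^2) with an RBF kernel between two
  latent samples, with the median-heuristic bandwidth;
* a within-session baseline: MMD between the first and second temporal halves
  of the reference session;
* a paired Wilcoxon signed-rank test of cross-condition MMD vs baseline MMD
  across mice (continuity-corrected normal or exact enumeration);
* a shuffle test for cross-mouse consistency of the latent shift direction
  (mean pairwise cosine similarity of per-mouse shift vectors against a
  within-mouse label-permutation null);
* condition information in bits from a five-fold class-balanced logistic
  regression (prior entropy minus held-out cross-entropy);
* a UMAP projection of latents for visualization (library-backed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import norm, mannwhitneyu

from .segment import Spectrogram

__all__ = [
    "MMDResult",
    "PairedComparison",
    "ShiftConsistencyResult",
    "ConditionInfoResult",
    "median_heuristic_bandwidth",
    "rbf_mmd2",
    "half_split_baseline_mmd",
    "paired_repertoire_comparison",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "mean_latent_shift",
    "cosine_similarity",
    "shift_consistency_shuffle_test",
    "condition_information",
    "umap_embed",
    "syllable_acoustic_features",
]


# --------------------------------------------------------------------- MMD


@dataclass
class MMDResult:
    value: float
    estimator: Literal["biased_v", "unbiased_u"]
    bandwidth: float
    n1: int
    n2: int


def median_heuristic_bandwidth(X: np.ndarray, Y: np.ndarray | None = None) -> float:
    """Median pairwise Euclidean distance over the pooled sample."""
    pooled = X if Y is None else np.vstack([X, Y])
    d = pdist(pooled)
    med = float(np.median(d))
    if med <= 0:
        med = float(np.mean(d)) or 1.0
    return med


def rbf_mmd2(
    X: np.ndarray,
    Y: np.ndarray,
    bandwidth: float | None = None,
    estimator: Literal["biased_v", "unbiased_u"] = "biased_v",
) -> MMDResult:
    """Squared MMD with RBF kernel k(a,b) = exp(-||a-b||^2 / (2 sigma^2)).

    The biased V-statistic is nonnegative and zero for identical multisets;
    the unbiased U-statistic excludes diagonal terms and has expectation 0
    under equality of distributions (it can be slightly negative).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if len(X) == 0 or len(Y) == 0:
        raise ValueError("X and Y must be nonempty")
    sigma = bandwidth if bandwidth is not None else median_heuristic_bandwidth(X, Y)
    if sigma <= 0:
        raise ValueError("bandwidth must be > 0")
    g = 1.0 / (2.0 * sigma**2)
    Kxx = np.exp(-g * cdist(X, X, "sqeuclidean"))
    Kyy = np.exp(-g * cdist(Y, Y, "sqeuclidean"))
    Kxy = np.exp(-g * cdist(X, Y, "sqeuclidean"))
    m, n = len(X), len(Y)
    if estimator == "biased_v":
        value = Kxx.mean() + Kyy.mean() - 2.0 * Kxy.mean()
    elif estimator == "unbiased_u":
        if m < 2 or n < 2:
            raise ValueError("unbiased estimator needs >= 2 points per sample")
        value = (
            (Kxx.sum() - np.trace(Kxx)) / (m * (m - 1))
            + (Kyy.sum() - np.trace(Kyy)) / (n * (n - 1))
            - 2.0 * Kxy.mean()
        )
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return MMDResult(float(value), estimator, float(sigma), m, n)


def half_split_baseline_mmd(
    latents: np.ndarray,
    bandwidth: float | None = None,
    estimator: Literal["biased_v", "unbiased_u"] = "unbiased_u",
) -> MMDResult:
    """Within-session repertoire variability: MMD between the first and
    second temporal halves of one session's latents (rows in temporal order).
    """
    X = np.atleast_2d(np.asarray(latents, dtype=float))
    n = len(X)
    if n < 4:
        raise ValueError(f"need >= 4 syllables for a half-split baseline, got {n}")
    cut = int(np.ceil(n / 2))
    return rbf_mmd2(X[:cut], X[cut:], bandwidth=bandwidth, estimator=estimator)


# ----------------------------------------------------------- rank statistics


def wilcoxon_signed_rank(
    differences: Sequence[float],
    mode: Literal["exact", "normal_cc", "auto"] = "normal_cc",
) -> dict[str, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped, ties get mid-ranks, and W is the smaller of
    the positive- and negative-rank sums.  ``normal_cc`` uses the
    continuity-corrected normal approximation
    z = (W - n(n+1)/4 + 0.5) / sqrt(n(n+1)(2n+1)/24); ``exact`` enumerates the
    distribution of the rank sum over all 2^n sign assignments; ``auto``
    picks exact for n <= 25 without tied magnitudes, normal_cc otherwise.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {n}")
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    if mode == "auto":
        no_ties = len(np.unique(np.abs(d))) == n
        mode = "exact" if (n <= 25 and no_ties) else "normal_cc"
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    W = min(w_pos, w_neg)
    if mode == "normal_cc":
        mean = n * (n + 1) / 4.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        z = (W - mean + 0.5) / sd
        p = min(1.0, 2.0 * norm.cdf(z))
    elif mode == "exact":
        if n > 25:
            raise ValueError("exact enumeration supported for n <= 25")
        # integer DP over doubled ranks (mid-ranks may be half-integers)
        r2 = np.round(2 * ranks).astype(int)
        total = r2.sum()
        counts = np.zeros(total + 1, dtype=np.int64)
        counts[0] = 1
        for r in r2:
            counts[r:] = counts[r:] + counts[:-r or None].copy()
        w2 = int(round(2 * W))
        p_le = counts[: w2 + 1].sum() / float(2**n)
        p = min(1.0, 2.0 * p_le)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {"W": W, "p": float(p), "n": n, "mode": mode}


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Two-sided Mann-Whitney U test; U is the smaller of the two U values.

    Exact null enumeration for small samples without ties, tie-corrected
    normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) * len(y) <= 400 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    U1 = float(res.statistic)
    U = min(U1, len(x) * len(y) - U1)
    return {"U": U, "p": float(res.pvalue), "method": method}


# --------------------------------------------------------- repertoire shifts


def _mouse_groups(labels: pd.DataFrame) -> list[str]:
    return sorted(labels["mouse_id"].unique().tolist())


def _mouse_condition_latents(
    latents: np.ndarray, labels: pd.DataFrame, mouse: str, condition: str,
    sort_by_onset: bool = False,
) -> np.ndarray:
    mask = (labels["mouse_id"] == mouse) & (labels["condition"] == condition)
    idx = np.flatnonzero(mask.to_numpy())
    if sort_by_onset and "onset_s" in labels.columns:
        idx = idx[np.argsort(labels["onset_s"].to_numpy()[idx], kind="stable")]
    return latents[idx]


@dataclass
class PairedComparison:
    per_mouse: pd.DataFrame  # mouse_id, baseline_mmd, cross_condition_mmd
    W: float
    p: float
    mode: str

    @property
    def n_cross_greater(self) -> int:
        return int(
            (self.per_mouse["cross_condition_mmd"] > self.per_mouse["baseline_mmd"]).sum()
        )


def paired_repertoire_comparison(
    latents: np.ndarray,
    labels: pd.DataFrame,
    reference: str = "A",
    other: str = "B",
    estimator: Literal["biased_v", "unbiased_u"] = "unbiased_u",
    mode: Literal["exact", "normal_cc", "auto"] = "auto",
) -> PairedComparison:
    """Cross-condition vs within-session MMD, paired across mice.

    Per mouse: baseline = half-split MMD on the reference condition; cross =
    MMD(reference, other).  One median-heuristic bandwidth is computed from
    the mouse's pooled syllables and reused for both of that mouse's
    comparisons, so the pair is measured on the same kernel scale.  A
    Wilcoxon signed-rank test is applied to the (cross - baseline) pairs.
    """
    rows = []
    for mouse in _mouse_groups(labels):
        Xa = _mouse_condition_latents(latents, labels, mouse, reference, sort_by_onset=True)
        Xb = _mouse_condition_latents(latents, labels, mouse, other)
        if len(Xa) < 4 or len(Xb) == 0:
            raise ValueError(
                f"mouse {mouse}: needs >= 4 {reference!r} syllables and >= 1 {other!r} "
                f"syllable (got {len(Xa)}, {len(Xb)})"
            )
        sigma = median_heuristic_bandwidth(np.vstack([Xa, Xb]))
        baseline = half_split_baseline_mmd(Xa, bandwidth=sigma, estimator=estimator)
        cross = rbf_mmd2(Xa, Xb, bandwidth=sigma, estimator=estimator)
        rows.append(
            {"mouse_id": mouse, "baseline_mmd": baseline.value,
             "cross_condition_mmd": cross.value, "bandwidth": sigma}
        )
    table = pd.DataFrame(rows)
    diffs = table["cross_condition_mmd"] - table["baseline_mmd"]
    res = wilcoxon_signed_rank(diffs.to_numpy(), mode=mode)
    return PairedComparison(per_mouse=table, W=res["W"], p=res["p"], mode=res["mode"])


def mean_latent_shift(
    latents: np.ndarray, labels: pd.DataFrame, mouse_id: str,
    reference: str = "A", other: str = "B",
) -> np.ndarray:
    """Per-mouse repertoire shift: mean latent of ``other`` minus ``reference``."""
    Xa = _mouse_condition_latents(latents, labels, mouse_id, reference)
    Xb = _mouse_condition_latents(latents, labels, mouse_id, other)
    if len(Xa) == 0 or len(Xb) == 0:
        raise ValueError(f"mouse {mouse_id} lacks one of the conditions")
    return Xb.mean(axis=0) - Xa.mean(axis=0)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class ShiftConsistencyResult:
    shift_vectors: np.ndarray  # (n_mice, latent_dim)
    observed_mean_cosine: float
    null_sample: np.ndarray
    p: float
    n_shuffles: int
    seed: int


def _mean_pairwise_cosine(shifts: np.ndarray) -> float:
    norms = np.linalg.norm(shifts, axis=1)
    unit = shifts / norms[:, None]
    G = unit @ unit.T
    iu = np.triu_indices(len(shifts), k=1)
    return float(G[iu].mean())


def shift_consistency_shuffle_test(
    latents: np.ndarray,
    labels: pd.DataFrame,
    n_shuffles: int = 1000,
    seed: int = 0,
    reference: str = "A",
    other: str = "B",
) -> ShiftConsistencyResult:
    """Do repertoire shifts point the same way across mice?

    Observed statistic: mean cosine similarity over all pairs of per-mouse
    shift vectors.  Null: within each mouse independently, condition labels
    are permuted across that mouse's syllables (preserving per-condition
    counts) and the statistic recomputed.  The permutation p-value uses the
    add-one rule p = (1 + #{null >= observed}) / (1 + n_shuffles).
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    mice = _mouse_groups(labels)
    if len(mice) < 3:
        raise ValueError(f"need >= 3 mice with both conditions, got {len(mice)}")
    per_mouse = []
    for mouse in mice:
        Xa = _mouse_condition_latents(latents, labels, mouse, reference)
        Xb = _mouse_condition_latents(latents, labels, mouse, other)
        if len(Xa) == 0 or len(Xb) == 0:
            raise ValueError(f"mouse {mouse} lacks one of the conditions")
        per_mouse.append((np.vstack([Xa, Xb]), len(Xa)))
    shifts = np.stack(
        [X[na:].mean(0) - X[:na].mean(0) for X, na in per_mouse]
    )
    observed = _mean_pairwise_cosine(shifts)

    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    sums = [X.sum(0) for X, _ in per_mouse]
    for s in range(n_shuffles):
        null_shifts = np.empty_like(shifts)
        for k, (X, na) in enumerate(per_mouse):
            perm = rng.permutation(len(X))
            sum_a = X[perm[:na]].sum(0)
            mean_a = sum_a / na
            mean_b = (sums[k] - sum_a) / (len(X) - na)
            null_shifts[k] = mean_b - mean_a
        null[s] = _mean_pairwise_cosine(null_shifts)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_shuffles)
    return ShiftConsistencyResult(
        shift_vectors=shifts,
        observed_mean_cosine=observed,
        null_sample=null,
        p=float(p),
        n_shuffles=n_shuffles,
        seed=seed,
    )


# ------------------------------------------------------ condition information


@dataclass
class ConditionInfoResult:
    bits: float
    folds: int
    base_rate_entropy: float
    fold_cross_entropy: np.ndarray  # bits per fold
    seed: int


def condition_information(
    latents: np.ndarray,
    conditions: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> ConditionInfoResult:
    """Bits of condition identity predictable from latent descriptions.

    Stratified k-fold cross-validation; within every fold the majority class
    is subsampled to the minority count (class balancing, seeded) in both the
    training and held-out sets, so the base rate is 1 bit.  A standardized,
    L2-regularized linear logistic classifier is fit on the training folds and
    bits = 1 - mean held-out cross-entropy (log base 2), floored at 0.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    X = np.asarray(latents, dtype=float)
    y = np.asarray(conditions)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    for c in classes:
        if (y == c).sum() < 10:
            raise ValueError(f"need >= 10 syllables per class ({c!r} has {(y == c).sum()})")

    rng = np.random.default_rng(seed)

    def balance(idx: np.ndarray) -> np.ndarray:
        parts = []
        n_min = min((y[idx] == c).sum() for c in classes)
        for c in classes:
            sub = idx[y[idx] == c]
            parts.append(rng.choice(sub, size=n_min, replace=False))
        return np.concatenate(parts)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    ces = []
    for train_idx, test_idx in skf.split(X, y):
        tr = balance(train_idx)
        te = balance(test_idx)
        clf = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=C, max_iter=1000),
        )
        clf.fit(X[tr], y[tr])
        proba = clf.predict_proba(X[te])
        col = {c: i for i, c in enumerate(clf.classes_)}
        p_true = proba[np.arange(len(te)), [col[c] for c in y[te]]]
        ces.append(float(np.mean(-np.log2(np.clip(p_true, 1e-12, 1.0)))))
    ces = np.array(ces)
    base = 1.0  # balanced two-class prior
    bits = max(0.0, base - float(ces.mean()))
    return ConditionInfoResult(
        bits=bits, folds=folds, base_rate_entropy=base,
        fold_cross_entropy=ces, seed=seed,
    )


# ------------------------------------------------------------- visualization


def umap_embed(latents: np.ndarray, seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """2-D UMAP projection of latents (deterministic given seed)."""
    X = np.asarray(latents, dtype=float)
    if len(X) < 10:
        raise ValueError(f"need >= 10 points for a UMAP embedding, got {len(X)}")
    import umap

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, len(X) - 1),
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(X), dtype=float)


def syllable_acoustic_features(
    spec: Spectrogram,
    onset: float,
    offset: float,
    band: tuple[float, float] = (25_000.0, 120_000.0),
) -> dict[str, float]:
    """Total energy and frequency bandwidth of a syllable's spectrogram crop.

    Total energy is the sum of linear power over the crop restricted to
    ``band``; bandwidth is the range (max - min) of the per-frame
    peak-frequency track.
    """
    tmask = (spec.time_axis >= onset) & (spec.time_axis < offset)
    fmask = (spec.freq_axis >= band[0]) & (spec.freq_axis <= band[1])
    if not tmask.any() or not fmask.any():
        raise ValueError("empty syllable crop")
    P = np.exp(2.0 * spec.values[np.ix_(fmask, tmask)])
    freqs = spec.freq_axis[fmask]
    track = freqs[P.argmax(axis=0)]
    return {
        "total_energy": float(P.sum()),
        "bandwidth_hz": float(track.max() - track.min()),
    }
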