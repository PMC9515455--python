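"""Community-level statistics: ordination, permutation tests, differential features.

Distances are Bray-Curtis on relative-abundance rows; ordination is classical
PCoA (metric MDS on the double-centred Gower matrix); group effects are
tested with one-factor PERMANOVA (the adonis formulation on squared
distances, permutation p-values); matrix association with the Mantel test;
per-feature differences with the two-sided Wilcoxon rank-sum test and
Benjamini-Hochberg q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu


def _as_frame(matrix) -> pd.DataFrame:
    data = getattr(matrix, "data", matrix)
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(np.asarray(data, dtype=float))
    return data


def bray_curtis(matrix) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, d(x,y) = sum|x-y| / sum(x+y).

    Accepts an AbundanceMatrix or a samples x features DataFrame/array with
    non-negative entries; returns a square symmetric DataFrame with zero
    diagonal.
    """
    data = _as_frame(matrix)
    x = data.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative rows")
    if int((x.sum(axis=1) == 0).sum()) >= 2:
        raise ValueError("two or more all-zero rows: distance undefined")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=data.index, columns=data.index)


def _check_square(d: pd.DataFrame | np.ndarray) -> np.ndarray:
    arr = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return arr


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame        # samples x axes
    eigenvalues: np.ndarray          # all eigenvalues, descending (may be < 0)
    proportion_explained: np.ndarray  # per retained axis


def pcoa(distances: pd.DataFrame | np.ndarray, n_axes: int = 2,
         negative_in_denominator: bool = False) -> PCoAResult:
    """Classical principal-coordinate analysis of a distance matrix.

    Eigendecomposition of the double-centred Gower matrix -0.5*J D^2 J. Axes
    are ordered by eigenvalue; negative eigenvalues (non-Euclidean input) are
    reported but excluded from the %variance denominator unless
    ``negative_in_denominator`` (then their absolute values are added).
    """
    arr = _check_square(distances)
    n = arr.shape[0]
    d2 = arr**2
    j = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(gower)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_axes = min(n_axes, n)
    coords = np.zeros((n, n_axes))
    for a in range(n_axes):
        if evals[a] > 0:
            coords[:, a] = evecs[:, a] * np.sqrt(evals[a])
    denom = evals[evals > 0].sum()
    if negative_in_denominator:
        denom += np.abs(evals[evals < 0]).sum()
    prop = np.clip(evals[:n_axes], 0, None) / denom if denom > 0 else np.zeros(n_axes)
    index = distances.index if isinstance(distances, pd.DataFrame) else pd.RangeIndex(n)
    frame = pd.DataFrame(coords, index=index,
                         columns=[f"PCo{a + 1}" for a in range(n_axes)])
    return PCoAResult(frame, evals, prop)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_perm: float
    n_perm: int


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    """Within-group sum of squared distances for one labelling."""
    ss_w = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss_w += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    return ss_w


def permanova(
    distances: pd.DataFrame | np.ndarray,
    labels,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA (adonis) with a permutation p-value.

    Partitions the total sum of squared distances into between- and
    within-group components; pseudo-F = (SS_A/(a-1)) / (SS_W/(n-a)) and
    R^2 = SS_A/SS_T. The p-value is (1 + #{permuted F >= observed}) /
    (1 + n_perm) under uniform label permutation. Permutation F statistics
    are computed vectorised over all permutations at once.
    """
    arr = _check_square(distances)
    y = np.asarray(pd.Series(labels).reindex(distances.index).to_numpy()
                   if isinstance(distances, pd.DataFrame) and isinstance(labels, pd.Series)
                   else labels)
    if len(y) != arr.shape[0]:
        raise ValueError("labels length does not match distance matrix")
    groups, counts = np.unique(y, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two samples")
    n, a = arr.shape[0], len(groups)
    d2 = arr**2
    ss_t = d2.sum() / (2 * n)
    ss_w = _permanova_ss(d2, y, groups)
    ss_a = ss_t - ss_w
    with np.errstate(divide="ignore"):
        f_obs = (ss_a / (a - 1)) / (ss_w / (n - a)) if ss_w > 0 else np.inf
    r2 = ss_a / ss_t if ss_t > 0 else 0.0

    rng = np.random.default_rng(rng_seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_labels = y[perms]  # (n_perm, n)
    ss_w_perm = np.zeros(n_perm)
    for g in groups:
        m = (perm_labels == g).astype(float)
        n_g = int(counts[groups == g][0])
        q = np.einsum("bi,ij,bj->b", m, d2, m)
        ss_w_perm += q / (2 * n_g)
    ss_a_perm = ss_t - ss_w_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_a_perm / (a - 1)) / (ss_w_perm / (n - a))
    f_perm = np.where(ss_w_perm <= 0, np.inf, f_perm)
    p = (1 + int((f_perm >= f_obs).sum())) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


@dataclass
class MantelResult:
    r: float
    p_perm: float
    n_perm: int


def mantel(
    dist_a: pd.DataFrame | np.ndarray,
    dist_b: pd.DataFrame | np.ndarray,
    n_perm: int = 1000,
    rng_seed: int = 0,
    alternative: str = "two-sided",
) -> MantelResult:
    """Mantel test: Pearson r between two distance matrices.

    Correlates off-diagonal upper triangles; significance by simultaneous
    row/column permutation of the second matrix. ``alternative`` is
    ``two-sided`` (default) or ``greater``.
    """
    a = _check_square(dist_a)
    b = _check_square(dist_b)
    if a.shape != b.shape:
        raise ValueError("distance matrices must have matching dimensions")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    va = a[iu]
    r_obs = float(np.corrcoef(va, b[iu])[0, 1])
    rng = np.random.default_rng(rng_seed)
    r_perm = np.empty(n_perm)
    for i in range(n_perm):
        p = rng.permutation(n)
        r_perm[i] = np.corrcoef(va, b[np.ix_(p, p)][iu])[0, 1]
    if alternative == "greater":
        count = int((r_perm >= r_obs).sum())
    elif alternative == "two-sided":
        count = int((np.abs(r_perm) >= abs(r_obs)).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return MantelResult(r_obs, (1 + count) / (1 + n_perm), n_perm)


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    Step-up procedure: sort p ascending, scale p_(k) by m/k, take the running
    minimum from the largest rank down and cap at 1. Implemented directly so
    the arithmetic matches the textbook definition term for term.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def differential_features(
    matrix,
    labels: pd.Series,
    alpha: float = 0.05,
    use_q: bool = False,
    case: str | None = None,
    exact_max_n: int = 25,
) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum tests with BH correction.

    ``case`` names the group whose enrichment is reported as positive fold
    change (defaults to the first label in sorted order). The log2 fold
    change of group means uses a pseudocount of half the smallest positive
    value in the matrix. The test is exact when both groups have at most
    ``exact_max_n`` samples and the feature has no ties, else the normal
    approximation with continuity and tie correction. Constant features get
    p = 1 and are flagged.

    Returns a DataFrame indexed by feature with columns mean_case,
    mean_control, log2fc, p, q, direction ('case-enriched', 'control-enriched'
    or 'ns' at the configured threshold) and constant.
    """
    data = _as_frame(matrix)
    y = labels.reindex(data.index)
    groups = sorted(y.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    case = case if case is not None else groups[0]
    control = [g for g in groups if g != case][0]
    xs = data.loc[y == case].to_numpy(dtype=float)
    ys = data.loc[y == control].to_numpy(dtype=float)
    positive = data.to_numpy()[data.to_numpy() > 0]
    eps = 0.5 * positive.min() if positive.size else 1.0

    pvals, l2fc, const = [], [], []
    for j in range(data.shape[1]):
        xv, yv = xs[:, j], ys[:, j]
        both = np.concatenate([xv, yv])
        if np.all(both == both[0]):
            pvals.append(1.0)
            const.append(True)
        else:
            ties = len(np.unique(both)) < len(both)
            method = (
                "exact"
                if (max(len(xv), len(yv)) <= exact_max_n and not ties)
                else "asymptotic"
            )
            pvals.append(
                float(mannwhitneyu(xv, yv, alternative="two-sided", method=method).pvalue)
            )
            const.append(False)
        l2fc.append(float(np.log2((xv.mean() + eps) / (yv.mean() + eps))))
    q = bh_qvalues(pvals)
    crit = q if use_q else np.asarray(pvals)
    direction = [
        ("ns" if c >= alpha else (f"{case}-enriched" if f > 0 else f"{control}-enriched"))
        for c, f in zip(crit, l2fc)
    ]
    return pd.DataFrame(
        {
            "mean_case": xs.mean(axis=0),
            "mean_control": ys.mean(axis=0),
            "log2fc": l2fc,
            "p": pvals,
            "q": q,
            "direction": direction,
            "constant": const,
        },
        index=pd.Index(data.columns, name="feature_id"),
    )
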