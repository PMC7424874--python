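"""Behavioral and neural statistics.

Covers participant quality control, the cue-induced perceptual bias, the
cue-effect subtraction on decoded timecourses, Fisher's r-to-Z transform,
cluster-based permutation tests (one-sample via participant-wise sign
flipping, two-sample via group-label permutation) with sum-of-t cluster
mass, and the trialwise partial correlation between decoded and reported
directions controlling for the presented direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CUE_DIRECTIONS


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# behavior


def participant_qc(table: pd.DataFrame, threshold: float = 0.9):
    """Task-performance QC: Pearson r between presented directions and the
    mean reported direction per presented direction; pass iff r >= threshold.

    Returns ``(r, passed)``. A participant with constant mean reports has an
    undefined r and fails with r = nan.
    """
    rows = table[(table["task"] == "main") & table["reported_dir"].notna()]
    n_missing = int((table["task"] == "main").sum() - len(rows))
    if n_missing:
        warnings.warn(f"{n_missing} main-task trial(s) without a report excluded from QC",
                      RuntimeWarning, stacklevel=2)
    means = rows.groupby("presented_dir")["reported_dir"].mean()
    if len(means) < 3:
        raise InsufficientDataError(
            f"QC needs >= 3 distinct presented directions with reports, got {len(means)}"
        )
    if np.ptp(means.to_numpy()) == 0:
        return float("nan"), False
    r = float(np.corrcoef(means.index.to_numpy(), means.to_numpy())[0, 1])
    return r, bool(r >= threshold)


def perceptual_bias(table: pd.DataFrame, balanced: bool = True) -> float:
    """Cue-induced bias (deg): mean reported direction under cue63 minus
    under cue27. Positive = attraction toward the cued directions.

    By default the per-cue means weight the presented x predicted cells
    equally, so the (design-driven) difference in presented directions
    between the two cue conditions cancels and only the cue-induced report
    shift remains; ``balanced=False`` uses raw conditional means.
    """
    rows = table[(table["task"] == "main") & table["reported_dir"].notna()]
    for cue in CUE_DIRECTIONS:
        if not (rows["cue"] == cue).any():
            raise InsufficientDataError(f"no reported trials for {cue}")
    if not balanced:
        means = rows.groupby("cue")["reported_dir"].mean()
        return float(means["cue63"] - means["cue27"])
    cells = rows.groupby(["cue", "presented_dir"])["reported_dir"].mean().unstack()
    common = cells.columns[cells.notna().all(axis=0)]
    if len(common) == 0:
        raise InsufficientDataError("no presented direction occurs under both cues")
    if len(common) < cells.shape[1]:
        warnings.warn("presented direction(s) missing under one cue dropped from the bias",
                      RuntimeWarning, stacklevel=2)
    return float(cells.loc["cue63", common].mean() - cells.loc["cue27", common].mean())


def split_by_bias(biases) -> np.ndarray:
    """Post hoc participant split: True = positive bias (attracted toward the
    cues), False otherwise; an exact zero counts as unbiased."""
    biases = np.asarray(biases, dtype=float)
    return biases > 0


# ---------------------------------------------------------------------------
# cue effect on decoded direction


def cue_effect_timecourse(decoded: np.ndarray, table: pd.DataFrame) -> np.ndarray:
    """Cue effect (deg) per time step from a time x trials decoded matrix.

    Decoded directions are first averaged per (presented, predicted) cell,
    cells are then averaged within each predicted level with equal weight
    (balancing presented direction), and the cue27 level is subtracted from
    the cue63 level.
    """
    decoded = np.atleast_2d(np.asarray(decoded, dtype=float))
    main = (table["task"] == "main").to_numpy()
    if decoded.shape[1] != len(table):
        raise ValueError("decoded trials do not align with the trial table")
    presented = table["presented_dir"].to_numpy(dtype=float)
    cue = table["cue"].to_numpy()
    cell_means = {}
    for c in CUE_DIRECTIONS:
        for d in np.unique(presented[main]):
            sel = main & (cue == c) & (presented == d)
            cell_means[(c, d)] = decoded[:, sel].mean(axis=1) if sel.any() else None
    dirs = np.unique(presented[main])
    usable = [d for d in dirs if cell_means[("cue27", d)] is not None
              and cell_means[("cue63", d)] is not None]
    dropped = set(dirs) - set(usable)
    if dropped:
        warnings.warn(f"empty cue x direction cell(s); dropping direction(s) {sorted(dropped)} "
                      "from both cue levels", RuntimeWarning, stacklevel=2)
    if not usable:
        raise InsufficientDataError("no complete presented-direction cells")
    m63 = np.mean([cell_means[("cue63", d)] for d in usable], axis=0)
    m27 = np.mean([cell_means[("cue27", d)] for d in usable], axis=0)
    return m63 - m27


# ---------------------------------------------------------------------------
# correlations


def fisher_z(r):
    """Fisher's r-to-Z transform, z = atanh(r); domain |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    return np.arctanh(r)


def _residualize(y: np.ndarray, presented: np.ndarray, covariate: str) -> np.ndarray:
    """Residual of y (…, n_trials) after regressing out the presented
    direction (linear with intercept, or categorical per-level demeaning)."""
    y = np.atleast_2d(y)
    if covariate == "linear":
        X = np.column_stack([np.ones_like(presented), presented])
        beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
        return y - (X @ beta).T
    if covariate == "categorical":
        out = y.astype(float).copy()
        for level in np.unique(presented):
            sel = presented == level
            out[:, sel] -= out[:, sel].mean(axis=1, keepdims=True)
        return out
    raise ValueError(f"unknown covariate treatment {covariate!r}")


def trial_partial_correlation(
    decoded: np.ndarray, reported: np.ndarray, presented: np.ndarray,
    covariate: str = "linear",
):
    """Trialwise partial Pearson correlation between decoded and reported
    directions, controlling for the presented direction.

    ``decoded`` may be (n_trials,) or (n_times, n_trials); returns a scalar
    or per-time vector. Zero residual variance in either variable yields nan
    with a warning (undefined correlation).
    """
    decoded = np.asarray(decoded, dtype=float)
    scalar = decoded.ndim == 1
    reported = np.asarray(reported, dtype=float)
    presented = np.asarray(presented, dtype=float)
    n = len(reported)
    if n < 4:
        raise InsufficientDataError("partial correlation needs >= 4 trials")
    rd = _residualize(decoded, presented, covariate)
    rr = _residualize(reported, presented, covariate)[0]
    num = rd @ rr
    denom = np.sqrt(np.sum(rd**2, axis=1) * (rr @ rr))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    if np.any(~np.isfinite(r)):
        warnings.warn("zero residual variance: partial correlation undefined (nan)",
                      RuntimeWarning, stacklevel=2)
        r = np.where(np.isfinite(r), r, np.nan)
    return float(r[0]) if scalar else r


# ---------------------------------------------------------------------------
# cluster-based permutation tests


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    mass: float
    p: float
    d: float


@dataclass
class ClusterResult:
    clusters: list
    n_permutations: int
    threshold_p: float
    tail: str
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05):
        return [c for c in self.clusters if c.p < alpha]


def _max_run_sums(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per row, the maximum sum of ``values`` over a contiguous True run of
    ``mask`` (0 when a row has no True). Vectorized over rows."""
    vals = np.where(mask, values, 0.0)
    cs = np.cumsum(vals, axis=1)
    pos = np.arange(mask.shape[1])
    last_false = np.maximum.accumulate(np.where(~mask, pos, -1), axis=1)
    base = np.where(
        last_false >= 0,
        np.take_along_axis(cs, np.maximum(last_false, 0), axis=1),
        0.0,
    )
    run = np.where(mask, cs - base, 0.0)
    return run.max(axis=1, initial=0.0)


def _find_clusters(t: np.ndarray, mask: np.ndarray):
    """Contiguous True runs as (start_idx, end_idx_inclusive, sum_of_t)."""
    out = []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for lo, hi in zip(edges[::2], edges[1::2]):
        out.append((int(lo), int(hi - 1), float(t[lo:hi].sum())))
    return out


def _one_sample_t(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    m = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def _sign_flip_t(X: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t of sign-flipped data for every row of ``signs``
    (n_perm x n_subj), without materializing the flipped data: flipping
    changes the mean but leaves sum(x^2) unchanged."""
    n = X.shape[0]
    m = (signs @ X) / n
    ss = np.sum(X**2, axis=0)[None, :]
    var = (ss - n * m**2) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / np.sqrt(var / n)
    return np.where(np.isfinite(t), t, 0.0)


def _cluster_d_one_sample(X: np.ndarray, lo: int, hi: int) -> float:
    vals = X[:, lo:hi + 1].mean(axis=1)
    sd = vals.std(ddof=1)
    return float(vals.mean() / sd) if sd > 0 else float("inf")


def _assemble_result(t_obs, masks_and_nulls, X_for_d, times, n_perm, threshold_p, tail, seed,
                     d_fun):
    clusters = []
    for sign, mask, null in masks_and_nulls:
        for lo, hi, mass in _find_clusters(sign * t_obs, mask):
            p = (1.0 + np.sum(null >= mass)) / (1.0 + n_perm)
            clusters.append(Cluster(
                start_ms=float(times[lo]), end_ms=float(times[hi]),
                mass=float(sign * mass), p=float(p), d=d_fun(lo, hi),
            ))
    clusters.sort(key=lambda c: c.start_ms)
    return ClusterResult(clusters=clusters, n_permutations=n_perm,
                         threshold_p=threshold_p, tail=tail, seed=seed)


def cluster_perm_one_sample(
    X: np.ndarray,
    times: np.ndarray | None = None,
    threshold_p: float = 0.05,
    tail: str = "one",
    n_perm: int = 10000,
    seed: int | None = None,
) -> ClusterResult:
    """One-sample cluster-based permutation test of ``X`` (participants x
    time) against zero.

    Pointwise one-sample t values are thresholded at the one-tailed critical
    value for ``threshold_p``; contiguous supra-threshold runs form clusters
    whose mass is the sum of t. The null distribution is the maximal cluster
    mass over ``n_perm`` random participant-wise sign flips (exhaustive
    enumeration when 2**n <= n_perm); p = (1 + #{null >= mass}) / (1 +
    n_perm). ``tail='one'`` tests positive clusters only; ``'two'`` also
    forms negative clusters and uses the max of both tails as the null
    statistic. Cluster d = mean/SD across participants of the within-cluster
    mean.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_subj, n_time = X.shape
    if n_subj < 2:
        raise InsufficientDataError("need >= 2 participants")
    if times is None:
        times = np.arange(n_time, dtype=float)
    times = np.asarray(times, dtype=float)
    t_obs = _one_sample_t(X)
    t_crit = sps.t.ppf(1.0 - threshold_p, df=n_subj - 1)

    if n_subj <= 30 and 2 ** n_subj <= n_perm:
        n_eff = 2 ** n_subj
        bits = (np.arange(n_eff)[:, None] >> np.arange(n_subj)[None, :]) & 1
        signs = 2.0 * bits - 1.0
    else:
        n_eff = n_perm
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    t_perm = _sign_flip_t(X, signs)

    null_pos = _max_run_sums(t_perm, t_perm > t_crit)
    parts = []
    if tail == "one":
        parts.append((1.0, t_obs > t_crit, null_pos))
    elif tail == "two":
        null_neg = _max_run_sums(-t_perm, -t_perm > t_crit)
        null = np.maximum(null_pos, null_neg)
        parts.append((1.0, t_obs > t_crit, null))
        parts.append((-1.0, -t_obs > t_crit, null))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return _assemble_result(t_obs, parts, X, times, n_eff, threshold_p, tail, seed,
                            d_fun=lambda lo, hi: _cluster_d_one_sample(X, lo, hi))


def _two_sample_t(sumA, sumsqA, nA, sumB, sumsqB, nB):
    mA, mB = sumA / nA, sumB / nB
    ssA = sumsqA - nA * mA**2
    ssB = sumsqB - nB * mB**2
    sp2 = (ssA + ssB) / (nA + nB - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mA - mB) / np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
    return np.where(np.isfinite(t), t, 0.0)


def cluster_perm_between(
    A: np.ndarray,
    B: np.ndarray,
    times: np.ndarray | None = None,
    threshold_p: float = 0.05,
    tail: str = "two",
    n_perm: int = 10000,
    seed: int | None = None,
) -> ClusterResult:
    """Two-sample (between-participants) cluster permutation test.

    Pointwise independent-samples t (A minus B, pooled variance), clusters
    as in the one-sample test; the null redraws the group assignment
    uniformly among participants, preserving group sizes.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise InsufficientDataError("both groups need >= 2 participants")
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the time axis")
    nA, nB = A.shape[0], B.shape[0]
    n = nA + nB
    Z = np.vstack([A, B])
    Z2 = Z**2
    if times is None:
        times = np.arange(Z.shape[1], dtype=float)
    times = np.asarray(times, dtype=float)

    totals = Z.sum(axis=0)
    totals2 = Z2.sum(axis=0)
    t_obs = _two_sample_t(Z[:nA].sum(axis=0), Z2[:nA].sum(axis=0), nA,
                          Z[nA:].sum(axis=0), Z2[nA:].sum(axis=0), nB)
    t_crit = sps.t.ppf(1.0 - threshold_p, df=n - 2)

    rng = np.random.default_rng(seed)
    M = np.zeros((n_perm, n))
    for i in range(n_perm):
        M[i, rng.permutation(n)[:nA]] = 1.0
    sumA, sumsqA = M @ Z, M @ Z2
    t_perm = _two_sample_t(sumA, sumsqA, nA, totals - sumA, totals2 - sumsqA, nB)

    null_pos = _max_run_sums(t_perm, t_perm > t_crit)
    null_neg = _max_run_sums(-t_perm, -t_perm > t_crit)

    def d_fun(lo, hi):
        a = A[:, lo:hi + 1].mean(axis=1)
        b = B[:, lo:hi + 1].mean(axis=1)
        sp = np.sqrt(((nA - 1) * a.var(ddof=1) + (nB - 1) * b.var(ddof=1)) / (n - 2))
        return float((a.mean() - b.mean()) / sp) if sp > 0 else float("inf")

    parts = []
    if tail == "one":
        parts.append((1.0, t_obs > t_crit, null_pos))
    elif tail == "two":
        null = np.maximum(null_pos, null_neg)
        parts.append((1.0, t_obs > t_crit, null))
        parts.append((-1.0, -t_obs > t_crit, null))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return _assemble_result(t_obs, parts, Z, times, n_perm, threshold_p, tail, seed, d_fun)
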