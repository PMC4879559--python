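"""Nonparametric statistics for grouped imaging data.

The battery matches the study design the pipeline reproduces: an r×c
Fisher exact test for dendrite-classification contingency tables, a
Kruskal–Wallis test across condition groups of interval turnover rates,
Steel's many-to-one test of several treatments against one control with
family-wise error control, and a Mann–Whitney test for two-group
comparisons.  All tests are two-sided and use mid-ranks for ties.

Steel's test is implemented by permutation of the maximum standardized
Wilcoxon rank-sum statistic across the control-vs-treatment comparisons
(classical critical tables vary between sources); a multivariate-normal
approximation mode is provided for cross-checking.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln
from scipy.stats import rankdata

__all__ = [
    "TestResult",
    "fisher_exact_rc",
    "kruskal_wallis",
    "steel_test",
    "mann_whitney",
]

# relative tolerance when comparing table probabilities in the Fisher test,
# to avoid floating-point boundary misclassification
_PROB_RTOL = 1e-12


@dataclass
class TestResult:
    """Outcome of one hypothesis test.

    ``adjusted_p`` is populated only by Steel's test (one family-wise
    adjusted p per control-vs-treatment comparison). ``settings`` records
    everything needed to reproduce the computation (seed, Monte-Carlo
    repetitions, method variant).
    """

    method: str
    statistic: float
    p_value: float
    n_per_group: list[int]
    adjusted_p: list[float] | None = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")
        if self.adjusted_p is not None:
            for p in self.adjusted_p:
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"adjusted p out of [0, 1]: {p}")


# ---------------------------------------------------------------------------
# Fisher exact test on r x c tables


def _validate_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("table entries must be integers")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("table entries must be nonnegative")
    if arr.sum() < 1:
        raise ValueError("table total must be >= 1")
    return arr.astype(np.int64)


class _EnumerationCapExceeded(Exception):
    pass


def _enumerate_fisher(
    rows: np.ndarray, cols: np.ndarray, log_p_obs: float, cap: int
) -> tuple[float, float, int]:
    """Exact conditional p by full enumeration of margin-compatible tables.

    Returns (p_value, total_probability, n_tables).  Probabilities follow
    the multivariate hypergeometric law
    P(table) = prod(R_i!) prod(C_j!) / (N! prod(a_ij!)).
    Raises _EnumerationCapExceeded when more than ``cap`` tables exist.
    """
    r, c = len(rows), len(cols)
    n = int(rows.sum())
    log_k = float(gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1))
    lg = gammaln(np.arange(n + 2) + 1.0)  # lg[v] = log(v!)

    p_sum = 0.0
    total = 0.0
    count = 0
    col_rem = cols.astype(np.int64).copy()
    cutoff = log_p_obs + _PROB_RTOL

    def fill_row(i: int, acc_neg: float) -> None:
        # acc_neg = sum of log(a!) for all cells fixed so far
        nonlocal p_sum, total, count
        if i == r - 1:
            # last row forced by column remainders
            logp = log_k - acc_neg - float(lg[col_rem].sum())
            total += math.exp(logp)
            count += 1
            if count > cap:
                raise _EnumerationCapExceeded
            if logp <= cutoff:
                p_sum += math.exp(logp)
            return

        row_total = int(rows[i])
        suffix = np.concatenate([np.cumsum(col_rem[::-1])[::-1][1:], [0]])

        def fill_cell(j: int, rem: int, neg: float) -> None:
            if j == c - 1:
                if rem > col_rem[j]:
                    return
                col_rem[j] -= rem
                fill_row(i + 1, neg + float(lg[rem]))
                col_rem[j] += rem
                return
            lo = max(0, rem - int(suffix[j]))
            hi = min(rem, int(col_rem[j]))
            for v in range(lo, hi + 1):
                col_rem[j] -= v
                fill_cell(j + 1, rem - v, neg + float(lg[v]))
                col_rem[j] += v

        fill_cell(0, row_total, acc_neg)

    fill_row(0, 0.0)
    return p_sum, total, count


def _montecarlo_fisher(
    arr: np.ndarray,
    log_p_obs: float,
    n_draws: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte-Carlo conditional p: permute column labels against row labels.

    Sampling observations' column labels uniformly at random while keeping
    row labels fixed draws tables from the margin-conditioned null.
    Returns (p_hat, standard_error).
    """
    r, c = arr.shape
    n = int(arr.sum())
    row_labels = np.repeat(np.arange(r), arr.sum(axis=1))
    col_labels = np.repeat(np.arange(c), arr.sum(axis=0))
    log_k = float(
        gammaln(arr.sum(axis=1) + 1).sum()
        + gammaln(arr.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
    )
    cutoff = log_p_obs + _PROB_RTOL

    hits = 0
    batch = 5000
    done = 0
    while done < n_draws:
        b = min(batch, n_draws - done)
        perms = np.tile(col_labels, (b, 1))
        perms = rng.permuted(perms, axis=1)
        codes = row_labels[None, :] * c + perms  # (b, n)
        offsets = np.arange(b)[:, None] * (r * c)
        counts = np.bincount(
            (codes + offsets).ravel(), minlength=b * r * c
        ).reshape(b, r * c)
        logps = log_k - gammaln(counts + 1.0).sum(axis=1)
        hits += int(np.sum(logps <= cutoff))
        done += b
    p_hat = hits / n_draws
    se = math.sqrt(max(p_hat * (1 - p_hat), 0.0) / n_draws)
    return p_hat, se


def fisher_exact_rc(
    table,
    max_enumeration: int = 10**7,
    n_mc: int = 10**5,
    seed: int | None = None,
) -> TestResult:
    """Fisher's exact test for an r×c contingency table.

    The two-sided p-value is the total multivariate-hypergeometric
    probability of all tables with the observed margins whose probability
    does not exceed that of the observed table (within a 1e-12 relative
    tolerance).  Full enumeration is used while the margin-constrained
    table space stays within ``max_enumeration`` tables; beyond that a
    seeded Monte-Carlo estimate over ``n_mc`` label permutations is
    reported with its standard error.
    """
    arr = _validate_table(table)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    n = int(arr.sum())
    log_p_obs = float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(arr + 1).sum()
    )
    settings: dict = {"log_p_observed": log_p_obs}
    try:
        p, total, n_tables = _enumerate_fisher(rows, cols, log_p_obs, max_enumeration)
        settings.update(
            mode="enumeration", n_tables=n_tables, total_probability=total
        )
        p_value = min(p, 1.0)
    except _EnumerationCapExceeded:
        if n_mc < 10**5:
            warnings.warn(
                "fewer than 1e5 Monte-Carlo draws for the Fisher test",
                stacklevel=2,
            )
        rng = np.random.default_rng(seed)
        p_value, se = _montecarlo_fisher(arr, log_p_obs, n_mc, rng)
        settings.update(mode="monte_carlo", n_mc=n_mc, seed=seed, mc_se=se)
    return TestResult(
        method="fisher_exact_rc",
        statistic=math.exp(log_p_obs),
        p_value=p_value,
        n_per_group=[int(x) for x in cols],
        settings=settings,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def kruskal_wallis(samples: list) -> TestResult:
    """Kruskal–Wallis H test across two or more groups.

    H uses mid-ranks with the standard tie correction and is referred to a
    chi-square distribution with k−1 degrees of freedom.  When every pooled
    value is identical the data carry no ordering information and H = 0,
    p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    if any(g.size < 1 for g in groups):
        raise ValueError("every group must contain at least one value")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups)
    return TestResult(
        method="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        n_per_group=[int(g.size) for g in groups],
        settings={"df": len(groups) - 1},
    )


# ---------------------------------------------------------------------------
# Mann-Whitney

_EXACT_MAX_N = 8


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a by direct pairwise comparison (ties count 1/2)."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann–Whitney U test.

    When both groups have at most 8 observations the null distribution of U
    is enumerated exactly over all assignments of the pooled values to the
    two groups, which handles ties exactly.  Larger samples use the
    tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(a, b)
    n, m = a.size, b.size
    if n <= _EXACT_MAX_N and m <= _EXACT_MAX_N:
        pooled = np.concatenate([a, b])
        # pairwise "greater" matrix over pooled observations
        g = (pooled[:, None] > pooled[None, :]).astype(float)
        g += 0.5 * (pooled[:, None] == pooled[None, :])
        np.fill_diagonal(g, 0.0)
        mid = n * m / 2.0
        dev_obs = abs(u_obs - mid)
        total = 0
        hits = 0
        idx = np.arange(n + m)
        for combo in itertools.combinations(range(n + m), n):
            sel = np.zeros(n + m, dtype=bool)
            sel[list(combo)] = True
            u = g[np.ix_(idx[sel], idx[~sel])].sum()
            total += 1
            if abs(u - mid) >= dev_obs - 1e-12:
                hits += 1
        p = hits / total
        mode = "exact_enumeration"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        mode = "normal_approximation"
    return TestResult(
        method="mann_whitney",
        statistic=u_obs,
        p_value=min(p, 1.0),
        n_per_group=[int(n), int(m)],
        settings={"mode": mode},
    )


# ---------------------------------------------------------------------------
# Steel's many-to-one test


def _row_tie_terms(x: np.ndarray) -> np.ndarray:
    """Per-row tie correction term sum(t^3 - t) over runs of equal values."""
    r, m = x.shape
    s = np.sort(x, axis=1)
    eq = s[:, 1:] == s[:, :-1]
    # pad one False column so runs never span adjacent rows when flattened
    padded = np.concatenate([eq, np.zeros((r, 1), dtype=bool)], axis=1).ravel()
    padded = np.concatenate([[False], padded, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    t = (stops - starts) + 1  # run of L equal-pairs = t tied values
    terms = (t.astype(float)) ** 3 - t
    rows = starts // m
    out = np.zeros(r)
    np.add.at(out, rows, terms)
    return out


def _ranksum_z(subsets: np.ndarray, n0: int) -> np.ndarray:
    """Standardized Wilcoxon rank-sum z for each row of (control|treatment).

    ``subsets`` has shape (reps, n0 + nt); the first n0 columns are control.
    Mid-ranks, tie-corrected variance; a row with zero variance gives z 0.
    """
    reps, total = subsets.shape
    nt = total - n0
    ranks = rankdata(subsets, axis=1)
    w = ranks[:, n0:].sum(axis=1)
    expect = nt * (total + 1) / 2.0
    tie = _row_tie_terms(subsets)
    var = n0 * nt / 12.0 * ((total + 1) - tie / (total * (total - 1)))
    var = np.maximum(var, 0.0)
    z = np.zeros(reps)
    ok = var > 0
    z[ok] = (w[ok] - expect) / np.sqrt(var[ok])
    return z


def steel_test(
    control,
    treatments: list,
    alpha: float = 0.05,
    n_mc: int = 10_000,
    seed: int | None = None,
    method: str = "permutation",
) -> TestResult:
    """Steel's many-to-one test: each treatment group against one control.

    For each treatment the standardized Wilcoxon rank-sum statistic z_t is
    computed on (control ∪ treatment).  Family-wise adjusted p-values come
    from the permutation distribution of max_t |z_t| under ``n_mc`` seeded
    permutations of the pooled observations; unadjusted per-comparison
    permutation p-values are computed from the same draws, which guarantees
    adjusted p ≥ unadjusted p.  ``method="normal"`` instead refers |z_t| to
    the maximum of a correlated multivariate normal (the classical
    large-sample approximation).

    The reported ``p_value`` is the smallest adjusted p (the family-level
    test); ``statistic`` is max_t |z_t|.
    """
    control = np.asarray(control, dtype=float)
    groups = [np.asarray(t, dtype=float) for t in treatments]
    if control.size < 2:
        raise ValueError("control group needs at least 2 observations")
    if not groups:
        raise ValueError("at least one treatment group is required")
    if any(g.size < 2 for g in groups):
        raise ValueError("every treatment group needs at least 2 observations")
    if method not in ("permutation", "normal"):
        raise ValueError("method must be 'permutation' or 'normal'")
    if method == "permutation" and n_mc < 1000:
        warnings.warn(
            "fewer than 1000 permutations; Steel adjusted p-values will be noisy",
            stacklevel=2,
        )

    n0 = control.size
    sizes = [g.size for g in groups]
    k = len(groups)

    z_obs = np.array(
        [
            _ranksum_z(np.concatenate([control, g])[None, :], n0)[0]
            for g in groups
        ]
    )
    abs_obs = np.abs(z_obs)

    if method == "permutation":
        # sorting first makes the seeded draws invariant to the order in
        # which observations were supplied within groups
        pooled = np.sort(np.concatenate([control] + groups))
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(pooled, (n_mc, 1)), axis=1)
        offsets = np.cumsum([n0] + sizes)
        abs_z = np.empty((n_mc, k))
        for t in range(k):
            cols = np.concatenate(
                [np.arange(n0), np.arange(offsets[t], offsets[t + 1])]
            )
            abs_z[:, t] = np.abs(_ranksum_z(perms[:, cols], n0))
        max_abs = abs_z.max(axis=1)
        adjusted = [
            float((1 + np.sum(max_abs >= abs_obs[t] - 1e-12)) / (n_mc + 1))
            for t in range(k)
        ]
        unadjusted = [
            float((1 + np.sum(abs_z[:, t] >= abs_obs[t] - 1e-12)) / (n_mc + 1))
            for t in range(k)
        ]
        settings = {
            "method": "permutation",
            "n_mc": n_mc,
            "seed": seed,
            "alpha": alpha,
            "z_per_comparison": z_obs.tolist(),
            "unadjusted_p": unadjusted,
        }
    else:
        lam = np.sqrt(np.array(sizes) / (n0 + np.array(sizes)))
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
        mvn = sps.multivariate_normal(
            mean=np.zeros(k), cov=corr, allow_singular=True, seed=12345
        )
        adjusted = []
        for t in range(k):
            c = abs_obs[t]
            inside = float(mvn.cdf(np.full(k, c), lower_limit=np.full(k, -c)))
            adjusted.append(float(min(max(1.0 - inside, 0.0), 1.0)))
        unadjusted = [
            float(2.0 * sps.norm.sf(abs_obs[t])) for t in range(k)
        ]
        settings = {
            "method": "normal",
            "alpha": alpha,
            "z_per_comparison": z_obs.tolist(),
            "unadjusted_p": unadjusted,
        }

    return TestResult(
        method="steel_test",
        statistic=float(abs_obs.max()),
        p_value=float(min(adjusted)),
        n_per_group=[int(n0)] + [int(s) for s in sizes],
        adjusted_p=adjusted,
        settings=settings,
    )
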