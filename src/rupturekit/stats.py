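"""Screen statistics: exact unconditional testing, hit calling, morphology
comparisons, and gene-set enrichment against the screen background.

The workhorse is an exact unconditional (Barnard-type) test for 2x2 tables:
under independent binomials with a common success probability π, the p-value
is the supremum over π of the probability of observing a pooled score
statistic at least as extreme as the observed one. The supremum is taken on
a 1001-point equispaced π grid with local refinement around the maximizer.
The implementation factorizes the rejection region into per-row intervals of
the second group's count, which keeps the cost linear in group size and makes
pooled screen-scale tables (n ≈ 3000) tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "barnard_test",
    "bonferroni",
    "call_hits",
    "compare_morphology",
    "dunn_posthoc",
    "correlate",
    "enrich",
]

_GRID_SIZE = 1001
_REFINE_POINTS = 51


def pooled_z(x1: np.ndarray, n1: int, x2: np.ndarray, n2: int) -> np.ndarray:
    """Pooled score statistic Z for success counts x1/n1 vs x2/n2.

    Zero when the pooled proportion is degenerate (0 or 1).
    """
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    p = (x1 + x2) / (n1 + n2)
    var = p * (1.0 - p) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x1 / n1 - x2 / n2) / np.sqrt(var)
    return np.where(var > 0, z, 0.0)


def _rejection_intervals(n1: int, n2: int, z_obs: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-x1 acceptance intervals [lo, hi] of x2 where |Z| < |z_obs|.

    The rejection region {|Z| >= |z_obs|} is the complement; Z(x1, ·) is
    monotone decreasing in x2 at fixed x1, so the acceptance set is an
    interval (possibly empty: lo > hi).
    """
    thr = abs(z_obs) - 1e-12
    x1 = np.arange(n1 + 1)
    # Z(x1, ·) is monotone decreasing in x2, so both acceptance bounds are
    # found by bisection: lo = first x2 with Z < thr, hi = last with Z > -thr.
    lo = _first_below(x1, n1, n2, thr)
    hi = _first_below(x1, n1, n2, -thr) - 1
    empty = lo > hi
    lo[empty] = 1
    hi[empty] = 0
    return lo, hi


def _first_below(x1: np.ndarray, n1: int, n2: int, t: float) -> np.ndarray:
    """Per-row smallest x2 with Z(x1, x2) < t (n2+1 when none), by bisection."""
    lo_b = np.zeros_like(x1)
    hi_b = np.full_like(x1, n2 + 1)
    while np.any(lo_b < hi_b):
        mid = (lo_b + hi_b) // 2
        z = pooled_z(x1, n1, np.minimum(mid, n2), n2)
        below = (z < t) & (mid <= n2)
        hi_b = np.where(below & (lo_b < hi_b), mid, hi_b)
        lo_b = np.where(~below & (lo_b < hi_b), mid + 1, lo_b)
    return lo_b


def _reject_prob(pi_grid: np.ndarray, n1: int, n2: int,
                 lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """P(reject) under independent Binomial(n1, π), Binomial(n2, π)."""
    pi = np.asarray(pi_grid, float)
    pmf1 = _binom_pmf_grid(n1, pi)                     # (grid, n1+1)
    pmf2 = _binom_pmf_grid(n2, pi)                     # (grid, n2+1)
    cdf2 = np.concatenate([np.zeros((len(pi), 1)), np.cumsum(pmf2, axis=1)],
                          axis=1)
    acc = (cdf2[:, hi + 1] - cdf2[:, lo]).clip(0.0)    # (grid, n1+1)
    return 1.0 - np.einsum("ij,ij->i", pmf1, acc)


_PMF_CACHE: dict = {}
_PMF_CACHE_MAX_N = 64  # only small-table grids are worth keeping around


def _binom_pmf_grid(n: int, pi: np.ndarray) -> np.ndarray:
    """Binomial pmf for all x = 0..n at each π, via log-gamma (fast path).

    Grids for small n are cached: sweeps over many tables with shared group
    sizes (e.g. the enumeration oracle) reuse the same matrices.
    """
    key = None
    if n <= _PMF_CACHE_MAX_N:
        key = (n, pi.tobytes())
        cached = _PMF_CACHE.get(key)
        if cached is not None:
            return cached
    out = _binom_pmf_grid_uncached(n, pi)
    if key is not None:
        _PMF_CACHE[key] = out
    return out


def _binom_pmf_grid_uncached(n: int, pi: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    x = np.arange(n + 1)
    logc = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(pi)[:, None] * x[None, :]
        logq = np.log1p(-pi)[:, None] * (n - x)[None, :]
    # 0·log 0 = 0 at the grid endpoints
    logp[pi == 0.0, :] = np.where(x == 0, 0.0, -np.inf)
    logq[pi == 1.0, :] = np.where(n - x == 0, 0.0, -np.inf)
    return np.exp(logc[None, :] + logp + logq)


def barnard_test(a: int, b: int, c: int, d: int,
                 pi_grid: np.ndarray | None = None,
                 refine: bool = True,
                 return_grid: bool = False):
    """Exact unconditional two-sided p-value for a 2x2 table.

    The table is (successes, failures) per group: group 1 = (a, b),
    group 2 = (c, d). p = sup over nuisance π of P(|Z| >= |Z_obs|) with Z the
    pooled score statistic under independent binomials.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    n1, n2 = a + b, c + d
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups need a positive total")
    z_obs = float(pooled_z(np.array([a]), n1, np.array([c]), n2)[0])
    if z_obs == 0.0:
        # every outcome is at least as extreme; p = 1 at any π
        return (1.0, np.array([0.5]), np.array([1.0])) if return_grid else 1.0

    lo, hi = _rejection_intervals(n1, n2, z_obs)
    if pi_grid is None:
        pi_grid = np.linspace(0.0, 1.0, _GRID_SIZE)
    probs = _reject_prob(pi_grid, n1, n2, lo, hi)
    best = int(np.argmax(probs))
    p = float(probs[best])
    if refine and pi_grid is not None and len(pi_grid) > 2:
        lo_pi = pi_grid[max(best - 1, 0)]
        hi_pi = pi_grid[min(best + 1, len(pi_grid) - 1)]
        fine = np.linspace(lo_pi, hi_pi, _REFINE_POINTS)
        fine_probs = _reject_prob(fine, n1, n2, lo, hi)
        if fine_probs.max() > p:
            p = float(fine_probs.max())
        if return_grid:
            pi_grid = np.concatenate([pi_grid, fine])
            probs = np.concatenate([probs, fine_probs])
    p = min(p, 1.0)
    return (p, pi_grid, probs) if return_grid else p


def barnard_enumeration_oracle(a: int, b: int, c: int, d: int,
                               pi_grid: np.ndarray) -> float:
    """Brute-force unconditional p: full outcome enumeration on a π grid.

    Independent of the interval factorization; O((n1·n2) · |grid|), so only
    for small tables.
    """
    n1, n2 = a + b, c + d
    x1 = np.arange(n1 + 1)
    x2 = np.arange(n2 + 1)
    z = pooled_z(x1[:, None], n1, x2[None, :], n2)
    z_obs = z[a, c]
    reject = np.abs(z) >= abs(z_obs) - 1e-12
    pi = np.asarray(pi_grid, float)
    pmf1 = _binom_pmf_grid(n1, pi)   # (grid, n1+1)
    pmf2 = _binom_pmf_grid(n2, pi)   # (grid, n2+1)
    probs = np.einsum("gi,gj,ij->g", pmf1, pmf2, reject.astype(float))
    return min(float(probs.max()), 1.0)


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m·p)."""
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def _log2fc(p_cond: float, n_cond: int, p_ctrl: float, n_ctrl: int,
            k_cond: int, k_ctrl: int) -> float:
    """log2 ratio of proportions, Haldane-adjusted only when a zero occurs."""
    if k_cond == 0 or k_ctrl == 0 or k_cond == n_cond or k_ctrl == n_ctrl:
        p_cond = (k_cond + 0.5) / (n_cond + 1.0)
        p_ctrl = (k_ctrl + 0.5) / (n_ctrl + 1.0)
    return math.log2(p_cond / p_ctrl)


def call_hits(summaries: pd.DataFrame, control_condition: str = "CTRL",
              alpha: float = 0.05, lfc_cut: float = 0.3,
              proportion_col: str = "prop_rfp_positive",
              count_col: str = "n_rfp_positive") -> pd.DataFrame:
    """Hit calling versus the pooled control: exact test + Bonferroni + log2FC.

    A condition is a hit when its adjusted p-value is below ``alpha`` AND
    |log2FC| >= ``lfc_cut``; direction is the sign of the fold change. Counts
    are pooled across replicates for the test. Returns the volcano table.
    """
    ctrl = summaries[summaries["condition"] == control_condition]
    if len(ctrl) != 1:
        raise ValueError(f"expected exactly one control row {control_condition!r}")
    k_ctrl = int(ctrl[count_col].iloc[0])
    n_ctrl = int(ctrl["n"].iloc[0])
    rows = []
    for _, s in summaries[summaries["condition"] != control_condition].iterrows():
        k, n = int(s[count_col]), int(s["n"])
        p = barnard_test(k, n - k, k_ctrl, n_ctrl - k_ctrl)
        lfc = _log2fc(s[proportion_col], n, ctrl[proportion_col].iloc[0],
                      n_ctrl, k, k_ctrl)
        rows.append({"condition": s["condition"], "n": n, "k": k,
                     "proportion": s[proportion_col], "log2fc": lfc, "p": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bonferroni(out["p"].to_numpy())
    out["direction"] = np.where(out["log2fc"] > 0, "up",
                                np.where(out["log2fc"] < 0, "down", "none"))
    out["hit"] = (out["p_adjusted"] < alpha) & (out["log2fc"].abs() >= lfc_cut)
    out.loc[~out["hit"] & (out["log2fc"] == 0), "direction"] = "none"
    out["neg_log10_p_adjusted"] = -np.log10(out["p_adjusted"].clip(lower=1e-300))
    return out


def compare_morphology(groups: dict[str, np.ndarray], test: str = "wilcoxon"
                       ) -> pd.DataFrame:
    """Two-sided comparisons of a continuous per-cell measure between groups.

    ``test``: 'wilcoxon' (rank-sum) or 'ks' for exactly two groups;
    'kruskal' for more than two, followed by Dunn's pairwise comparisons with
    Bonferroni family adjustment. Returns one row per comparison.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], float) for k in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for name, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    if test in ("wilcoxon", "ks"):
        if len(arrays) != 2:
            raise ValueError(f"{test} requires exactly two groups")
        if test == "wilcoxon":
            stat, p = sps.ranksums(arrays[0], arrays[1])
        else:
            stat, p = sps.ks_2samp(arrays[0], arrays[1])
        return pd.DataFrame([{"group1": names[0], "group2": names[1],
                              "test": test, "stat": stat, "p": p,
                              "p_adjusted": p}])
    if test != "kruskal":
        raise ValueError(f"unknown test {test!r}")
    h, p_global = sps.kruskal(*arrays)
    out = dunn_posthoc(groups)
    out.insert(0, "test", "kruskal+dunn")
    out["kw_stat"] = h
    out["kw_p"] = p_global
    return out


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons with tie correction.

    Z for a pair = difference of mean ranks over the pooled sample divided by
    its standard error; family adjustment is Bonferroni over all pairs.
    """
    names = list(groups)
    data = [np.asarray(groups[k], float) for k in names]
    pooled = np.concatenate(data)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    mean_ranks, sizes = [], []
    start = 0
    for arr in data:
        mean_ranks.append(ranks[start:start + arr.size].mean())
        sizes.append(arr.size)
        start += arr.size
    rows = []
    m = len(names) * (len(names) - 1) // 2
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = math.sqrt((n * (n + 1) / 12.0 - tie_term)
                           * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group1": names[i], "group2": names[j],
                         "stat": z, "p": p,
                         "p_adjusted": min(1.0, p * m)})
    return pd.DataFrame(rows)


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p (e.g. median nucleus area vs
    rupture proportion across conditions)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class EnrichmentResult:
    term: str
    description: str
    k: int  # hits in set
    n: int  # hits tested
    K: int  # screen genes in set
    N: int  # screen size
    score: float  # (k/n) / (K/N)
    p: float  # one-sided Fisher / hypergeometric upper tail


def enrich(hits: list[str], screen_genes: list[str],
           gene_sets: dict[str, list[str]],
           descriptions: dict[str, str] | None = None
           ) -> pd.DataFrame:
    """Over-representation of hits in gene sets, against the screen universe.

    Gene sets are intersected with the screened gene list before testing, so
    enrichment is relative to the landscape of the screen, not the genome.
    score = (k/n)/(K/N); p = one-sided Fisher exact = P(X >= k) for
    X ~ Hypergeom(N, K, n).
    """
    screen = set(screen_genes)
    hit_set = set(hits)
    if not hit_set:
        raise ValueError("empty hit list")
    if not hit_set <= screen:
        raise ValueError("hits must be a subset of the screened genes")
    N = len(screen)
    n = len(hit_set)
    rows = []
    descriptions = descriptions or {}
    for term, genes in gene_sets.items():
        members = set(genes) & screen
        K = len(members)
        if K == 0:
            continue
        k = len(members & hit_set)
        score = (k / n) / (K / N)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append(EnrichmentResult(term=term,
                                     description=descriptions.get(term, ""),
                                     k=k, n=n, K=K, N=N, score=score,
                                     p=min(p, 1.0)))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if len(out):
        out = out.sort_values("p", ignore_index=True)
    return out
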