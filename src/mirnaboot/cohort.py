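"""Cohort demographic statistics: Freeman-Halton Fisher exact r x c test,
Kruskal-Wallis rank test, and the demographic summary table.

The Freeman-Halton test generalizes Fisher's exact test to r x c
contingency tables: conditional on the margins, each table has a
multivariate hypergeometric probability

    P(T) = (prod_i r_i!) (prod_j c_j!) / (N! prod_ij n_ij!),

and the two-sided p-value is the sum of P over all margin-compatible
tables whose probability does not exceed the observed one.  Small
tables are enumerated exactly (margin-constrained traversal); larger
tables use a seeded Monte Carlo over margin-fixed tables
(scipy.stats.random_table) with a standard error estimate.

Bundled demographic contingency tables (recruitment site, education,
smoking, child sex, ...) provide the maternal PAE cohort counts used
throughout the tests; columns are in group order HEa, HEua, UE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

#: relative tolerance when comparing table probabilities to the observed
_REL_TOL = 1e-7

#: enumeration-size ceiling above which auto mode switches to Monte Carlo
_EXACT_LIMIT = 200_000

GROUP_COLUMNS = ("HEa", "HEua", "UE")


@dataclass
class FisherResult:
    """Outcome of the r x c Fisher exact test."""

    p: float
    method: str  # "exact" or "montecarlo"
    n_draws: Optional[int] = None
    se: Optional[float] = None

    def __float__(self) -> float:
        return self.p


def _validate_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=np.int64)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (arr < 0).any():
        raise ValueError("counts must be >= 0")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("zero row or column margin")
    return arr


def _bounded_compositions(
    total: int, bounds: Sequence[int]
) -> Iterator[Tuple[int, ...]]:
    """All ways to split ``total`` over cells with per-cell upper bounds."""
    if len(bounds) == 1:
        if 0 <= total <= bounds[0]:
            yield (total,)
        return
    rest = sum(bounds[1:])
    lo = max(0, total - rest)
    hi = min(total, bounds[0])
    for first in range(lo, hi + 1):
        for tail in _bounded_compositions(total - first, bounds[1:]):
            yield (first,) + tail


def _count_compositions(total: int, bounds: Sequence[int]) -> int:
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for b in bounds:
        new = np.zeros_like(counts)
        cum = np.cumsum(counts)
        for t in range(total + 1):
            lo = t - min(b, t)
            new[t] = cum[t] - (cum[lo - 1] if lo > 0 else 0.0)
        counts = new
    return int(counts[total])


def _enumeration_size(rows: np.ndarray, cols: np.ndarray) -> float:
    est = 1.0
    for r in rows[:-1]:
        est *= max(1, _count_compositions(int(r), list(cols)))
        if est > 1e12:
            break
    return est


def _exact_p(arr: np.ndarray) -> float:
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    n = int(arr.sum())
    lf = gammaln(np.arange(n + 2, dtype=np.float64))  # lf[k] = log(k-1)!... shifted

    def logfact(k):
        return lf[k + 1] if np.ndim(k) == 0 else lf[np.asarray(k) + 1]

    const = float(logfact(rows).sum() + logfact(cols).sum() - logfact(n))
    obs_logp = const - float(logfact(arr).sum())
    threshold = obs_logp + math.log1p(_REL_TOL)

    r = arr.shape[0]
    p_sum = 0.0
    stack_cols = cols.astype(int)

    def recurse(row_idx: int, rem: Tuple[int, ...], acc: float) -> None:
        nonlocal p_sum
        if row_idx == r - 1:
            logp = const - acc - float(logfact(np.array(rem)).sum())
            if logp <= threshold:
                p_sum += math.exp(logp)
            return
        for comp in _bounded_compositions(int(rows[row_idx]), rem):
            new_rem = tuple(m - c for m, c in zip(rem, comp))
            recurse(row_idx + 1, new_rem, acc + float(logfact(np.array(comp)).sum()))

    recurse(0, tuple(stack_cols), 0.0)
    return min(p_sum, 1.0)


def _montecarlo_p(
    arr: np.ndarray, n_draws: int, seed: int
) -> Tuple[float, float]:
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    n = int(arr.sum())
    lf = gammaln(np.arange(n + 2, dtype=np.float64))
    obs_sum_lf = float(lf[arr + 1].sum())
    # P(T) <= P(obs)(1 + tol)  <=>  sum log n_ij! >= obs_sum_lf - log1p(tol)
    cut = obs_sum_lf - math.log1p(_REL_TOL)
    dist = stats.random_table(rows, cols)
    rng = np.random.default_rng([int(seed), 911])
    hits = 0
    chunk = 200_000
    remaining = n_draws
    while remaining > 0:
        k = min(chunk, remaining)
        draws = dist.rvs(k, random_state=rng)  # (k, r, c)
        sums = lf[draws.astype(np.int64) + 1].sum(axis=(1, 2))
        hits += int(np.count_nonzero(sums >= cut))
        remaining -= k
    p = (hits + 1) / (n_draws + 1)
    se = math.sqrt(p * (1.0 - p) / n_draws)
    return p, se


def fisher_exact_rxc(
    table,
    method: str = "auto",
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> FisherResult:
    """Freeman-Halton Fisher exact test for an r x c table.

    method : "exact" enumerates all margin-compatible tables (feasible
        for small tables, e.g. up to ~3x3 at N ~ 100); "montecarlo"
        draws ``n_draws`` margin-fixed tables; "auto" picks exact when
        the enumeration is small enough.
    """
    arr = _validate_table(table)
    # orient with fewer rows to shrink the enumeration depth
    if arr.shape[0] > arr.shape[1]:
        arr = arr.T
    if method == "auto":
        size = _enumeration_size(arr.sum(axis=1), arr.sum(axis=0))
        method = "exact" if size <= _EXACT_LIMIT else "montecarlo"
    if method == "exact":
        return FisherResult(_exact_p(arr), "exact")
    if method == "montecarlo":
        if n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        p, se = _montecarlo_p(arr, n_draws, seed)
        return FisherResult(p, "montecarlo", n_draws=n_draws, se=se)
    raise ValueError("method must be auto, exact or montecarlo")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared p-value.

    Degenerate all-identical data returns (0, 1).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) == 0 for g in arrays):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# demographic summary


def cohort_table(
    meta: pd.DataFrame,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
    group_col: str = "group",
    fisher_method: str = "auto",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-variable demographic summary with the matching test p-value.

    Continuous variables get per-group mean +/- SD and a Kruskal-Wallis
    p; categorical variables get per-group counts and a Fisher exact p.
    """
    groups = [g for g in GROUP_COLUMNS if g in set(meta[group_col])]
    if len(groups) < 2:
        raise ValueError("need >= 2 exposure groups present")
    rows = []
    for var in continuous:
        vals = [meta.loc[meta[group_col] == g, var].dropna() for g in groups]
        _, p = kruskal_wallis(vals)
        cells = {
            g: f"{v.mean():.2f} +/- {v.std(ddof=1):.2f}" for g, v in zip(groups, vals)
        }
        rows.append({"variable": var, "test": "kruskal-wallis", "p": p, **cells})
    for var in categorical:
        tab = pd.crosstab(meta[var], meta[group_col]).reindex(columns=groups)
        if (tab.to_numpy().sum(axis=0) == 0).any() or tab.shape[0] < 2:
            p = 1.0
        else:
            p = fisher_exact_rxc(tab.to_numpy(), method=fisher_method, seed=seed).p
        cells = {g: "/".join(str(c) for c in tab[g]) for g in groups}
        rows.append({"variable": var, "test": "fisher-exact", "p": p, **cells})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundled demographic contingency tables (columns HEa, HEua, UE)

_T = lambda rows, labels: pd.DataFrame(  # noqa: E731
    rows, index=labels, columns=list(GROUP_COLUMNS)
)

DEMOGRAPHIC_TABLES: Dict[str, pd.DataFrame] = {
    "recruitment_site": _T(
        [[20, 6, 13], [14, 17, 23]], ["Khmelnytsky", "Rivne"]
    ),
    "marital_status": _T(
        [[30, 20, 34], [4, 3, 2]], ["married_cohabiting", "single_separated"]
    ),
    "education": _T(
        [[4, 1, 0], [18, 13, 13], [12, 9, 23]],
        ["less_than_high_school", "high_school", "some_college_or_higher"],
    ),
    "socioeconomic": _T(
        [[8, 1, 2], [4, 5, 6], [12, 10, 8], [8, 5, 13], [2, 2, 7]],
        ["8-19", "20-29", "30-39", "40-54", "55-66"],
    ),
    "gravidity": _T([[16, 12, 20], [18, 11, 16]], ["gt1", "eq1"]),
    "parity": _T([[14, 10, 16], [20, 13, 20]], ["gt0", "eq0"]),
    "smoking": _T(
        [[10, 5, 3], [9, 6, 31], [11, 7, 1], [3, 5, 1]],
        ["current", "never", "quit_after_pregnancy", "quit_before_pregnancy"],
    ),
    "multivitamin_after": _T([[12, 3, 8], [22, 20, 28]], ["no", "yes"]),
    "multivitamin_prior": _T([[14, 7, 15], [20, 16, 21]], ["no", "yes"]),
    "child_sex": _T([[18, 14, 14], [16, 9, 22]], ["F", "M"]),
}

#: published two-sided Fisher p-values for the tables above (smoking is
#: reported as a bound)
PUBLISHED_FISHER_P: Dict[str, float] = {
    "recruitment_site": 0.036,
    "marital_status": 0.506,
    "education": 0.042,
    "socioeconomic": 0.13,
    "gravidity": 0.808,
    "parity": 0.964,
    "multivitamin_after": 0.165,
    "multivitamin_prior": 0.687,
    "child_sex": 0.246,
}
PUBLISHED_FISHER_P_BOUNDS: Dict[str, float] = {"smoking": 0.001}


def write_fixture_tables(outdir) -> Dict[str, pd.DataFrame]:
    """Write the demographic contingency tables as TSV fixtures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, tab in DEMOGRAPHIC_TABLES.items():
        tab.to_csv(outdir / f"table_{name}.tsv", sep="\t", index_label="level")
    return {k: v.copy() for k, v in DEMOGRAPHIC_TABLES.items()}
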