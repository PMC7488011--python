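"""Co-secretion correlation networks and bootstrap count statistics.

A correlation network for one (group, sex stratum, time point) cell is
the matrix of pairwise Pearson correlations across miRNAs, with the
number of significant (p < alpha, two-sided t test on n-2 df) unordered
pairs as its headline statistic.  Stability is assessed by resampling
the cell B times, recording the significant-pair count per iteration,
and testing whether an exposed cell's counts exceed the unexposed
reference's bootstrap mean count:

    p = 1 - #{i : count_exposed[i] > mean(count_reference)} / B.

Partial correlations (residualizing every miRNA on gestational age at
blood draw) quantify how much of the network is attributable to the GA
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NormalizedExpression
from .resampling import BootstrapConfig, resample_index_matrix

_TINY = np.finfo(float).tiny


@dataclass
class CorrelationSummary:
    """Pearson matrix, p matrix and significant-pair count for one cell."""

    r: pd.DataFrame
    p: pd.DataFrame
    alpha: float
    n_samples: int

    @property
    def n_significant(self) -> int:
        return count_significant(self.p.to_numpy(), self.alpha)

    def edges(self) -> pd.DataFrame:
        """Significant-pair edge list (mirna_a, mirna_b, r, p), stable order."""
        ids = self.r.columns
        rmat = self.r.to_numpy()
        pmat = self.p.to_numpy()
        iu, ju = np.triu_indices(len(ids), k=1)
        sig = pmat[iu, ju] < self.alpha
        return pd.DataFrame(
            {
                "mirna_a": ids[iu[sig]],
                "mirna_b": ids[ju[sig]],
                "r": rmat[iu, ju][sig],
                "p": pmat[iu, ju][sig],
            }
        )


@dataclass
class CountDistribution:
    """Bootstrap distribution of significant-pair counts for one cell."""

    counts: np.ndarray
    group: str
    stratum: str
    time_point: str

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.counts))

    @property
    def n_iterations(self) -> int:
        return len(self.counts)


# ---------------------------------------------------------------------------
# plain-sample statistics


def _corr_from_standardized(z: np.ndarray) -> np.ndarray:
    r = z.T @ z / z.shape[0]
    np.clip(r, -1.0, 1.0, out=r)
    return r


def _standardize(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Column-standardize; constant columns become all-zero (flagged)."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    const = sd == 0.0
    sd_safe = np.where(const, 1.0, sd)
    z = (x - mu) / sd_safe
    z[:, const] = 0.0
    return z, const


def pearson_matrix(
    x: np.ndarray | pd.DataFrame, alpha: float = 0.05
) -> CorrelationSummary:
    """All-pairs Pearson r with two-sided p from t = r sqrt((n-2)/(1-r^2)).

    Constant columns yield r = 0, p = 1 for all their pairs; |r| = 1
    p-values are clamped to the smallest positive representable value.
    """
    if isinstance(x, pd.DataFrame):
        ids = x.columns
        arr = x.to_numpy(dtype=float)
    else:
        arr = np.asarray(x, dtype=float)
        ids = pd.Index([f"v{i}" for i in range(arr.shape[1])])
    n = arr.shape[0]
    if n < 3:
        raise ValueError("need >= 3 samples")
    z, const = _standardize(arr)
    r = _corr_from_standardized(z)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = _TINY
    p[const, :] = 1.0
    p[:, const] = 1.0
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, _TINY)
    return CorrelationSummary(
        pd.DataFrame(r, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
        alpha,
        n,
    )


def count_significant(p: np.ndarray, alpha: float) -> int:
    """Number of unordered off-diagonal pairs with p strictly < alpha."""
    iu, ju = np.triu_indices(p.shape[0], k=1)
    return int(np.count_nonzero(p[iu, ju] < alpha))


def partial_correlation_matrix(
    x: np.ndarray | pd.DataFrame, covariates: np.ndarray
) -> pd.DataFrame | np.ndarray:
    """Pearson correlation of residuals after regressing out covariates.

    Each column is residualized on [1, covariates] by least squares;
    the correlation of the residuals is the partial correlation
    controlling for the covariates.
    """
    frame = isinstance(x, pd.DataFrame)
    arr = x.to_numpy(dtype=float) if frame else np.asarray(x, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != arr.shape[0]:
        cov = cov.T
    n = arr.shape[0]
    if cov.shape[0] != n:
        raise ValueError("covariates not aligned with samples")
    if n <= cov.shape[1] + 2:
        raise ValueError("too few samples for the covariate set")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear or constant covariates")
    beta, *_ = np.linalg.lstsq(design, arr, rcond=None)
    resid = arr - design @ beta
    z, const = _standardize(resid)
    r = _corr_from_standardized(z)
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    if frame:
        return pd.DataFrame(r, index=x.columns, columns=x.columns)
    return r


def correlation_concordance(full, partial) -> float:
    """R^2 between the vectorized upper triangles of two matrices."""
    a = np.asarray(full, dtype=float)
    b = np.asarray(partial, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrix shapes differ")
    iu, ju = np.triu_indices(a.shape[0], k=1)
    va, vb = a[iu, ju], b[iu, ju]
    if va.std() == 0.0 or vb.std() == 0.0:
        raise ValueError("zero variance in an upper triangle")
    return float(np.corrcoef(va, vb)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# bootstrap counts


def _critical_r(n: int, alpha: float) -> float:
    """|r| threshold equivalent to the strict two-sided p < alpha test."""
    df = n - 2
    t_crit = stats.t.isf(alpha / 2.0, df)
    return float(np.sqrt(t_crit**2 / (t_crit**2 + df)))


def _bootstrap_counts(
    x: np.ndarray, idx: np.ndarray, alpha: float, chunk: int = 64
) -> np.ndarray:
    """Significant-pair count per resample row of ``idx``.

    Duplicated-draw degeneracies (constant columns in a resample)
    standardize to zero, giving r = 0 — non-significant — so every
    iteration counts over the same fixed pair universe.
    """
    n, m = x.shape
    r_crit = _critical_r(n, alpha)
    b_total = idx.shape[0]
    counts = np.empty(b_total, dtype=np.int64)
    iu, ju = np.triu_indices(m, k=1)
    for start in range(0, b_total, chunk):
        sl = slice(start, min(start + chunk, b_total))
        res = x[idx[sl]]  # (b, n, m)
        mu = res.mean(axis=1, keepdims=True)
        sd = res.std(axis=1, keepdims=True)
        const = sd == 0.0
        z = (res - mu) / np.where(const, 1.0, sd)
        z = np.where(const, 0.0, z)
        r = np.einsum("bnm,bnk->bmk", z, z) / n
        sig = np.abs(r[:, iu, ju]) > r_crit
        counts[sl] = sig.sum(axis=1)
    return counts


def bootstrap_correlation_counts(
    expr: NormalizedExpression,
    meta: pd.DataFrame,
    config: BootstrapConfig,
    group: str,
    time_point: str = "T2",
    sex: Optional[str] = None,
) -> CountDistribution:
    """Bootstrap distribution of significant-correlation counts.

    The (group, sex, time point) cell is resampled with replacement at
    its own size B times; each iteration's count of p < alpha pairs is
    recorded.
    """
    mask = (meta["group"] == group) & (meta["time_point"] == time_point)
    stratum = "aggregated"
    if sex is not None:
        mask &= meta["sex"] == sex
        stratum = {"M": "male", "F": "female"}[sex]
    rows = meta.index[mask]
    if len(rows) < 4:
        raise ValueError(
            f"cell ({group}, {stratum}, {time_point}) has {len(rows)} samples; "
            "need >= 4"
        )
    x = expr.dct.loc[rows].to_numpy(dtype=float)
    tag = f"{time_point}/{stratum}/{group}"
    idx = resample_index_matrix(
        len(rows), config.n_iterations, config.seed, "corr", tag
    )
    counts = _bootstrap_counts(x, idx, config.alpha)
    return CountDistribution(counts, group, stratum, time_point)


def correlation_count_test(
    exposed: CountDistribution, reference: CountDistribution
) -> float:
    """Count-exceedance p-value for 'exposed has more significant pairs'.

    p = 1 - (#{exposed counts strictly > reference bootstrap mean}) / B;
    reject the equal-mean null when p < 0.05.
    """
    if exposed.n_iterations != reference.n_iterations:
        raise ValueError("distributions come from different iteration counts")
    ref_mean = reference.mean_count
    frac = np.mean(exposed.counts > ref_mean)
    return float(1.0 - frac)


def iteration_calibration(
    expr: NormalizedExpression,
    meta: pd.DataFrame,
    group: str,
    iteration_grid: Sequence[int] = (50, 100, 250, 500, 1000, 2000, 3000),
    n_runs: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
    time_point: str = "T2",
    sex: Optional[str] = None,
) -> pd.DataFrame:
    """Stability of the mean significant-correlation count versus B.

    For each B in the grid and each of ``n_runs`` independent bootstrap
    streams, runs :func:`bootstrap_correlation_counts` and records the
    mean count.  The across-run spread of the mean shrinks as 1/sqrt(B),
    guiding the choice of iteration count.
    """
    if not iteration_grid:
        raise ValueError("empty iteration grid")
    rows = []
    for b in iteration_grid:
        if int(b) < 1:
            raise ValueError(f"invalid iteration count {b}")
        for run in range(n_runs):
            cfg = BootstrapConfig(
                n_iterations=int(b),
                alpha=alpha,
                seed=int(np.random.default_rng([seed, 5551, int(b), run]).integers(2**31)),
            )
            dist = bootstrap_correlation_counts(
                expr, meta, cfg, group, time_point=time_point, sex=sex
            )
            rows.append(
                {"n_iterations": int(b), "run": run, "mean_count": dist.mean_count}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results facade


@dataclass
class CorrelationNetworkResults:
    """Per-cell correlation summaries, bootstrap counts and tests."""

    summaries: Dict[Tuple[str, str, str], CorrelationSummary]
    distributions: Dict[Tuple[str, str, str], CountDistribution]
    tests: pd.DataFrame  # group, stratum, time_point, p, significant
    config: BootstrapConfig

    def counts_table(self) -> pd.DataFrame:
        rows = [
            {
                "group": g,
                "stratum": s,
                "time_point": t,
                "n_significant": summ.n_significant,
            }
            for (g, s, t), summ in self.summaries.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Correlation-network bootstrap (B={self.config.n_iterations})"]
        tbl = self.counts_table()
        for _, row in tbl.iterrows():
            lines.append(
                f"  {row['time_point']} {row['stratum']:<10s} {row['group']:<5s} "
                f"significant pairs {row['n_significant']:6d}"
            )
        for _, row in self.tests.iterrows():
            mark = "*" if row["significant"] else " "
            lines.append(
                f"  test {row['time_point']} {row['stratum']:<10s} "
                f"{row['group']:<5s} vs UE : p = {row['p']:.4f}{mark}"
            )
        return "\n".join(lines)


class CorrelationNetwork:
    """Model object: co-secretion network analysis over chosen cells.

    For every requested (time point, sex stratum), computes the sample
    correlation summary for each exposure group, bootstraps the count
    distributions, and tests HEa and HEua against the UE reference.
    """

    def __init__(
        self,
        expr: NormalizedExpression,
        meta: pd.DataFrame,
        config: Optional[BootstrapConfig] = None,
        time_points: Sequence[str] = ("T2", "T3"),
        sexes: Sequence[Optional[str]] = (None, "M", "F"),
    ) -> None:
        self.expr = expr
        self.meta = meta
        self.config = config or BootstrapConfig()
        self.time_points = time_points
        self.sexes = sexes

    def fit(self) -> CorrelationNetworkResults:
        summaries: Dict[Tuple[str, str, str], CorrelationSummary] = {}
        dists: Dict[Tuple[str, str, str], CountDistribution] = {}
        test_rows = []
        for tp in self.time_points:
            for sex in self.sexes:
                stratum = {None: "aggregated", "M": "male", "F": "female"}[sex]
                for g in ("UE", "HEua", "HEa"):
                    mask = (self.meta["group"] == g) & (
                        self.meta["time_point"] == tp
                    )
                    if sex is not None:
                        mask &= self.meta["sex"] == sex
                    rows = self.meta.index[mask]
                    summaries[(g, stratum, tp)] = pearson_matrix(
                        self.expr.dct.loc[rows], alpha=self.config.alpha
                    )
                    dists[(g, stratum, tp)] = bootstrap_correlation_counts(
                        self.expr, self.meta, self.config, g, tp, sex
                    )
                for g in ("HEua", "HEa"):
                    p = correlation_count_test(
                        dists[(g, stratum, tp)], dists[("UE", stratum, tp)]
                    )
                    test_rows.append(
                        {
                            "group": g,
                            "stratum": stratum,
                            "time_point": tp,
                            "p": p,
                            "significant": p < 0.05,
                        }
                    )
        return CorrelationNetworkResults(
            summaries, dists, pd.DataFrame(test_rows), self.config
        )
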