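"""Hedges' g effect sizes with bootstrap percentile confidence intervals.

Each exposed group (HEa or HEua) is compared to the unexposed reference
(UE): both groups are resampled with replacement at their own sizes for
B iterations, Hedges' g (small-sample corrected standardized mean
difference) is computed per iteration, and the estimate is the median
with the 2.5/97.5 bootstrap percentiles as the 95% CI.

Sign convention: g is computed on normalized delta-Ct, so a positive g
means a higher delta-Ct — i.e. *lower* abundance — in the first
(exposed) group relative to the reference.  Baseline fetal-sex
dimorphism is assessed the same way inside the UE group, comparing
male-fetus to female-fetus pregnancies (negative median = lower
delta-Ct = more abundant in mothers of males).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import NormalizedExpression
from .resampling import BootstrapConfig, resample_index_matrix


def hedges_correction(n_total: int) -> float:
    """Small-sample bias correction J = 1 - 3 / (4 N - 9)."""
    return 1.0 - 3.0 / (4.0 * n_total - 9.0)


def hedges_g(x: Sequence[float], y: Sequence[float]) -> float:
    """Hedges' g of x versus y (x the exposed group, y the reference).

    g = J * (mean(x) - mean(y)) / s_p with the pooled SD
    s_p = sqrt(((n_x - 1) s_x^2 + (n_y - 1) s_y^2) / (n_x + n_y - 2)).
    Zero pooled SD with equal means gives g = 0; with unequal means it
    is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need >= 2 observations per group")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0
        raise ValueError("zero pooled SD with unequal means")
    return float(hedges_correction(nx + ny) * diff / np.sqrt(sp2))


def _bootstrap_g_matrix(
    x: np.ndarray,
    y: np.ndarray,
    idx_x: np.ndarray,
    idx_y: np.ndarray,
    chunk: int = 512,
) -> np.ndarray:
    """Hedges' g per (iteration, miRNA); zero-pooled-SD draws give g = 0."""
    nx, ny = x.shape[0], y.shape[0]
    j = hedges_correction(nx + ny)
    b_total = idx_x.shape[0]
    out = np.empty((b_total, x.shape[1]))
    for start in range(0, b_total, chunk):
        sl = slice(start, min(start + chunk, b_total))
        rx = x[idx_x[sl]]  # (b, nx, m)
        ry = y[idx_y[sl]]
        mx = rx.mean(axis=1)
        my = ry.mean(axis=1)
        vx = rx.var(axis=1, ddof=1)
        vy = ry.var(axis=1, ddof=1)
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = j * (mx - my) / np.sqrt(sp2)
        out[sl] = np.where(sp2 <= 0.0, 0.0, g)
    return out


def _estimate_frame(
    gmat: np.ndarray, mirna_ids: Sequence[str], comparison: str, stratum: str, b: int
) -> pd.DataFrame:
    lo, med, hi = np.percentile(gmat, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame(
        {
            "mirna_id": list(mirna_ids),
            "comparison": comparison,
            "stratum": stratum,
            "median_g": med,
            "ci_low": lo,
            "ci_high": hi,
            "n_iterations": b,
        }
    )


def _rows_for(meta: pd.DataFrame, group: str, time_point: str, sex: Optional[str]):
    mask = (meta["group"] == group) & (meta["time_point"] == time_point)
    if sex is not None:
        mask &= meta["sex"] == sex
    return meta.index[mask]


def bootstrap_effect_size(
    expr: NormalizedExpression,
    meta: pd.DataFrame,
    config: BootstrapConfig,
    comparison: Tuple[str, str] = ("HEa", "UE"),
    stratum: str = "aggregated",
    time_point: str = "T2",
) -> pd.DataFrame:
    """Median Hedges' g and 95% percentile CI per miRNA.

    ``comparison`` is (exposed group, reference group); ``stratum`` one
    of aggregated/male/female.
    """
    sex = {"aggregated": None, "male": "M", "female": "F"}[stratum]
    exp_group, ref_group = comparison
    rows_x = _rows_for(meta, exp_group, time_point, sex)
    rows_y = _rows_for(meta, ref_group, time_point, sex)
    if len(rows_x) < 2 or len(rows_y) < 2:
        raise ValueError(
            f"stratum ({time_point}, {stratum}) needs >= 2 samples per group"
        )
    x = expr.dct.loc[rows_x].to_numpy(dtype=float)
    y = expr.dct.loc[rows_y].to_numpy(dtype=float)
    tag = f"{time_point}/{stratum}/{exp_group}-vs-{ref_group}"
    idx_x = resample_index_matrix(
        len(rows_x), config.n_iterations, config.seed, "effect", tag + "/x"
    )
    idx_y = resample_index_matrix(
        len(rows_y), config.n_iterations, config.seed, "effect", tag + "/y"
    )
    gmat = _bootstrap_g_matrix(x, y, idx_x, idx_y)
    label = f"{exp_group} vs {ref_group}"
    return _estimate_frame(gmat, expr.mirna_ids, label, stratum, config.n_iterations)


def classify_significant_effect(ci_low: float, ci_high: float) -> bool:
    """True iff the 95% CI excludes zero (endpoints touching zero fail)."""
    return bool(ci_low > 0.0 or ci_high < 0.0)


def classify_outside_composite(
    sex_median: float, composite_ci_low: float, composite_ci_high: float
) -> bool:
    """True iff a sex-stratified median falls strictly outside the
    composite sample's 95% CI."""
    return bool(sex_median < composite_ci_low or sex_median > composite_ci_high)


def baseline_dimorphism(
    expr: NormalizedExpression,
    meta: pd.DataFrame,
    config: BootstrapConfig,
    time_point: str = "T2",
    group: str = "UE",
) -> pd.DataFrame:
    """Fetal-sex effect at baseline: bootstrap g of male minus female
    within the unexposed group.

    Returns the per-miRNA estimates with ``significant`` (CI excludes
    zero) and ``direction`` (+1 higher delta-Ct in males = less
    abundant, -1 more abundant) columns.
    """
    rows_m = _rows_for(meta, group, time_point, "M")
    rows_f = _rows_for(meta, group, time_point, "F")
    if len(rows_m) < 2 or len(rows_f) < 2:
        raise ValueError(f"{group} needs >= 2 samples of each sex at {time_point}")
    x = expr.dct.loc[rows_m].to_numpy(dtype=float)
    y = expr.dct.loc[rows_f].to_numpy(dtype=float)
    tag = f"{time_point}/baseline/{group}"
    idx_x = resample_index_matrix(
        len(rows_m), config.n_iterations, config.seed, "effect", tag + "/M"
    )
    idx_y = resample_index_matrix(
        len(rows_f), config.n_iterations, config.seed, "effect", tag + "/F"
    )
    gmat = _bootstrap_g_matrix(x, y, idx_x, idx_y)
    est = _estimate_frame(
        gmat, expr.mirna_ids, f"{group}-M vs {group}-F", "baseline", config.n_iterations
    )
    est["significant"] = [
        classify_significant_effect(lo, hi)
        for lo, hi in zip(est["ci_low"], est["ci_high"])
    ]
    est["direction"] = np.sign(est["median_g"]).astype(int)
    return est


# ---------------------------------------------------------------------------
# model / results facade


@dataclass
class EffectSizeResults:
    """Composite + sex-stratified bootstrap effect sizes for one comparison."""

    estimates: pd.DataFrame  # stacked composite/male/female rows
    baseline: Optional[pd.DataFrame]
    config: BootstrapConfig
    comparison: Tuple[str, str]
    time_point: str

    def stratum(self, name: str) -> pd.DataFrame:
        return (
            self.estimates[self.estimates["stratum"] == name]
            .set_index("mirna_id")
            .copy()
        )

    def significant(self, stratum: str) -> pd.DataFrame:
        sub = self.stratum(stratum)
        keep = [
            classify_significant_effect(lo, hi)
            for lo, hi in zip(sub["ci_low"], sub["ci_high"])
        ]
        return sub[keep]

    def sex_specific(self, sex_stratum: str) -> pd.DataFrame:
        """miRNAs significant in a sex stratum but not in the composite."""
        comp = self.stratum("aggregated")
        sub = self.significant(sex_stratum)
        comp_sig = {
            mid
            for mid, lo, hi in zip(comp.index, comp["ci_low"], comp["ci_high"])
            if classify_significant_effect(lo, hi)
        }
        return sub[~sub.index.isin(comp_sig)]

    def outside_composite(self, sex_stratum: str) -> pd.DataFrame:
        comp = self.stratum("aggregated")
        sub = self.stratum(sex_stratum)
        keep = [
            classify_outside_composite(
                med, comp.loc[mid, "ci_low"], comp.loc[mid, "ci_high"]
            )
            for mid, med in zip(sub.index, sub["median_g"])
        ]
        return sub[keep]

    def tally(self) -> Dict[str, object]:
        """Counts of sex-specific significant miRNAs, with the overlap
        against baseline sexual dimorphism in brackets."""
        base_ids = (
            set(self.baseline[self.baseline["significant"]]["mirna_id"])
            if self.baseline is not None
            else set()
        )
        out: Dict[str, object] = {"baseline_dimorphic": len(base_ids)}
        for stratum in ("male", "female"):
            ids = set(self.sex_specific(stratum).index)
            out[stratum] = {
                "n": len(ids),
                "overlap_with_baseline": len(ids & base_ids),
            }
        return out

    def summary(self) -> str:
        exp, ref = self.comparison
        lines = [
            f"Effect-size bootstrap ({exp} vs {ref}, {self.time_point}, "
            f"B={self.config.n_iterations})"
        ]
        for stratum in ("aggregated", "male", "female"):
            sub = self.stratum(stratum)
            n_sig = len(self.significant(stratum))
            lines.append(
                f"  {stratum:<10s} median |g| {sub['median_g'].abs().median():.3f}  "
                f"significant {n_sig:4d}"
            )
        t = self.tally()
        lines.append(
            f"  sex-specific: male {t['male']['n']} "
            f"({t['male']['overlap_with_baseline']}), "
            f"female {t['female']['n']} "
            f"({t['female']['overlap_with_baseline']}); "
            f"baseline dimorphic {t['baseline_dimorphic']}"
        )
        return "\n".join(lines)


class EffectSizeBootstrap:
    """Model object: bootstrap Hedges' g for one exposed-vs-UE comparison.

    ``fit()`` runs independent bootstrap streams for the composite and
    each sex stratum, plus (optionally) the UE baseline sex comparison.
    """

    def __init__(
        self,
        expr: NormalizedExpression,
        meta: pd.DataFrame,
        comparison: Tuple[str, str] = ("HEa", "UE"),
        time_point: str = "T2",
        config: Optional[BootstrapConfig] = None,
        with_baseline: bool = True,
    ) -> None:
        self.expr = expr
        self.meta = meta
        self.comparison = comparison
        self.time_point = time_point
        self.config = config or BootstrapConfig()
        self.with_baseline = with_baseline

    def fit(self) -> EffectSizeResults:
        frames = [
            bootstrap_effect_size(
                self.expr,
                self.meta,
                self.config,
                comparison=self.comparison,
                stratum=stratum,
                time_point=self.time_point,
            )
            for stratum in ("aggregated", "male", "female")
        ]
        base = (
            baseline_dimorphism(
                self.expr, self.meta, self.config, time_point=self.time_point
            )
            if self.with_baseline
            else None
        )
        return EffectSizeResults(
            pd.concat(frames, ignore_index=True),
            base,
            self.config,
            self.comparison,
            self.time_point,
        )
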