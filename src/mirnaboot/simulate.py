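"""Synthetic qPCR cohort generator.

Emulates the statistical structure of a maternal-plasma miRNA qPCR study
of prenatal alcohol exposure: three exposure groups (UE unexposed, HEua
heavily exposed/unaffected infant, HEa heavily exposed/affected infant),
fetal sex, two gestational time points (T2 mid-pregnancy, T3 late
pregnancy), per-sample global Ct offsets, gestational-age covariate
effects, detection dropout, optional planted group/sex mean shifts
(ground truth for effect-size recovery), and an optional latent
co-secretion factor that induces a dense block of cross-correlated
miRNAs in chosen (group, sex, time point) strata.

Cohort sizes default to the study layout:

====== ==== ===== ====
stratum  UE  HEua  HEa
====== ==== ===== ====
T2 M     17     7   11
T2 F      8    12   13
T3 M     22     9   16
T3 F     14    14   18
====== ==== ===== ====

Undetected wells are generated as missing-with-flag; the Ct = 45
substitution is deliberately left to preprocessing so generation and
imputation stay separable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import (
    CHROMOSOMES,
    CtMatrix,
    validate_annotation,
)
from .resampling import stream_rng

# Study-layout sample counts per (time_point, group, sex)
DEFAULT_GROUP_SIZES: Dict[Tuple[str, str, str], int] = {
    ("T2", "UE", "M"): 17,
    ("T2", "UE", "F"): 8,
    ("T2", "HEua", "M"): 7,
    ("T2", "HEua", "F"): 12,
    ("T2", "HEa", "M"): 11,
    ("T2", "HEa", "F"): 13,
    ("T3", "UE", "M"): 22,
    ("T3", "UE", "F"): 14,
    ("T3", "HEua", "M"): 9,
    ("T3", "HEua", "F"): 14,
    ("T3", "HEa", "M"): 16,
    ("T3", "HEa", "F"): 18,
}

# Rough human mature-miRNA chromosomal distribution (X intentionally
# well-populated; clusters on 14 and 19 give those autosomes weight).
DEFAULT_CHROM_WEIGHTS: Dict[str, float] = {
    "1": 0.08, "2": 0.05, "3": 0.05, "4": 0.04, "5": 0.05, "6": 0.04,
    "7": 0.05, "8": 0.05, "9": 0.04, "10": 0.03, "11": 0.05, "12": 0.04,
    "13": 0.02, "14": 0.06, "15": 0.03, "16": 0.04, "17": 0.05, "18": 0.01,
    "19": 0.07, "20": 0.03, "21": 0.01, "22": 0.03, "X": 0.07, "Y": 0.01,
}

# Gestational age at blood draw (weeks): overall cohort mean +/- SD
DEFAULT_GA = ((18.88, 4.93), (33.08, 2.42))
GA_CLIP = (10.0, 42.0)


@dataclass
class PlantedEffect:
    """A ground-truth mean shift for one miRNA.

    ``shift`` is on the standardized (Hedges' g) scale and converted to
    Ct units via ``noise_sd``; it is added to the target group (and sex,
    unless 'both') in every time point unless ``time_point`` is set.
    """

    mirna_index: int
    target_group: str = "HEa"
    target_sex: str = "both"  # M, F or both
    shift: float = 1.0
    time_point: Optional[str] = None

    def __post_init__(self) -> None:
        if self.target_group not in ("HEa", "HEua"):
            raise ValueError("target_group must be HEa or HEua")
        if self.target_sex not in ("M", "F", "both"):
            raise ValueError("target_sex must be M, F or both")
        if not np.isfinite(self.shift):
            raise ValueError("shift must be finite")


@dataclass
class CoSecretionSpec:
    """A single latent Gaussian factor shared by a block of miRNAs.

    In each active stratum, member miRNA values are generated as
    ``loading * F + sqrt(1 - loading^2) * eps`` (times ``noise_sd``),
    with F ~ N(0,1) per sample, so any two members correlate at
    ``loading**2``.  ``active_strata`` maps (group, sex, time_point) ->
    loading, allowing e.g. an attenuated ("half-variance") block.
    A configurable fraction of members is annotated to chromosome X and
    the rest to ``partner_chromosomes``.
    """

    member_indices: Tuple[int, ...]
    active_strata: Dict[Tuple[str, str, str], float]
    baseline_loading: float = 0.45
    member_background: float = 0.35
    fraction_x: float = 0.5
    partner_chromosomes: Tuple[str, ...] = ("6", "21")

    def __post_init__(self) -> None:
        if len(self.member_indices) == 0:
            raise ValueError("co-secretion member set is empty")
        for loading in (*self.active_strata.values(), self.baseline_loading):
            if not 0.0 <= loading < 1.0:
                raise ValueError("loading must be in [0, 1)")
            if loading**2 + self.member_background**2 >= 1.0:
                raise ValueError(
                    "factor + member background loadings exceed unit variance"
                )

    def loading_for(self, group: str, sex: str, time_point: str) -> float:
        return self.active_strata.get((group, sex, time_point), self.baseline_loading)


#: study-pattern loadings, calibrated against the published per-cell
#: significant-pair counts: the block is hyper-coordinated in HEa-F at
#: both time points, intermediately in HEua-F at mid-pregnancy and
#: HEa-M at late pregnancy, and sits at the baseline loading elsewhere
FULL_LOADING = 0.92
INTERMEDIATE_LOADING = 0.86
DEFAULT_ACTIVE_STRATA: Dict[Tuple[str, str, str], float] = {
    ("HEa", "F", "T2"): FULL_LOADING,
    ("HEa", "F", "T3"): FULL_LOADING,
    ("HEua", "F", "T2"): INTERMEDIATE_LOADING,
    ("HEa", "M", "T3"): 0.84,
}


@dataclass
class SimConfig:
    """Full description of one synthetic cohort.

    Defaults are the study conditions: cohort layout above, base Ct ~
    U(22, 35), technical per-sample shift SD 1.0 Ct, residual noise SD
    1.5 Ct, detection dropout 0.05 for 75% of a 200-assay candidate
    panel and 0.60 for the remaining 25% (so the 80% expression filter
    retains roughly 150 assays), GA draws from N(18.88, 4.93) and
    N(33.08, 2.42) weeks clipped to [10, 42].
    """

    group_sizes: Dict[Tuple[str, str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_mirnas: int = 200
    chrom_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_WEIGHTS)
    )
    base_ct_range: Tuple[float, float] = (22.0, 35.0)
    sample_shift_sd: float = 1.0
    noise_sd: float = 1.5
    detect_dropout: object = None  # scalar, sequence of len n_mirnas, or None
    high_dropout: float = 0.60
    low_dropout: float = 0.05
    high_dropout_fraction: float = 0.25
    planted_effects: List[PlantedEffect] = field(default_factory=list)
    cosecretion: Optional[CoSecretionSpec] = None
    ga_means_sds: Tuple[Tuple[float, float], Tuple[float, float]] = DEFAULT_GA
    ga_slopes: Dict[int, float] = field(default_factory=dict)
    background_loading: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        w = np.array(list(self.chrom_weights.values()), dtype=float)
        if (w < 0).any() or (w > 1).any() or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("chrom_weights must be probabilities summing to 1")
        for eff in self.planted_effects:
            if not 0 <= eff.mirna_index < self.n_mirnas:
                raise ValueError("planted effect index outside panel")
        if not 0.0 <= self.background_loading < 1.0:
            raise ValueError("background_loading must be in [0, 1)")
        if self.cosecretion is not None:
            if max(self.cosecretion.member_indices) >= self.n_mirnas:
                raise ValueError("co-secretion member index outside panel")

    def dropout_vector(self) -> np.ndarray:
        """Per-miRNA probability of non-detection.

        Ground-truth columns (planted effects, co-secretion members) are
        generated fully detected: an imputed Ct = 45 sentinel is a >10 SD
        outlier that would change the realized effect size away from the
        planted one, and the planted values are the recovery targets.
        """
        if self.detect_dropout is None:
            n_high = int(round(self.high_dropout_fraction * self.n_mirnas))
            vec = np.full(self.n_mirnas, self.low_dropout)
            if n_high:
                vec[-n_high:] = self.high_dropout
            for eff in self.planted_effects:
                vec[eff.mirna_index] = 0.0
            if self.cosecretion is not None:
                vec[list(self.cosecretion.member_indices)] = 0.0
            return vec
        vec = np.asarray(self.detect_dropout, dtype=float)
        if vec.ndim == 0:
            vec = np.full(self.n_mirnas, float(vec))
        if vec.shape != (self.n_mirnas,):
            raise ValueError("detect_dropout length must equal n_mirnas")
        if ((vec < 0) | (vec > 1)).any():
            raise ValueError("dropout probabilities must be in [0, 1]")
        return vec

    def to_json(self) -> str:
        d = asdict(self)
        d["group_sizes"] = {"|".join(k): v for k, v in self.group_sizes.items()}
        if self.cosecretion is not None:
            d["cosecretion"]["active_strata"] = {
                "|".join(k): v for k, v in self.cosecretion.active_strata.items()
            }
        d["ga_slopes"] = {str(k): v for k, v in self.ga_slopes.items()}
        return json.dumps(d, indent=2, default=list)


# ---------------------------------------------------------------------------


def simulate_annotation(config: SimConfig) -> pd.DataFrame:
    """Synthetic miRNA annotation table (accession, name, chromosome).

    Chromosomes are drawn from ``config.chrom_weights``; co-secretion
    members (if any) are re-annotated so ``fraction_x`` of them sit on X
    and the rest cycle through the partner chromosomes, giving the
    chromosome-pair analysis a recoverable ground truth.
    """
    rng = stream_rng(config.seed, "simulate", 1)
    labels = list(config.chrom_weights)
    probs = np.array([config.chrom_weights[c] for c in labels], dtype=float)
    chrom = rng.choice(labels, size=config.n_mirnas, p=probs)
    if config.cosecretion is not None:
        spec = config.cosecretion
        members = list(spec.member_indices)
        n_x = int(round(spec.fraction_x * len(members)))
        for j, idx in enumerate(members):
            if j < n_x:
                chrom[idx] = "X"
            else:
                chrom[idx] = spec.partner_chromosomes[
                    (j - n_x) % len(spec.partner_chromosomes)
                ]
    annot = pd.DataFrame(
        {
            "mirna_id": [f"MIMAT{5000000 + i:07d}" for i in range(config.n_mirnas)],
            "name": [f"syn-miR-{i:03d}" for i in range(config.n_mirnas)],
            "chromosome": chrom.astype(str),
        }
    )
    return validate_annotation(annot)


def _metadata(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    counter = 0
    (ga1_mu, ga1_sd), (ga2_mu, ga2_sd) = config.ga_means_sds
    for (tp, group, sex), n in sorted(config.group_sizes.items()):
        for _ in range(n):
            counter += 1
            rows.append(
                {
                    "sample_id": f"S{counter:04d}",
                    "subject_id": f"P{counter:04d}",
                    "group": group,
                    "sex": sex,
                    "time_point": tp,
                    "GA_bd1": np.clip(rng.normal(ga1_mu, ga1_sd), *GA_CLIP),
                    "GA_bd2": np.clip(rng.normal(ga2_mu, ga2_sd), *GA_CLIP),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_cohort(
    config: SimConfig,
) -> Tuple[CtMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate (CtMatrix, sample metadata, annotation) for one cohort.

    Ct_ij = base_i + sample_shift_j + ga_slope_i * (GA_j - GA_mean)
            + planted group/sex shift + latent-factor contribution
            + N(0, noise_sd),
    with wells knocked out (flag False, Ct missing) at the per-miRNA
    dropout probability.  Fully deterministic given ``config`` (seed
    included).
    """
    rng = stream_rng(config.seed, "simulate", 2)
    meta = _metadata(config, rng)
    n_samples = len(meta)
    m = config.n_mirnas
    if n_samples == 0:
        raise ValueError("group_sizes request zero samples")

    base = rng.uniform(*config.base_ct_range, size=m)
    sample_shift = rng.normal(0.0, config.sample_shift_sd, size=n_samples)

    values = base[None, :] + sample_shift[:, None]

    # GA covariate effects, centred so they do not move group means
    if config.ga_slopes:
        ga1 = meta["GA_bd1"].to_numpy()
        ga2 = meta["GA_bd2"].to_numpy()
        is_t2 = (meta["time_point"] == "T2").to_numpy()
        ga = np.where(is_t2, ga1, ga2)
        (ga1_mu, _), (ga2_mu, _) = config.ga_means_sds
        ga_centered = ga - np.where(is_t2, ga1_mu, ga2_mu)
        for idx, slope in config.ga_slopes.items():
            values[:, idx] += slope * ga_centered

    # planted mean shifts (Hedges'-g scale -> Ct via noise_sd)
    group = meta["group"].to_numpy()
    sex = meta["sex"].to_numpy()
    tp = meta["time_point"].to_numpy()
    for eff in config.planted_effects:
        mask = group == eff.target_group
        if eff.target_sex != "both":
            mask &= sex == eff.target_sex
        if eff.time_point is not None:
            mask &= tp == eff.time_point
        values[mask, eff.mirna_index] += eff.shift * config.noise_sd

    # Residual structure (all columns unit variance before noise_sd
    # scaling):
    #   non-member:  l_i * G_j + sqrt(1 - l_i^2) * eps,
    #     with l_i = +/- background_loading (random sign) — circulating
    #     miRNA panels are broadly cross-correlated even in unexposed
    #     pregnancies, with correlations of either sign;
    #   member:      lam_s * F_j + d_i * G_j
    #                + sqrt(1 - lam_s^2 - d_i^2) * eps,
    #     with d_i = +/- member_background and lam_s the co-secretion
    #     factor loading of the sample's stratum (baseline everywhere,
    #     elevated in active strata);
    #   planted-effect columns: pure eps, so the realized Hedges' g is
    #     exactly the planted one.
    eps = rng.normal(0.0, 1.0, size=(n_samples, m))
    noise = eps
    if config.background_loading > 0 or config.cosecretion is not None:
        signs = rng.choice([-1.0, 1.0], size=m)
        loadings = signs * config.background_loading
        loadings[[e.mirna_index for e in config.planted_effects]] = 0.0
        g_factor = rng.normal(0.0, 1.0, size=n_samples)
        f_factor = rng.normal(0.0, 1.0, size=n_samples)
        lam = np.zeros((n_samples, m))
        if config.cosecretion is not None:
            spec = config.cosecretion
            members = np.array(spec.member_indices, dtype=int)
            loadings[members] = signs[members] * spec.member_background
            stratum_lam = np.array(
                [spec.loading_for(g, s, t) for g, s, t in zip(group, sex, tp)]
            )
            lam[:, members] = stratum_lam[:, None]
        resid = np.sqrt(1.0 - lam**2 - loadings[None, :] ** 2)
        noise = (
            lam * f_factor[:, None]
            + g_factor[:, None] * loadings[None, :]
            + resid * eps
        )
    values = values + config.noise_sd * noise

    dropout = config.dropout_vector()
    detected = rng.random((n_samples, m)) >= dropout[None, :]

    annot = simulate_annotation(config)
    ct = pd.DataFrame(values, index=meta.index, columns=annot["mirna_id"].to_numpy())
    ct = ct.where(pd.DataFrame(detected, index=ct.index, columns=ct.columns))
    det = pd.DataFrame(detected, index=ct.index, columns=ct.columns)
    return CtMatrix(ct, det), meta, annot


def truth_tables(config: SimConfig) -> Dict[str, object]:
    """Ground-truth description (planted effects, factor membership)."""
    annot = simulate_annotation(config)
    ids = annot["mirna_id"].to_list()
    truth: Dict[str, object] = {
        "planted_effects": [
            {
                "mirna_id": ids[e.mirna_index],
                "target_group": e.target_group,
                "target_sex": e.target_sex,
                "shift": e.shift,
                "time_point": e.time_point,
            }
            for e in config.planted_effects
        ]
    }
    if config.cosecretion is not None:
        spec = config.cosecretion
        truth["cosecretion"] = {
            "members": [ids[i] for i in spec.member_indices],
            "active_strata": {
                "|".join(k): v for k, v in spec.active_strata.items()
            },
        }
    return truth


# ---------------------------------------------------------------------------
# Scenario factories (the conditions exercised by the recovery analyses)


def null_config(seed: int = 0, **kw) -> SimConfig:
    """Cohort with no planted structure at all."""
    return SimConfig(seed=seed, **kw)


def sex_effect_config(
    seed: int = 0,
    n_effects: int = 10,
    shift: float = 1.5,
    target_group: str = "HEa",
    **kw,
) -> SimConfig:
    """Cohort with ``n_effects`` one-sex mean shifts in ``target_group``.

    Effects alternate male/female and are placed on the low-dropout part
    of the panel so they survive the expression filter.  The scenario is
    a mean-shift recovery design, so the panel is generated with
    independent residuals (no background co-regulation) unless
    overridden.
    """
    effects = [
        PlantedEffect(
            mirna_index=i,
            target_group=target_group,
            target_sex="M" if i % 2 == 0 else "F",
            shift=shift,
        )
        for i in range(n_effects)
    ]
    kw.setdefault("background_loading", 0.0)
    return SimConfig(seed=seed, planted_effects=effects, **kw)


def cosecretion_config(
    seed: int = 0,
    n_members: int = 70,
    active_strata: Optional[Dict[Tuple[str, str, str], float]] = None,
    **kw,
) -> SimConfig:
    """Cohort with the latent co-secretion factor in the study pattern."""
    spec = CoSecretionSpec(
        member_indices=tuple(range(n_members)),
        active_strata=dict(
            DEFAULT_ACTIVE_STRATA if active_strata is None else active_strata
        ),
    )
    return SimConfig(seed=seed, cosecretion=spec, **kw)
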