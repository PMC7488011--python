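"""End-to-end pipeline: preprocess -> stability -> effect size ->
correlation network -> chromosome enrichment -> cohort table.

Configuration lives in a YAML/JSON mapping (see :class:`PipelineConfig`).
All outputs are plain TSV/JSON with pinned float formatting, so two runs
with the same config are byte-identical; a manifest records the seed,
config hash and every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .containers import (
    TIME_POINTS,
    read_annotation,
    read_ct_matrix,
    read_meta,
    write_expression,
)
from .chromosomes import chromosome_enrichment
from .cohort import DEMOGRAPHIC_TABLES, fisher_exact_rxc, write_fixture_tables
from .corrnet import CorrelationNetwork
from .effects import EffectSizeBootstrap
from .preprocess import filter_expressed, global_mean_normalize, impute_undetected
from .resampling import BootstrapConfig
from .stability import StabilityBootstrap

log = logging.getLogger("mirnaboot")

KNOWN_ANALYSES = ("preprocess", "anova", "ancova", "effect", "corr", "chrom", "cohort")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Paths, bootstrap settings and the list of analyses to run."""

    ct_path: str
    detection_path: str
    metadata_path: str
    annotation_path: Optional[str] = None
    output_dir: str = "out"
    analyses: Sequence[str] = KNOWN_ANALYSES
    n_iterations: int = 2000
    alpha: float = 0.05
    seed: int = 0
    threshold: float = 0.80
    per_group_filter: bool = False
    time_points: Sequence[str] = TIME_POINTS
    covariates: str = "auto"
    top_k: int = 10
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - set(KNOWN_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def bootstrap(self) -> BootstrapConfig:
        return BootstrapConfig(
            n_iterations=self.n_iterations, alpha=self.alpha, seed=self.seed
        )

    def canonical_json(self) -> str:
        d = {k: (list(v) if isinstance(v, (tuple, list)) else v) for k, v in vars(self).items()}
        return json.dumps(d, sort_keys=True)


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False, **kw) -> Path:
    frame.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT, **kw)
    return path


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the requested stages and return the manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    boot = config.bootstrap()

    for p in (config.ct_path, config.detection_path, config.metadata_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")

    mat = read_ct_matrix(config.ct_path, config.detection_path)
    meta = read_meta(config.metadata_path)
    log.info("loaded %d samples x %d assays", *mat.ct.shape)

    per_group = meta["group"] if config.per_group_filter else None
    retained = filter_expressed(mat, threshold=config.threshold, per_group=per_group)
    if not retained:
        raise ValueError("preprocess: no assay passed the expression filter")
    expr = global_mean_normalize(impute_undetected(mat), retained)
    log.info("retained %d of %d assays", len(retained), mat.ct.shape[1])

    want = set(config.analyses)
    if "preprocess" in want:
        path = out / "retained_assays.txt"
        path.write_text("\n".join(retained) + "\n")
        written.append(path)
        written.append(out / "normalized_dct.tsv")
        write_expression(expr, out / "normalized_dct.tsv")

    edges: Dict[Tuple[str, str, str], pd.DataFrame] = {}

    for tp in config.time_points:
        if want & {"anova", "ancova"}:
            for model in ("anova", "ancova"):
                if model not in want:
                    continue
                res = StabilityBootstrap(
                    expr, meta, tp, boot, model=model, covariates=config.covariates
                ).fit()
                written.append(
                    _write_tsv(res.profiles, out / f"stability_{model}_{tp}.tsv")
                )
                written.append(
                    _write_tsv(res.labels, out / f"sex_specific_{model}_{tp}.tsv")
                )
                log.info("%s %s:\n%s", model, tp, res.summary())

        if "effect" in want:
            for exposed in ("HEa", "HEua"):
                res = EffectSizeBootstrap(
                    expr, meta, (exposed, "UE"), tp, boot,
                    with_baseline=(exposed == "HEa"),
                ).fit()
                est = res.estimates.copy()
                comp = res.stratum("aggregated")
                est["significant"] = (est["ci_low"] > 0) | (est["ci_high"] < 0)
                est["outside_composite"] = [
                    (m < comp.loc[mid, "ci_low"]) or (m > comp.loc[mid, "ci_high"])
                    for mid, m in zip(est["mirna_id"], est["median_g"])
                ]
                written.append(
                    _write_tsv(est, out / f"effect_{exposed}_vs_UE_{tp}.tsv")
                )
                tally_path = out / f"effect_tally_{exposed}_vs_UE_{tp}.json"
                tally_path.write_text(json.dumps(res.tally(), indent=2, sort_keys=True))
                written.append(tally_path)
                if res.baseline is not None:
                    written.append(
                        _write_tsv(res.baseline, out / f"baseline_dimorphism_{tp}.tsv")
                    )

    if "corr" in want:
        net = CorrelationNetwork(
            expr, meta, boot, time_points=config.time_points
        ).fit()
        written.append(_write_tsv(net.counts_table(), out / "correlation_counts.tsv"))
        written.append(_write_tsv(net.tests, out / "correlation_tests.tsv"))
        dist_rows = []
        for (g, s, tp), dist in net.distributions.items():
            for i, c in enumerate(dist.counts):
                dist_rows.append(
                    {"group": g, "stratum": s, "time_point": tp,
                     "iteration": i, "count": int(c)}
                )
        written.append(
            _write_tsv(pd.DataFrame(dist_rows), out / "correlation_count_distributions.tsv")
        )
        for (g, s, tp), summ in net.summaries.items():
            edges[(g, s, tp)] = summ.edges()
            written.append(
                _write_tsv(edges[(g, s, tp)], out / f"edges_{g}_{s}_{tp}.tsv")
            )
        log.info("correlation network:\n%s", net.summary())

    if "chrom" in want:
        if config.annotation_path is None or not Path(config.annotation_path).exists():
            raise FileNotFoundError(
                "chromosome analysis requested but annotation file missing: "
                f"{config.annotation_path}"
            )
        annot = read_annotation(config.annotation_path)
        if not edges:
            raise ValueError("chromosome analysis requires the 'corr' stage")
        for (g, s, tp), edge in edges.items():
            if g == "UE":
                continue
            control = edges[("UE", s, tp)]
            try:
                ranked = chromosome_enrichment(
                    edge, control, annot, k=config.top_k
                )
            except ValueError:
                continue  # no defined enrichment in this cell
            written.append(
                _write_tsv(ranked, out / f"chrom_enrichment_{g}_vs_UE_{s}_{tp}.tsv")
            )

    if "cohort" in want:
        fixdir = out / "demographics"
        write_fixture_tables(fixdir)
        written.extend(sorted(fixdir.glob("*.tsv")))
        stats_rows = []
        for name, tab in DEMOGRAPHIC_TABLES.items():
            res = fisher_exact_rxc(tab.to_numpy(), seed=config.seed)
            stats_rows.append(
                {"variable": name, "p": res.p, "method": res.method}
            )
        path = out / "demographic_fisher.json"
        path.write_text(json.dumps(stats_rows, indent=2))
        written.append(path)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_iterations": config.n_iterations,
        "alpha": config.alpha,
        "config_sha256": hashlib.sha256(
            config.canonical_json().encode()
        ).hexdigest(),
        "outputs": sorted(str(p.relative_to(out)) for p in set(written)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
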