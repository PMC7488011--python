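"""Chromosome-pair enrichment of significant miRNA correlations.

Every significant miRNA pair is mapped to the unordered pair of
chromosomes its two members are encoded on (intra-chromosome pairs are
legal buckets), counts are compared between an alcohol-exposed group
and the unexposed control, and pairs are ranked by

    percent change = 100 * (count_exposed - count_control) / count_control,

undefined (and excluded from ranking) when the control count is zero.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .containers import validate_annotation

ChromPair = Tuple[str, str]


def _canonical(a: str, b: str) -> ChromPair:
    # order numerically then X, Y for stable labels
    def key(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    return (a, b) if key(a) <= key(b) else (b, a)


def map_pairs_to_chromosomes(
    edges: pd.DataFrame, annot: pd.DataFrame
) -> Dict[ChromPair, int]:
    """Count significant miRNA pairs per unordered chromosome pair.

    ``edges`` needs columns mirna_a / mirna_b; every endpoint must be
    annotated.  The result conserves the edge total: each edge lands in
    exactly one bucket.
    """
    annot = validate_annotation(annot)
    chrom_of = dict(zip(annot["mirna_id"], annot["chromosome"]))
    counts: Dict[ChromPair, int] = {}
    for a, b in zip(edges["mirna_a"], edges["mirna_b"]):
        try:
            pair = _canonical(chrom_of[a], chrom_of[b])
        except KeyError as err:
            raise KeyError(f"miRNA {err.args[0]!r} missing from annotation") from None
        counts[pair] = counts.get(pair, 0) + 1
    return counts


def percent_change(count_exposed: int, count_control: int) -> float:
    """100 * (exposed - control) / control; NaN sentinel if control = 0."""
    if count_control < 0 or count_exposed < 0:
        raise ValueError("counts must be >= 0")
    if count_control == 0:
        return float("nan")
    return 100.0 * (count_exposed - count_control) / count_control


def enrichment_table(
    exposed_counts: Dict[ChromPair, int],
    control_counts: Dict[ChromPair, int],
    min_control: int = 1,
) -> pd.DataFrame:
    """Per chromosome pair: exposed/control counts and percent change.

    Pairs whose control count is below ``min_control`` carry a NaN
    percent change and are excluded from ranking.
    """
    pairs = sorted(set(exposed_counts) | set(control_counts))
    rows = []
    for pair in pairs:
        ce = exposed_counts.get(pair, 0)
        cc = control_counts.get(pair, 0)
        pc = percent_change(ce, cc) if cc >= min_control else float("nan")
        rows.append(
            {
                "chrom_a": pair[0],
                "chrom_b": pair[1],
                "count_exposed": ce,
                "count_control": cc,
                "percent_change": pc,
            }
        )
    return pd.DataFrame(rows)


def top_pairs(enrichment: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k chromosome pairs by percent change (descending).

    Ties break by exposed count (descending) then lexicographic pair
    label, so the ranking is deterministic; undefined rows never rank.
    """
    defined = enrichment.dropna(subset=["percent_change"]).copy()
    if defined.empty:
        raise ValueError("no defined enrichment to rank")
    defined["_neg_ce"] = -defined["count_exposed"]
    ranked = defined.sort_values(
        by=["percent_change", "_neg_ce", "chrom_a", "chrom_b"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).drop(columns="_neg_ce")
    out = ranked.head(k).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def chromosome_enrichment(
    exposed_edges: pd.DataFrame,
    control_edges: pd.DataFrame,
    annot: pd.DataFrame,
    k: int = 10,
    min_control: int = 1,
) -> pd.DataFrame:
    """Edge lists to ranked enrichment in one call."""
    table = enrichment_table(
        map_pairs_to_chromosomes(exposed_edges, annot),
        map_pairs_to_chromosomes(control_edges, annot),
        min_control=min_control,
    )
    return top_pairs(table, k=k)
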