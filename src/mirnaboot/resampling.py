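"""Bootstrap resampling primitive and RNG policy shared by all analyses.

Every analysis resamples each stratum (exposure group, optionally further
split by fetal sex) with replacement, drawing exactly the stratum's own
sample size, and repeats for B iterations (default 2000).  Reproducibility
contract: the draw for a given ``(seed, stream, stratum, iteration)`` is
fixed regardless of evaluation order, chunking, or how many other strata
or analyses are run — each analysis pulls from a named child stream so
adding analyses never perturbs existing results.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

#: named child streams; one per analysis family
STREAMS = ("anova", "ancova", "effect", "corr", "calibration", "simulate")


def _tag(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def stream_rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    """Generator for a named child stream of the master seed.

    ``extra`` integers (iteration number, stratum index, ...) extend the
    entropy so distinct contexts get independent, order-free streams.
    """
    return np.random.default_rng([int(seed), _tag(stream), *map(int, extra)])


@dataclass
class BootstrapConfig:
    """Knobs of the resampling engine.

    n_iterations : number of bootstrap iterations B (study default 2000)
    alpha        : significance level for per-iteration tests
    seed         : master seed; all child streams derive from it
    strata       : "group" (aggregated) or "group_sex"
    """

    n_iterations: int = 2000
    alpha: float = 0.05
    seed: int = 0
    strata: str = "group"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.strata not in ("group", "group_sex"):
            raise ValueError("strata must be 'group' or 'group_sex'")


def resample_stratum(
    n: int, seed: int, stream: str, stratum: str, iteration: int
) -> np.ndarray:
    """One with-replacement draw of ``n`` positions for one stratum.

    The draw is a pure function of (seed, stream, stratum, iteration).
    """
    if n < 1:
        raise ValueError(f"empty stratum {stratum!r}")
    rng = stream_rng(seed, stream, _tag(stratum), iteration)
    return rng.integers(0, n, size=n)


def resample_index_matrix(
    n: int, n_iterations: int, seed: int, stream: str, stratum: str
) -> np.ndarray:
    """Stack of per-iteration draws, shape (B, n).

    Row ``i`` equals :func:`resample_stratum` for iteration ``i`` — the
    vectorised analyses and any per-iteration audit loop therefore see
    identical draws.
    """
    if n < 1:
        raise ValueError(f"empty stratum {stratum!r}")
    out = np.empty((n_iterations, n), dtype=np.intp)
    for i in range(n_iterations):
        out[i] = resample_stratum(n, seed, stream, stratum, i)
    return out


def resample_strata(
    sizes: Dict[str, int], config: BootstrapConfig, iteration: int, stream: str = "anova"
) -> Dict[str, np.ndarray]:
    """Per-stratum with-replacement draws for one iteration.

    ``sizes`` maps stratum label -> stratum sample size; each stratum is
    drawn independently at its own size.
    """
    return {
        label: resample_stratum(n, config.seed, stream, label, iteration)
        for label, n in sizes.items()
    }
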