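"""miRNA selection, sentinel imputation and global-mean normalization.

The pipeline mirrors standard qPCR panel practice: wells that never
amplified get the sentinel Ct of 45, assays detected in fewer than 80%
of samples are discarded, and each retained Ct is normalized to the
per-sample mean Ct over all retained assays (global-mean delta-Ct),
which exactly removes per-sample additive technical offsets.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
import pandas as pd

from .containers import CtMatrix, NormalizedExpression, UNDETECTED_CT


def impute_undetected(mat: CtMatrix, sentinel: float = UNDETECTED_CT) -> CtMatrix:
    """Assign the sentinel Ct to every undetected well.

    Detected wells are untouched; detection flags are preserved so the
    expression filter still sees the original detection pattern.
    """
    ct = mat.ct.where(mat.detected, other=sentinel)
    return CtMatrix(ct, mat.detected.copy())


def filter_expressed(
    mat: CtMatrix,
    threshold: float = 0.80,
    per_group: pd.Series | None = None,
) -> List[str]:
    """Assay ids detected in at least ``threshold`` of the samples.

    By default the detection fraction is computed over all samples
    pooled ("collectively"); passing per-sample group labels switches to
    the stricter per-group reading, retaining an assay only if it clears
    the threshold inside every group.  The boundary is inclusive: a
    detection fraction exactly equal to ``threshold`` is retained.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if mat.ct.shape[0] == 0 or mat.ct.shape[1] == 0:
        raise ValueError("empty Ct matrix")
    det = mat.detected
    if per_group is None:
        frac = det.mean(axis=0)
        keep = frac >= threshold
    else:
        labels = per_group.reindex(det.index)
        if labels.isna().any():
            raise ValueError("group labels missing for some samples")
        keep = det.groupby(labels, observed=True).mean().min(axis=0) >= threshold
    return [a for a in mat.assay_ids if bool(keep[a])]


def global_mean_normalize(
    mat: CtMatrix, retained: Sequence[str]
) -> NormalizedExpression:
    """delta-Ct: each retained Ct minus the sample's mean retained Ct.

    Requires imputation to have been applied first (no missing values
    among retained assays).  Row means of the result are exactly zero,
    so any per-sample additive shift cancels.
    """
    retained = list(retained)
    if not retained:
        raise ValueError("retained assay set is empty")
    sub = mat.ct[retained]
    if sub.isna().any().any():
        raise ValueError("missing Ct among retained assays; impute first")
    dct = sub.sub(sub.mean(axis=1), axis=0)
    return NormalizedExpression(dct)


def preprocess(
    mat: CtMatrix,
    threshold: float = 0.80,
    per_group: pd.Series | None = None,
    sentinel: float = UNDETECTED_CT,
) -> NormalizedExpression:
    """Impute, filter and normalize in one step."""
    retained = filter_expressed(mat, threshold=threshold, per_group=per_group)
    if not retained:
        raise ValueError("no assay passed the expression filter")
    return global_mean_normalize(impute_undetected(mat, sentinel), retained)
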