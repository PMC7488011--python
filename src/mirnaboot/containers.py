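"""In-memory containers for qPCR panel data and their TSV round-trip.

Conventions used throughout the package:

* Ct matrices are samples x assays :class:`pandas.DataFrame` objects
  (rows indexed by sample id, columns by assay id).  Undetected wells are
  ``NaN`` in the Ct frame and ``False`` in the parallel detection frame.
* Sample metadata is a DataFrame indexed by sample id carrying at least
  ``group`` (UE / HEua / HEa), ``sex`` (M / F), ``time_point`` (T2 / T3)
  and the gestational-age covariates ``GA_bd1`` / ``GA_bd2`` (weeks).
* miRNA annotation is a DataFrame with columns ``mirna_id`` (MIMAT-style
  accession), ``name`` and ``chromosome`` (string labels "1".."22","X","Y").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("HEa", "HEua", "UE")
SEXES = ("M", "F")
TIME_POINTS = ("T2", "T3")

#: sentinel Ct assigned to undetected wells during imputation
UNDETECTED_CT = 45.0

CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


@dataclass
class CtMatrix:
    """Raw qPCR cycle-threshold values with per-well detection flags.

    Parameters
    ----------
    ct : DataFrame
        Samples x assays cycle-threshold values; NaN where undetected.
    detected : DataFrame
        Boolean frame of identical shape/labels; True where the assay
        amplified in that sample.
    """

    ct: pd.DataFrame
    detected: pd.DataFrame

    def __post_init__(self) -> None:
        if self.ct.shape != self.detected.shape:
            raise ValueError("ct and detected shapes differ")
        if not self.ct.index.equals(self.detected.index) or not self.ct.columns.equals(
            self.detected.columns
        ):
            raise ValueError("ct and detected labels differ")
        if self.ct.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        det = self.detected.to_numpy(dtype=bool)
        if not np.isfinite(self.ct.to_numpy(dtype=float)[det]).all():
            raise ValueError("non-finite Ct among detected wells")

    @property
    def sample_ids(self) -> pd.Index:
        return self.ct.index

    @property
    def assay_ids(self) -> pd.Index:
        return self.ct.columns

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.ct.copy(), self.detected.copy())


@dataclass
class NormalizedExpression:
    """Global-mean normalized expression (delta-Ct, cycles).

    ``dct`` holds Ct minus the per-sample mean Ct over the retained
    assays; every row therefore sums to ~0.  Lower values mean more
    abundant transcript.
    """

    dct: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.dct.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("non-finite normalized values")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dct.index

    @property
    def mirna_ids(self) -> pd.Index:
        return self.dct.columns


def validate_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    """Check an annotation table (mirna_id, name, chromosome) and return it."""
    for col in ("mirna_id", "name", "chromosome"):
        if col not in annot.columns:
            raise ValueError(f"annotation missing column {col!r}")
    bad = set(annot["chromosome"].astype(str)) - set(CHROMOSOMES)
    if bad:
        raise ValueError(f"unknown chromosome labels: {sorted(bad)}")
    if annot["mirna_id"].duplicated().any():
        raise ValueError("duplicate mirna_id in annotation")
    out = annot.copy()
    out["chromosome"] = out["chromosome"].astype(str)
    return out


# ---------------------------------------------------------------------------
# TSV round-trip


def write_ct_matrix(mat: CtMatrix, ct_path, detected_path) -> None:
    mat.ct.to_csv(ct_path, sep="\t", index_label="sample_id", float_format="%.6f")
    mat.detected.to_csv(detected_path, sep="\t", index_label="sample_id")


def read_ct_matrix(ct_path, detected_path) -> CtMatrix:
    ct = pd.read_csv(ct_path, sep="\t", index_col="sample_id")
    det = pd.read_csv(detected_path, sep="\t", index_col="sample_id").astype(bool)
    return CtMatrix(ct, det)


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id", float_format="%.6f")


def read_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_annotation(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    return validate_annotation(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))


def write_expression(expr: NormalizedExpression, path) -> None:
    expr.dct.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def read_expression(path) -> NormalizedExpression:
    return NormalizedExpression(pd.read_csv(path, sep="\t", index_col="sample_id"))
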