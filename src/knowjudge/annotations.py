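"""Rater annotations of image descriptions: ingestion, mode aggregation and
inter-rater reliability.

Each image description is scored by several independent raters, who count the
specific statements it contains and label each as true or false.  For analysis
the per-rater counts are collapsed to their mode across raters, and rater
agreement is quantified by the intraclass correlation coefficient ICC(2,1)
(two-way random effects, absolute agreement, single rater).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bayes import InvalidInputError

ANNOTATION_COLUMNS = ["informant_id", "category_id", "image_id", "rater_id",
                      "n_specific", "n_true", "n_false"]


@dataclass(frozen=True)
class DescriptionAnnotation:
    """One rater's statement counts for one image description."""

    informant_id: str
    category_id: str
    image_id: str
    rater_id: str
    n_specific: int
    n_true: int
    n_false: int

    def __post_init__(self) -> None:
        for name in ("n_specific", "n_true", "n_false"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InvalidInputError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_true + self.n_false != self.n_specific:
            raise InvalidInputError(
                f"rater counts inconsistent: {self.n_true} true + "
                f"{self.n_false} false != {self.n_specific} specific")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.informant_id, self.category_id, self.image_id)


@dataclass(frozen=True)
class AggregatedAnnotation:
    """Mode-across-raters counts for one description.

    Because the three modes are taken independently, the identity
    true + false = specific can break after aggregation; such descriptions
    are flagged, never reconciled.  Downstream models use n_specific_mode
    and n_false_mode only.
    """

    informant_id: str
    category_id: str
    image_id: str
    n_specific_mode: int
    n_true_mode: int
    n_false_mode: int
    n_raters: int

    @property
    def consistent_flag(self) -> bool:
        return self.n_true_mode + self.n_false_mode == self.n_specific_mode


def mode_aggregate(counts: Sequence[int]) -> int:
    """Most frequent value; ties resolve to the smallest tied value."""
    if len(counts) == 0:
        raise InvalidInputError("cannot take the mode of an empty list")
    arr = [int(c) for c in counts]
    if any(c < 0 for c in arr):
        raise InvalidInputError("counts must be non-negative")
    tally = Counter(arr)
    best = max(tally.values())
    return min(v for v, k in tally.items() if k == best)


def aggregate_description(annotations: Sequence[DescriptionAnnotation]) -> AggregatedAnnotation:
    """Collapse one description's rater annotations to per-field modes."""
    if len(annotations) == 0:
        raise InvalidInputError("need at least one rater annotation")
    keys = {a.key for a in annotations}
    if len(keys) != 1:
        raise InvalidInputError(f"annotations mix descriptions: {sorted(keys)}")
    a0 = annotations[0]
    return AggregatedAnnotation(
        informant_id=a0.informant_id,
        category_id=a0.category_id,
        image_id=a0.image_id,
        n_specific_mode=mode_aggregate([a.n_specific for a in annotations]),
        n_true_mode=mode_aggregate([a.n_true for a in annotations]),
        n_false_mode=mode_aggregate([a.n_false for a in annotations]),
        n_raters=len(annotations),
    )


def icc_agreement(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an items x raters matrix with no missing cells.  Computed
    from the two-way ANOVA mean squares:

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

    with n items, k raters, MS_R the between-items, MS_C the between-raters
    and MS_E the residual mean square.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InvalidInputError("ICC requires at least 2 items and 2 raters")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("ICC input contains missing or non-finite cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0:
        return 1.0 if ms_r == ms_e else 0.0
    return float((ms_r - ms_e) / denom)


def icc_consistency(ratings: np.ndarray) -> float:
    """ICC(3,1): two-way mixed, consistency, single rater (config alternative)."""
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InvalidInputError("ICC requires at least 2 items and 2 raters")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = np.sum((x - grand) ** 2) - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e
    if denom == 0:
        return 1.0 if ms_r == ms_e else 0.0
    return float((ms_r - ms_e) / denom)


ICC_FORMS = {"icc2_1": icc_agreement, "icc3_1": icc_consistency}


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the per-rater annotation table and validate its schema."""
    df = pd.read_csv(path, dtype={c: str for c in ANNOTATION_COLUMNS[:4]})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"annotation table {path} missing columns {missing}")
    for c in ("n_specific", "n_true", "n_false"):
        if (df[c] < 0).any():
            raise InvalidInputError(f"negative counts in column {c}")
    bad = df["n_true"] + df["n_false"] != df["n_specific"]
    if bad.any():
        raise InvalidInputError(
            f"{int(bad.sum())} rows violate n_true + n_false = n_specific")
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=ANNOTATION_COLUMNS)


def aggregate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Mode-aggregate a per-rater annotation table to one row per description."""
    rows = []
    for (inf, cat, img), grp in df.groupby(
            ["informant_id", "category_id", "image_id"], sort=True):
        ns = mode_aggregate(grp["n_specific"].tolist())
        nt = mode_aggregate(grp["n_true"].tolist())
        nf = mode_aggregate(grp["n_false"].tolist())
        rows.append({
            "informant_id": inf, "category_id": cat, "image_id": img,
            "n_specific_mode": ns, "n_true_mode": nt, "n_false_mode": nf,
            "n_raters": len(grp), "consistent_flag": nt + nf == ns,
        })
    return pd.DataFrame(rows)


def rating_matrix(df: pd.DataFrame, column: str) -> np.ndarray:
    """Pivot one count column to an items x raters matrix (descriptions as items)."""
    pivot = df.pivot_table(index=["informant_id", "category_id", "image_id"],
                           columns="rater_id", values=column)
    if pivot.isna().any().any():
        raise InvalidInputError(
            "rating matrix has missing cells; ICC needs a complete design "
            "(compute per rater group)")
    return pivot.to_numpy(dtype=float)


def reliability_report(df: pd.DataFrame, icc_form: str = "icc2_1",
                       group_column: str | None = "rater_group") -> pd.DataFrame:
    """One ICC per rater group x statement type (true / false / any).

    When the table carries no rater-group column all raters form one group.
    """
    icc_fn = ICC_FORMS[icc_form]
    if group_column and group_column in df.columns:
        groups = list(df.groupby(group_column, sort=True))
    else:
        groups = [("all", df)]
    rows = []
    for gname, gdf in groups:
        for label, col in (("true", "n_true"), ("false", "n_false"),
                           ("any", "n_specific")):
            rows.append({"rater_group": gname, "statement_type": label,
                         "icc": icc_fn(rating_matrix(gdf, col)),
                         "icc_form": icc_form})
    return pd.DataFrame(rows)
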