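"""Cohort ingestion and descriptive summaries for the 12-item ACL-RSI scale.

The ACL-RSI (Anterior Cruciate Ligament Return to Sport after Injury) scale
consists of 12 items, each scored on a 0-100 numerical rating scale, with
higher scores indicating greater psychological readiness to return to sport.
A participant's return-to-sport status is derived from a four-category
self-report; only "returned at the same or higher level than before injury"
counts as a return.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical item labels, fixed order; all matrices downstream are
#: index-addressed against this order.
ITEM_LABELS: tuple[str, ...] = tuple(f"Q{i}" for i in range(1, 13))

N_ITEMS = 12

#: Self-report categories for return-to-sport status and their classification.
RETURN_CATEGORIES: dict[str, bool] = {
    "Yes, at the same or higher level compared to before injury": True,
    "Yes, at a lower level compared to before injury": False,
    "Yes, training only": False,
    "No": False,
}


class SchemaError(ValueError):
    """A required column is missing or unresolvable."""


class CohortValidationError(ValueError):
    """Scores or labels violate the cohort contract."""


def classify_return(status_text: str) -> bool:
    """Classify a return-to-sport self-report category.

    Only a return at the same or higher level than before injury counts as
    a return; training-only and lower-level returns do not.

    Raises
    ------
    ValueError
        If the category is not one of the four recognized self-report
        options (never silently defaults).
    """
    try:
        return RETURN_CATEGORIES[status_text.strip()]
    except KeyError:
        raise ValueError(
            f"unrecognized return-to-sport category: {status_text!r}; "
            f"expected one of {sorted(RETURN_CATEGORIES)}"
        ) from None


@dataclass
class CohortTable:
    """Participant-by-item response matrix with return-to-sport labels.

    Attributes
    ----------
    items : ndarray, shape (n, 12)
        Item scores, each in [0, 100].
    returned : ndarray of bool, shape (n,)
        True where the participant returned to pre-injury level sport.
    participant_id : ndarray of object, shape (n,)
        Opaque identifiers.
    item_labels : tuple of str
        Always ``Q1..Q12`` in fixed order.
    """

    items: np.ndarray
    returned: np.ndarray
    participant_id: np.ndarray | None = None
    item_labels: tuple[str, ...] = field(default=ITEM_LABELS)

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=float)
        self.returned = np.asarray(self.returned, dtype=bool)
        if self.items.ndim != 2 or self.items.shape[1] != len(self.item_labels):
            raise CohortValidationError(
                f"items must be n x {len(self.item_labels)}, got {self.items.shape}"
            )
        if len(set(self.item_labels)) != len(self.item_labels):
            raise CohortValidationError("item labels must be unique")
        if self.returned.shape != (self.items.shape[0],):
            raise CohortValidationError("returned vector length must match items")
        if self.participant_id is None:
            self.participant_id = np.array(
                [f"P{i:04d}" for i in range(self.items.shape[0])], dtype=object
            )
        self.participant_id = np.asarray(self.participant_id, dtype=object)
        if self.participant_id.shape != (self.items.shape[0],):
            raise CohortValidationError("participant_id length must match items")
        if np.isnan(self.items).any():
            raise CohortValidationError(
                "missing values present; apply complete-case filtering before "
                "constructing a CohortTable"
            )
        bad = np.argwhere((self.items < 0) | (self.items > 100))
        if bad.size:
            r, c = bad[0]
            raise CohortValidationError(
                f"score outside [0, 100] at row {r}, item {self.item_labels[c]}: "
                f"{self.items[r, c]}"
            )

    @property
    def n(self) -> int:
        return self.items.shape[0]

    @property
    def p(self) -> int:
        return self.items.shape[1]

    def subset(self, mask: np.ndarray) -> "CohortTable":
        """Row subset (boolean mask or integer indices)."""
        mask = np.asarray(mask)
        return CohortTable(
            items=self.items[mask],
            returned=self.returned[mask],
            participant_id=self.participant_id[mask],
            item_labels=self.item_labels,
        )

    def split_by_return(self) -> tuple["CohortTable", "CohortTable"]:
        """(returned, not-returned) subgroup tables."""
        return self.subset(self.returned), self.subset(~self.returned)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.items, columns=list(self.item_labels))
        df.insert(0, "participant_id", self.participant_id)
        df["returned"] = self.returned
        return df


def concat(tables: list[CohortTable]) -> CohortTable:
    """Row-concatenate cohort tables sharing the same item labels."""
    labels = tables[0].item_labels
    if any(t.item_labels != labels for t in tables):
        raise CohortValidationError("cannot concatenate cohorts with different items")
    return CohortTable(
        items=np.vstack([t.items for t in tables]),
        returned=np.concatenate([t.returned for t in tables]),
        participant_id=np.concatenate([t.participant_id for t in tables]),
        item_labels=labels,
    )


def read_cohort(
    path,
    schema: dict[str, str] | None = None,
    delimiter: str = ",",
    encoding: str = "utf-8",
) -> CohortTable:
    """Read and validate a participant-item CSV.

    Expected columns are ``Q1..Q12`` plus a return-status column: either a
    boolean ``returned`` column or a ``return_status`` column holding the raw
    self-report category text. ``schema`` may remap any of these (e.g.
    ``{"Q1": "rsi_item_1", "returned": "rts"}``); keys are canonical names,
    values are the column names in the file. Columns are canonicalized to
    Q1..Q12 order regardless of their order in the file.

    Rows with any missing item score are excluded (complete-case analysis)
    and the exclusion count is logged.
    """
    schema = schema or {}
    df = pd.read_csv(path, sep=delimiter, encoding=encoding)

    colmap = {canon: schema.get(canon, canon) for canon in ITEM_LABELS}
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise SchemaError(f"missing item column(s): {missing}")

    status_bool_col = schema.get("returned", "returned")
    status_text_col = schema.get("return_status", "return_status")
    if status_bool_col in df.columns:
        returned = df[status_bool_col].astype(bool).to_numpy()
    elif status_text_col in df.columns:
        returned = np.array(
            [classify_return(str(v)) for v in df[status_text_col]], dtype=bool
        )
    else:
        raise SchemaError(
            f"no return-status column: expected {status_bool_col!r} (boolean) "
            f"or {status_text_col!r} (category text)"
        )

    id_col = schema.get("participant_id", "participant_id")
    ids = (
        df[id_col].astype(str).to_numpy(dtype=object)
        if id_col in df.columns
        else None
    )

    items = df[[colmap[c] for c in ITEM_LABELS]].apply(
        pd.to_numeric, errors="coerce"
    )
    complete = ~items.isna().any(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info(
            "excluded %d row(s) with missing item scores (complete-case)",
            n_excluded,
        )
    items_arr = items.to_numpy(dtype=float)[complete.to_numpy()]

    bad = np.argwhere((items_arr < 0) | (items_arr > 100))
    if bad.size:
        r, c = bad[0]
        raise CohortValidationError(
            f"score outside [0, 100] at data row {r}, item {ITEM_LABELS[c]}"
        )

    keep = complete.to_numpy()
    return CohortTable(
        items=items_arr,
        returned=returned[keep],
        participant_id=ids[keep] if ids is not None else None,
    )


STRATA = ("whole", "returned", "not_returned")


def summarize(cohort: CohortTable) -> pd.DataFrame:
    """Per-item mean/SD/count by stratum (whole / returned / not-returned).

    SDs use the sample (n-1) denominator, on the original 0-100 scale.

    Returns a tidy frame with columns ``item, stratum, n, mean, sd``.
    """
    strata = {
        "whole": np.ones(cohort.n, dtype=bool),
        "returned": cohort.returned,
        "not_returned": ~cohort.returned,
    }
    rows = []
    for name, mask in strata.items():
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"empty stratum: {name}")
        if n < 2:
            raise ValueError(f"stratum {name!r} has fewer than 2 participants")
        sub = cohort.items[mask]
        means = sub.mean(axis=0)
        sds = sub.std(axis=0, ddof=1)
        for j, label in enumerate(cohort.item_labels):
            rows.append(
                {"item": label, "stratum": name, "n": n,
                 "mean": means[j], "sd": sds[j]}
            )
    return pd.DataFrame(rows)
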