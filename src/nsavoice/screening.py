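"""Auditory-perceptual screening statistics and the pure-sample filter.

Clinical voice-type labels come from a panel of expert raters, each of whom
assigns every token one of four categories (modal, breathy, pressed, or
"none of the above") together with a self-reported confidence in [0, 1].
This module provides the reliability statistics used to qualify such a panel
— Fleiss' kappa for inter-rater agreement on categorical ratings, and the
two-way random-effects intraclass correlation (absolute agreement) for
intra-rater test–retest reliability on duplicated tokens — plus the
screening rule that defines the ground-truth label set: a token is a *pure
sample* when at least ``min_agree`` of the raters chose the same voice type
and every one of those agreeing raters reported confidence of at least
``min_conf``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

#: Rating vocabulary. The first three are voice types; "none" is the
#: none-of-the-above escape used for distractor or mixed-quality tokens.
CATEGORIES: tuple[str, ...] = ("modal", "breathy", "pressed", "none")

#: The three target phonation types eligible to label a pure sample.
VOICE_TYPES: tuple[str, ...] = ("modal", "breathy", "pressed")

RATING_COLUMNS = ("sample_id", "rater_id", "category", "confidence")


@dataclass
class RatingTable:
    """Long-form panel ratings: one row per (sample, rater).

    ``duplicate_map`` pairs primary sample ids with the ids of their hidden
    second presentation (for the intra-rater design); duplicate copies are
    excluded from screening but participate in agreement statistics.
    """

    ratings: pd.DataFrame
    duplicate_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.ratings
        missing = [c for c in RATING_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"rating table missing columns {missing}")
        bad = set(df["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown rating categories {sorted(bad)}")
        conf = df["confidence"].to_numpy(float)
        if np.any((conf < 0) | (conf > 1)) or np.any(~np.isfinite(conf)):
            raise ValueError("confidence values must lie in [0, 1]")
        if df.duplicated(subset=["sample_id", "rater_id"]).any():
            raise ValueError("duplicate (sample_id, rater_id) rating rows")
        for orig, dup in self.duplicate_map.items():
            ids = set(df["sample_id"])
            if orig not in ids or dup not in ids:
                raise ValueError(f"duplicate_map entry ({orig}, {dup}) not in table")

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.ratings.to_csv(path, index=False, columns=list(RATING_COLUMNS))

    @classmethod
    def from_csv(cls, path, duplicate_map: dict[str, str] | None = None) -> "RatingTable":
        return cls(pd.read_csv(path), duplicate_map or {})

    # -- reshaping ---------------------------------------------------------

    def counts(self) -> pd.DataFrame:
        """Item-by-category rating counts (every sample id is an item)."""
        tab = pd.crosstab(self.ratings["sample_id"], self.ratings["category"])
        return tab.reindex(columns=list(CATEGORIES), fill_value=0)

    @property
    def n_raters(self) -> int:
        return self.ratings["rater_id"].nunique()


@dataclass
class ScreenedDataset:
    """Outcome of the pure-sample filter."""

    pure_labels: dict[str, str]
    rejected_ids: list[str]
    counts_by_type: dict[str, int]

    @property
    def n_pure(self) -> int:
        return len(self.pure_labels)


def fleiss_kappa(table: RatingTable | np.ndarray | pd.DataFrame) -> float:
    """Fleiss' kappa for multi-rater categorical agreement.

    Accepts a :class:`RatingTable` or an item-by-category count matrix whose
    rows must all sum to the same number of raters n >= 2. Computes
    kappa = (Pbar - Pe) / (1 - Pe) with per-item agreement
    P_i = [sum_j n_ij (n_ij - 1)] / [n (n - 1)].
    """
    if isinstance(table, RatingTable):
        counts = table.counts().to_numpy(float)
    else:
        counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 1 or counts.shape[1] < 2:
        raise ValueError("need an (items x categories) count matrix")
    row_sums = counts.sum(axis=1)
    n = row_sums[0]
    if n < 2:
        raise ValueError("Fleiss' kappa needs at least two raters per item")
    if not np.allclose(row_sums, n):
        raise ValueError("unequal rater counts per item; the design must be balanced")
    n_items = counts.shape[0]
    p_i = (np.sum(counts * (counts - 1), axis=1)) / (n * (n - 1))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / (n_items * n)
    p_e = float(np.sum(p_j**2))
    if 1.0 - p_e < 1e-12:
        # Every rating in a single category: unanimity, kappa := 1.
        return 1.0
    return (p_bar - p_e) / (1.0 - p_e)


def icc_two_way_random(scores, measure: str = "single") -> float:
    """Intraclass correlation, two-way random effects, absolute agreement.

    ``scores`` is an (items x raters) matrix with no missing cells. The
    default ``measure="single"`` returns ICC(2,1); ``measure="average"``
    returns ICC(2,k) for the mean of the k raters. Computed from the two-way
    ANOVA mean squares (rows = items/targets, columns = raters/occasions).
    """
    y = np.asarray(scores, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 score matrix")
    if not np.isfinite(y).all():
        raise ValueError("score matrix contains missing or non-finite cells")
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_total <= 0:
        raise ValueError("zero total variance; ICC undefined")
    if measure == "single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif measure == "average":
        denom = msr + (msc - mse) / n
    else:
        raise ValueError("measure must be 'single' or 'average'")
    if abs(denom) < 1e-300:
        raise ValueError("degenerate variance decomposition; ICC undefined")
    return float((msr - mse) / denom)


def filter_pure(
    table: RatingTable, min_agree: int = 4, min_conf: float = 0.8
) -> ScreenedDataset:
    """Apply the pure-sample rule to a balanced panel.

    A sample is *pure* iff at least ``min_agree`` raters chose the same
    category from the three voice types AND each of those agreeing raters
    reported confidence >= ``min_conf``. Everything else — including
    "none"-majority items and distractors — is rejected. Hidden duplicate
    copies (values of ``duplicate_map``) are not screened.
    """
    dup_copies = set(table.duplicate_map.values())
    pure: dict[str, str] = {}
    rejected: list[str] = []
    for sid, group in table.ratings.groupby("sample_id", sort=True):
        if sid in dup_copies:
            continue
        candidates: list[str] = []
        for cat in VOICE_TYPES:
            chosen = group[group["category"] == cat]
            if len(chosen) >= min_agree and (chosen["confidence"] >= min_conf).all():
                candidates.append(cat)
        if len(candidates) == 1:
            pure[str(sid)] = candidates[0]
        else:
            # zero candidates, or a tie (possible only for min_agree <=
            # half the panel): rejected either way.
            rejected.append(str(sid))
    counts = Counter(pure.values())
    return ScreenedDataset(
        pure_labels=pure,
        rejected_ids=rejected,
        counts_by_type={t: counts.get(t, 0) for t in VOICE_TYPES},
    )


def intra_rater_reliability(table: RatingTable) -> pd.DataFrame:
    """Per-rater test–retest reliability on the duplicated samples.

    For each rater, two statistics over the (first presentation, hidden
    duplicate) pairs: Cohen's kappa on the categorical ratings, and
    ICC(2,1) on the confidence scores with the two presentations as the
    "raters" of the two-way design. Requires at least two duplicate pairs.
    """
    if len(table.duplicate_map) < 2:
        raise ValueError("need at least two duplicated samples")
    df = table.ratings.set_index(["sample_id", "rater_id"])
    rows = []
    for rater in sorted(table.ratings["rater_id"].unique()):
        first_cat, second_cat, first_conf, second_conf = [], [], [], []
        for orig, dup in table.duplicate_map.items():
            a = df.loc[(orig, rater)]
            b = df.loc[(dup, rater)]
            first_cat.append(a["category"])
            second_cat.append(b["category"])
            first_conf.append(float(a["confidence"]))
            second_conf.append(float(b["confidence"]))
        if set(first_cat) == set(second_cat) and len(set(first_cat)) == 1:
            kappa = 1.0  # unanimous on one category: chance correction degenerate
        else:
            kappa = float(
                cohen_kappa_score(first_cat, second_cat, labels=list(CATEGORIES))
            )
        conf_mat = np.column_stack([first_conf, second_conf])
        try:
            icc = icc_two_way_random(conf_mat)
        except ValueError:
            icc = float("nan")
        rows.append({"rater_id": rater, "kappa": kappa, "icc_confidence": icc})
    return pd.DataFrame(rows).set_index("rater_id")
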