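"""Long-format multi-outcome survival data.

The central container couples a subject-level predictor table (n x P, no
missing values) with a long-format table of survival records: one row per
subject x outcome, carrying a counting-process interval (entry, exit] and an
event indicator. A subject may be absent for an outcome (not at risk, e.g.
prevalent disease at baseline); risk sets are always formed within outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

RECORD_COLUMNS = ["subject_id", "outcome", "entry", "exit", "status"]

__all__ = [
    "MultiOutcomeSurvivalData",
    "ScalingStats",
    "read_long_format",
    "write_long_format",
    "standardize",
    "split_train_test",
]


class FitArrays(NamedTuple):
    """Numeric view of a data set, used by the fitting machinery."""

    X: np.ndarray            # (n_subjects, P) predictor matrix
    row_subject: np.ndarray  # (n_rows,) int index into X
    row_stratum: np.ndarray  # (n_rows,) int outcome code, 0..Q-1
    entry: np.ndarray        # (n_rows,) float
    exit: np.ndarray         # (n_rows,) float
    status: np.ndarray       # (n_rows,) int in {0, 1}


@dataclass(frozen=True)
class ScalingStats:
    """Per-predictor centering/scaling statistics (sample sd, ddof=1)."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        bad = self.sd.index[~(self.sd > 0)]
        if len(bad):
            raise ValueError(f"non-positive sd for predictors: {list(bad)}")


class MultiOutcomeSurvivalData:
    """Validated long-format survival records joined to subject predictors.

    Parameters
    ----------
    records : DataFrame
        Columns ``subject_id, outcome, [entry,] exit, status``. At most one
        row per (subject, outcome); ``exit > entry`` strictly; ``status`` in
        {0, 1}. A missing ``entry`` column means entry = 0 for every row.
    predictors : DataFrame
        One row per subject. Either indexed by subject id or carrying a
        ``subject_id`` column; remaining columns are the P numeric predictors.
    outcome_labels : sequence, optional
        Fixed outcome (stratum) ordering. Defaults to order of first
        appearance in ``records``. Extra labels with zero records are
        rejected.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        predictors: pd.DataFrame,
        outcome_labels: Sequence | None = None,
    ):
        records = records.copy()
        predictors = predictors.copy()
        if "subject_id" in predictors.columns:
            predictors = predictors.set_index("subject_id")
        if predictors.index.has_duplicates:
            dup = predictors.index[predictors.index.duplicated()][0]
            raise ValueError(f"duplicate subject_id in predictors: {dup!r}")

        missing = [c for c in ("subject_id", "outcome", "exit", "status") if c not in records.columns]
        if missing:
            raise ValueError(f"records table lacks required columns: {missing}")
        if "entry" not in records.columns:
            records["entry"] = 0.0
        records = records[RECORD_COLUMNS]

        # predictor validation: numeric, finite
        for col in predictors.columns:
            vals = pd.to_numeric(predictors[col], errors="coerce")
            if vals.isna().any():
                row = predictors.index[vals.isna()][0]
                raise ValueError(
                    f"non-numeric or missing predictor value at subject {row!r}, column {col!r}"
                )
            predictors[col] = vals.astype(float)

        dup_mask = records.duplicated(subset=["subject_id", "outcome"], keep=False)
        if dup_mask.any():
            pair = records.loc[dup_mask, ["subject_id", "outcome"]].iloc[0]
            raise ValueError(
                f"duplicate record for subject {pair['subject_id']!r}, outcome {pair['outcome']!r}"
            )

        unknown = ~records["subject_id"].isin(predictors.index)
        if unknown.any():
            sid = records.loc[unknown, "subject_id"].iloc[0]
            raise ValueError(f"record subject {sid!r} missing from predictors table")

        records["entry"] = records["entry"].astype(float)
        records["exit"] = records["exit"].astype(float)
        if not (records["exit"] > records["entry"]).all():
            bad = records.loc[~(records["exit"] > records["entry"])].iloc[0]
            raise ValueError(
                f"exit <= entry for subject {bad['subject_id']!r}, outcome {bad['outcome']!r}"
            )
        status = records["status"]
        if not status.isin([0, 1]).all():
            raise ValueError("status must be 0 or 1")
        records["status"] = status.astype(int)

        seen = list(dict.fromkeys(records["outcome"]))
        if outcome_labels is None:
            outcome_labels = seen
        else:
            outcome_labels = list(outcome_labels)
            extra = set(seen) - set(outcome_labels)
            if extra:
                raise ValueError(f"records contain outcomes not in outcome_labels: {sorted(map(str, extra))}")
        empty = [q for q in outcome_labels if q not in set(seen)]
        if empty:
            raise ValueError(f"outcomes with zero records: {empty}")

        self.records = records.reset_index(drop=True)
        self.predictors = predictors
        self.outcome_labels = list(outcome_labels)
        self._arrays: FitArrays | None = None

    # -- derived counts ----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.predictors)

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def n_predictors(self) -> int:
        return self.predictors.shape[1]

    @property
    def n_outcomes(self) -> int:
        return len(self.outcome_labels)

    @property
    def predictor_names(self) -> list:
        return list(self.predictors.columns)

    @property
    def subject_ids(self) -> pd.Index:
        return self.predictors.index

    def events_per_outcome(self) -> pd.Series:
        counts = self.records.groupby("outcome", sort=False)["status"].sum()
        return counts.reindex(self.outcome_labels, fill_value=0)

    def to_arrays(self) -> FitArrays:
        """Numeric view (cached); subject and stratum codes are positional."""
        if self._arrays is None:
            subj_pos = pd.Index(self.predictors.index).get_indexer(self.records["subject_id"])
            strat_pos = pd.Index(self.outcome_labels).get_indexer(self.records["outcome"])
            self._arrays = FitArrays(
                X=self.predictors.to_numpy(dtype=float),
                row_subject=subj_pos.astype(np.int64),
                row_stratum=strat_pos.astype(np.int64),
                entry=self.records["entry"].to_numpy(dtype=float),
                exit=self.records["exit"].to_numpy(dtype=float),
                status=self.records["status"].to_numpy(dtype=np.int64),
            )
        return self._arrays

    def subset_subjects(self, subject_ids) -> "MultiOutcomeSurvivalData":
        ids = pd.Index(subject_ids)
        rec = self.records[self.records["subject_id"].isin(ids)]
        return MultiOutcomeSurvivalData(rec, self.predictors.loc[ids], self.outcome_labels)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MultiOutcomeSurvivalData):
            return NotImplemented
        a = self.records.sort_values(["subject_id", "outcome"], kind="stable").reset_index(drop=True)
        b = other.records.sort_values(["subject_id", "outcome"], kind="stable").reset_index(drop=True)
        # record sets are compared ordering-insensitively; times exactly
        a["outcome"] = a["outcome"].astype(str)
        b["outcome"] = b["outcome"].astype(str)
        a["subject_id"] = a["subject_id"].astype(str)
        b["subject_id"] = b["subject_id"].astype(str)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
            pd.testing.assert_frame_equal(
                self.predictors.sort_index(), other.predictors.sort_index(), check_dtype=False
            )
        except AssertionError:
            return False
        return list(map(str, self.outcome_labels)) == list(map(str, other.outcome_labels))

    def __repr__(self) -> str:
        return (
            f"MultiOutcomeSurvivalData(n_subjects={self.n_subjects}, "
            f"P={self.n_predictors}, Q={self.n_outcomes}, n_rows={self.n_rows})"
        )


def read_long_format(records_path, predictors_path, outcome_labels=None) -> MultiOutcomeSurvivalData:
    """Read and validate the two CSV files (comma-separated, header row, UTF-8)."""
    records = pd.read_csv(records_path)
    predictors = pd.read_csv(predictors_path)
    if "subject_id" not in predictors.columns:
        raise ValueError(f"predictors file {predictors_path} lacks a subject_id column")
    return MultiOutcomeSurvivalData(records, predictors, outcome_labels)


def write_long_format(data: MultiOutcomeSurvivalData, records_path, predictors_path) -> None:
    """Write the records/predictors CSV pair; floats at 17 significant digits."""
    data.records.to_csv(records_path, index=False, float_format="%.17g")
    data.predictors.reset_index(names="subject_id").to_csv(
        predictors_path, index=False, float_format="%.17g"
    )


def standardize(
    data: MultiOutcomeSurvivalData, stats: ScalingStats | None = None
) -> tuple[MultiOutcomeSurvivalData, ScalingStats]:
    """Center and scale the predictor columns.

    With ``stats=None`` the statistics (mean, sample sd with ddof=1) are
    computed on ``data`` itself and applied — each split standardized on its
    own statistics. Passing precomputed ``stats`` (e.g. from the training
    split) applies those instead.
    """
    P = data.predictors
    if stats is None:
        mean = P.mean()
        sd = P.std(ddof=1)
        tiny = sd <= 1e-12
        if tiny.any():
            raise ValueError(f"zero-variance predictor: {sd.index[tiny][0]!r}")
        stats = ScalingStats(mean=mean, sd=sd)
    scaled = (P - stats.mean) / stats.sd
    out = MultiOutcomeSurvivalData(data.records, scaled, data.outcome_labels)
    return out, stats


def split_train_test(
    data: MultiOutcomeSurvivalData, test_fraction: float, seed: int
) -> tuple[MultiOutcomeSurvivalData, MultiOutcomeSurvivalData]:
    """Subject-level random split (all records of a subject stay together)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = np.asarray(data.subject_ids)
    perm = rng.permutation(len(ids))
    n_test = int(round(len(ids) * test_fraction))
    test_ids = ids[perm[:n_test]]
    train_ids = ids[perm[n_test:]]
    train = data.subset_subjects(train_ids)
    test = data.subset_subjects(test_ids)
    for name, part in (("train", train), ("test", test)):
        ev = part.events_per_outcome()
        if (ev == 0).any():
            warnings.warn(
                f"{name} split has zero events for outcome(s) "
                f"{list(ev.index[ev == 0])}; those strata contribute nothing to the fit",
                UserWarning,
                stacklevel=2,
            )
    return train, test


def combine(a: MultiOutcomeSurvivalData, b: MultiOutcomeSurvivalData) -> MultiOutcomeSurvivalData:
    """Union of two subject-disjoint data sets (same predictors and outcomes)."""
    if a.predictor_names != b.predictor_names:
        raise ValueError("predictor columns differ between the two data sets")
    if set(a.outcome_labels) != set(b.outcome_labels):
        raise ValueError("outcome labels differ between the two data sets")
    overlap = a.subject_ids.intersection(b.subject_ids)
    if len(overlap):
        raise ValueError(f"subject overlap between data sets, e.g. {overlap[0]!r}")
    rec = pd.concat([a.records, b.records], ignore_index=True)
    pred = pd.concat([a.predictors, b.predictors])
    return MultiOutcomeSurvivalData(rec, pred, a.outcome_labels)
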