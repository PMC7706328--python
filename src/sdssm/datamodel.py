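"""Sequence tables, CSV I/O, masking, standardization and grouped splits.

The unit record is one cultivation-bed day: daily averaged climate covariates
(temperature, solar radiation, VPD, CO2), growth covariates (elapsed days
since flowering, accumulated temperature), the dense stem-diameter channel
y_t (mm, always present) and the sparse sugar-content channel x_t (brix,
measured every few days; empty CSV cell = missing).  Sequences are keyed by
(bed, cultivation step) and indexed by day; cross-validation always splits by
whole beds so no bed leaks across train/validation/test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMA_COLUMNS", "STANDARDIZED_COLUMNS", "CV_PATTERNS",
    "SchemaError", "IntegrityError",
    "SequenceTable", "SplitDataset", "Scaler",
    "CovariateRouting", "SequenceTensorBundle",
    "load_timeseries_csv", "write_timeseries_csv",
    "split_by_beds", "split_by_pattern", "standardize",
    "bundle_table", "make_training_sequences", "stack_bundles",
]

SCHEMA_COLUMNS = [
    "bed_id", "step_id", "date", "day_index",
    "temperature", "solar_radiation", "vpd", "co2",
    "elapsed_days", "accum_temp", "stem_diameter", "sugar_brix",
]

#: columns z-scored by :func:`standardize` (one-hot step encoding excluded)
STANDARDIZED_COLUMNS = [
    "temperature", "solar_radiation", "vpd", "co2",
    "elapsed_days", "accum_temp", "stem_diameter", "sugar_brix",
]

#: bed assignments of the four grouped cross-validation patterns
CV_PATTERNS = {
    "A": {"train": (3, 4, 5, 6, 7, 11, 13, 14, 15),
          "val": (8, 12, 16), "test": (1, 2, 9, 10)},
    "B": {"train": (1, 5, 7, 8, 9, 13, 14, 15, 16),
          "val": (2, 6, 10), "test": (3, 4, 11, 12)},
    "C": {"train": (1, 2, 3, 4, 7, 9, 10, 11, 15),
          "val": (8, 12, 16), "test": (5, 6, 13, 14)},
    "D": {"train": (1, 3, 4, 5, 9, 11, 12, 13, 14),
          "val": (2, 6, 10), "test": (7, 8, 15, 16)},
}


class SchemaError(ValueError):
    """The CSV header does not match the expected schema."""


class IntegrityError(ValueError):
    """Duplicate or inconsistent (bed, step, day) records."""


class SequenceTable:
    """Long-format daily records, one row per (bed, step, day)."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in SCHEMA_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        frame = frame[SCHEMA_COLUMNS].copy()
        key = ["bed_id", "step_id", "day_index"]
        if frame.duplicated(subset=key).any():
            dup = frame[frame.duplicated(subset=key)].iloc[0]
            raise IntegrityError(
                "duplicate record for (bed, step, day) = "
                f"({dup.bed_id}, {dup.step_id}, {dup.day_index})")
        self.frame = frame.sort_values(key).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SequenceTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.frame, other.frame,
                                          check_exact=False, atol=1e-12)
            return True
        except AssertionError:
            return False

    @property
    def beds(self) -> set:
        return set(int(b) for b in self.frame.bed_id.unique())

    @property
    def mask(self) -> np.ndarray:
        """1 where sugar content is observed, 0 where missing."""
        return self.frame.sugar_brix.notna().to_numpy().astype(int)

    def subset_beds(self, beds) -> "SequenceTable":
        beds = set(int(b) for b in beds)
        return SequenceTable(self.frame[self.frame.bed_id.isin(beds)])

    def sequences(self):
        """Iterate (bed_id, step_id, per-sequence frame) in sorted order."""
        for (bed, step), grp in self.frame.groupby(["bed_id", "step_id"],
                                                   sort=True):
            yield int(bed), int(step), grp.reset_index(drop=True)


def load_timeseries_csv(path) -> SequenceTable:
    """Read the daily-record CSV; empty sugar cells become missing (NaN)."""
    frame = pd.read_csv(path)
    missing = [c for c in SCHEMA_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    frame["sugar_brix"] = pd.to_numeric(frame["sugar_brix"], errors="coerce")
    frame["date"] = frame["date"].astype(str)
    return SequenceTable(frame)


def write_timeseries_csv(table: SequenceTable, path) -> None:
    table.frame.to_csv(path, index=False, na_rep="")


@dataclass
class SplitDataset:
    """Bed-grouped train/validation/test subsets of one table."""

    train: SequenceTable
    val: SequenceTable
    test: SequenceTable
    train_beds: tuple
    val_beds: tuple
    test_beds: tuple

    @property
    def counts(self) -> dict:
        return {"train": len(self.train), "val": len(self.val),
                "test": len(self.test)}

    @property
    def labeled_counts(self) -> dict:
        return {"train": int(self.train.mask.sum()),
                "val": int(self.val.mask.sum()),
                "test": int(self.test.mask.sum())}


def split_by_beds(table: SequenceTable, train_beds, val_beds,
                  test_beds) -> SplitDataset:
    """Route every record by bed id; the three bed sets must be disjoint."""
    sets = [set(map(int, s)) for s in (train_beds, val_beds, test_beds)]
    for i in range(3):
        for j in range(i + 1, 3):
            if sets[i] & sets[j]:
                raise ValueError(
                    f"bed sets overlap: {sorted(sets[i] & sets[j])}")
    present = table.beds
    unknown = (sets[0] | sets[1] | sets[2]) - present
    if unknown:
        raise ValueError(f"bed id(s) not present in table: {sorted(unknown)}")
    return SplitDataset(
        train=table.subset_beds(sets[0]),
        val=table.subset_beds(sets[1]),
        test=table.subset_beds(sets[2]),
        train_beds=tuple(sorted(sets[0])),
        val_beds=tuple(sorted(sets[1])),
        test_beds=tuple(sorted(sets[2])),
    )


def split_by_pattern(table: SequenceTable, pattern: str) -> SplitDataset:
    """Split with one of the named bed-assignment patterns A-D."""
    try:
        beds = CV_PATTERNS[pattern.upper()]
    except KeyError:
        raise ValueError(f"unknown CV pattern {pattern!r}; "
                         f"choose from {sorted(CV_PATTERNS)}") from None
    return split_by_beds(table, beds["train"], beds["val"], beds["test"])


@dataclass
class Scaler:
    """Per-column z-score statistics fitted on the training split only."""

    loc: dict = field(default_factory=dict)
    scale: dict = field(default_factory=dict)

    @classmethod
    def fit(cls, table: SequenceTable,
            columns=tuple(STANDARDIZED_COLUMNS)) -> "Scaler":
        if len(table) == 0:
            raise ValueError("cannot fit a scaler on an empty training split")
        loc, scale = {}, {}
        for col in columns:
            values = table.frame[col].to_numpy(dtype=float)
            values = values[np.isfinite(values)]  # masked sugar excluded
            loc[col] = float(values.mean())
            sd = float(values.std(ddof=0))
            if sd <= 0.0:
                warnings.warn(f"zero-variance feature {col!r}: scale clamped "
                              "to 1", RuntimeWarning, stacklevel=2)
                sd = 1.0
            scale[col] = sd
        return cls(loc=loc, scale=scale)

    def transform(self, table: SequenceTable) -> SequenceTable:
        frame = table.frame.copy()
        for col, m in self.loc.items():
            frame[col] = (frame[col] - m) / self.scale[col]
        return SequenceTable(frame)

    def inverse_transform(self, table: SequenceTable) -> SequenceTable:
        frame = table.frame.copy()
        for col, m in self.loc.items():
            frame[col] = frame[col] * self.scale[col] + m
        return SequenceTable(frame)

    def inverse_values(self, column: str, values):
        """Map standardized values of one column back to original units."""
        return np.asarray(values, float) * self.scale[column] + self.loc[column]

    def inverse_scale(self, column: str, values):
        """Map standardized spreads (std devs) back to original units."""
        return np.asarray(values, float) * self.scale[column]

    def to_dict(self) -> dict:
        return {"loc": dict(self.loc), "scale": dict(self.scale)}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(loc=dict(d["loc"]), scale=dict(d["scale"]))


def standardize(split: SplitDataset) -> tuple[SplitDataset, Scaler]:
    """Z-score all splits with statistics fitted on the training split."""
    scaler = Scaler.fit(split.train)
    return replace(
        split,
        train=scaler.transform(split.train),
        val=scaler.transform(split.val),
        test=scaler.transform(split.test),
    ), scaler


@dataclass
class CovariateRouting:
    """Which table columns feed the u/v/s/r conditioning vectors.

    The token ``"step_onehot"`` expands to a 3-way one-hot encoding of the
    cultivation-step id.
    """

    u_cols: tuple = ()
    v_cols: tuple = ()
    s_cols: tuple = ()
    r_cols: tuple = ()

    def _matrix(self, frame: pd.DataFrame, cols) -> np.ndarray:
        parts = []
        for col in cols:
            if col == "step_onehot":
                step = frame["step_id"].to_numpy()
                parts.append(np.stack([(step == k).astype(float)
                                       for k in (1, 2, 3)], axis=1))
            else:
                parts.append(frame[col].to_numpy(dtype=float)[:, None])
        if not parts:
            return np.zeros((len(frame), 0))
        return np.concatenate(parts, axis=1)

    def dims(self) -> dict:
        def width(cols):
            return sum(3 if c == "step_onehot" else 1 for c in cols)
        return {"u": width(self.u_cols), "v": width(self.v_cols),
                "s": width(self.s_cols), "r": width(self.r_cols)}


@dataclass
class SequenceTensorBundle:
    """One contiguous sequence as arrays sharing length T."""

    bed_id: int
    step_id: int
    day_index: np.ndarray    # [T]
    x: np.ndarray            # [T] sugar (0 where missing)
    m: np.ndarray            # [T] in {0,1}; 1 iff sugar observed
    y: np.ndarray            # [T] stem diameter
    U: np.ndarray            # [T, dim_u]
    V: np.ndarray            # [T, dim_v]
    S: np.ndarray            # [T, dim_s]
    R: np.ndarray            # [T, dim_r]

    @property
    def T(self) -> int:
        return len(self.y)

    def window(self, start: int, stop: int) -> "SequenceTensorBundle":
        return SequenceTensorBundle(
            bed_id=self.bed_id, step_id=self.step_id,
            day_index=self.day_index[start:stop],
            x=self.x[start:stop], m=self.m[start:stop], y=self.y[start:stop],
            U=self.U[start:stop], V=self.V[start:stop],
            S=self.S[start:stop], R=self.R[start:stop])

    def labeled_subsequence(self) -> "SequenceTensorBundle":
        """Restrict to timesteps with observed sugar (the labeled dataset).

        This is the training view seen by supervised baselines: the latent
        chain then steps over measurement days only and never touches the
        unlabeled records.
        """
        idx = np.flatnonzero(self.m > 0)
        return SequenceTensorBundle(
            bed_id=self.bed_id, step_id=self.step_id,
            day_index=self.day_index[idx],
            x=self.x[idx], m=self.m[idx], y=self.y[idx],
            U=self.U[idx], V=self.V[idx], S=self.S[idx], R=self.R[idx])


def bundle_table(table: SequenceTable,
                 routing: CovariateRouting) -> list[SequenceTensorBundle]:
    """One bundle per (bed, step), covariates routed per ``routing``."""
    bundles = []
    for bed, step, grp in table.sequences():
        sugar = grp.sugar_brix.to_numpy(dtype=float)
        mask = np.isfinite(sugar).astype(float)
        bundles.append(SequenceTensorBundle(
            bed_id=bed, step_id=step,
            day_index=grp.day_index.to_numpy(),
            x=np.where(mask > 0, sugar, 0.0),
            m=mask,
            y=grp.stem_diameter.to_numpy(dtype=float),
            U=routing._matrix(grp, routing.u_cols),
            V=routing._matrix(grp, routing.v_cols),
            S=routing._matrix(grp, routing.s_cols),
            R=routing._matrix(grp, routing.r_cols),
        ))
    return bundles


def make_training_sequences(bundles, seq_len: int,
                            stride: int | None = None
                            ) -> list[SequenceTensorBundle]:
    """Cut sequences into contiguous windows (non-overlapping by default).

    The trailing shorter window is kept, so with the default stride the
    windows partition each sequence exactly.
    """
    if seq_len < 2:
        raise ValueError("seq_len must be at least 2")
    stride = seq_len if stride is None else int(stride)
    if stride < 1:
        raise ValueError("stride must be at least 1")
    windows = []
    for b in bundles:
        start = 0
        while start < b.T:
            windows.append(b.window(start, min(start + seq_len, b.T)))
            start += stride
    return windows


def stack_bundles(bundles) -> list[dict]:
    """Group bundles by length T and stack each group into batched arrays.

    Returns a list of dicts with keys x, m, y [B, T] and U, V, S, R
    [B, T, dim], plus the source bundles.
    """
    by_len: dict[int, list] = {}
    for b in bundles:
        by_len.setdefault(b.T, []).append(b)
    batches = []
    for T in sorted(by_len):
        group = by_len[T]
        batches.append({
            "x": np.stack([b.x for b in group]),
            "m": np.stack([b.m for b in group]),
            "y": np.stack([b.y for b in group]),
            "U": np.stack([b.U for b in group]),
            "V": np.stack([b.V for b in group]),
            "S": np.stack([b.S for b in group]),
            "R": np.stack([b.R for b in group]),
            "bundles": group,
        })
    return batches
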