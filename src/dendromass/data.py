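"""Per-tree biomass datasets: CSV I/O, validation, transforms, subsampling.

A dataset is a table of destructively sampled trees.  Each record carries six
size/density predictors and the total dry biomass response:

======  ==============================================  =====
column  meaning                                         units
======  ==============================================  =====
dbh     diameter at breast height (1.3 m)               cm
dm      mean crown diameter                             m
ht      total height                                    m
hc      height of the lowest living branch              m
da      apparent wood density                           g/cm3
db      basic wood density                              g/cm3
w       total dry biomass (above- plus belowground)     kg
======  ==============================================  =====

All values are strictly positive except ``hc`` which may be zero (a living
branch at ground level).  ``hc <= ht`` and ``db <= da`` always hold.  An
optional ``species`` column is carried through for bookkeeping but never used
by the estimators.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: canonical predictor order; variable subsets are always reported in this order
PREDICTORS = ("dbh", "dm", "ht", "hc", "da", "db")
RESPONSE = "w"
REQUIRED_COLUMNS = PREDICTORS + (RESPONSE,)

#: the four predictor subsets examined in the benchmark sweep
CANONICAL_SUBSETS = (
    ("dbh",),
    ("dbh", "ht"),
    ("dbh", "ht", "da", "db"),
    PREDICTORS,
)


class DatasetFormatError(ValueError):
    """Raised when a CSV file does not conform to the expected dialect."""


class DatasetValidationError(ValueError):
    """Raised when record values violate the dataset invariants."""


def canonical_subset(names) -> tuple[str, ...]:
    """Validate a collection of predictor names and return it in canonical order.

    Raises ``ValueError`` on unknown names or duplicates; an empty subset is
    rejected because a distance needs at least one coordinate.
    """
    names = list(names)
    if not names:
        raise ValueError("variable subset must be non-empty")
    unknown = [n for n in names if n not in PREDICTORS]
    if unknown:
        raise ValueError(f"unknown variable name(s): {unknown}; valid: {PREDICTORS}")
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate variable names in subset: {names}")
    return tuple(n for n in PREDICTORS if n in names)


@dataclass(frozen=True)
class TreeDataset:
    """An immutable table of tree records plus its transform state.

    ``records`` holds one row per tree with the columns of
    :data:`REQUIRED_COLUMNS`, a unique ``record_id`` and optionally
    ``species``.  ``transform_state`` is ``"raw"`` or ``"log"`` (natural
    logarithm applied to every predictor and to ``w``).
    """

    records: pd.DataFrame
    transform_state: str = "raw"
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "records", self.records.reset_index(drop=True))

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def record_ids(self) -> np.ndarray:
        return self.records["record_id"].to_numpy()

    def validate(self) -> "TreeDataset":
        """Check all record invariants; return self if clean, raise otherwise."""
        df = self.records
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetFormatError(f"missing required column(s): {missing}")
        if "record_id" not in df.columns:
            raise DatasetFormatError("missing record_id column")
        if df["record_id"].duplicated().any():
            dupes = df.loc[df["record_id"].duplicated(), "record_id"].tolist()
            raise DatasetValidationError(f"duplicate record_id values: {dupes}")
        if self.n < 2:
            raise DatasetValidationError(f"dataset needs >= 2 records, got {self.n}")
        for col in REQUIRED_COLUMNS:
            vals = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                row = int(np.flatnonzero(~np.isfinite(vals))[0])
                raise DatasetValidationError(f"non-finite value in '{col}' at row {row}")
        if self.transform_state == "raw":
            for col in REQUIRED_COLUMNS:
                if col == "hc":
                    continue
                vals = df[col].to_numpy(dtype=float)
                if np.any(vals <= 0):
                    row = int(np.flatnonzero(vals <= 0)[0])
                    raise DatasetValidationError(
                        f"non-positive value in positive-only field '{col}' at row {row}"
                    )
            hc = df["hc"].to_numpy(dtype=float)
            if np.any(hc < 0):
                row = int(np.flatnonzero(hc < 0)[0])
                raise DatasetValidationError(f"negative hc at row {row}")
            bad = df["hc"].to_numpy(float) > df["ht"].to_numpy(float) + 1e-12
            if np.any(bad):
                row = int(np.flatnonzero(bad)[0])
                raise DatasetValidationError(f"hc > ht at row {row}")
            bad = df["db"].to_numpy(float) > df["da"].to_numpy(float) + 1e-12
            if np.any(bad):
                row = int(np.flatnonzero(bad)[0])
                raise DatasetValidationError(f"db > da at row {row}")
        return self


def _with_record_ids(df: pd.DataFrame) -> pd.DataFrame:
    if "record_id" not in df.columns:
        df = df.copy()
        df.insert(0, "record_id", np.arange(len(df)))
    return df


def load_dataset(path) -> TreeDataset:
    """Read a comma-separated tree table (header row, '.' decimal, UTF-8).

    Requires at least the columns ``dbh, dm, ht, hc, da, db, w``; a
    ``record_id`` column is used if present, otherwise row numbers are
    assigned.  Values are validated against the record invariants; violations
    raise with the offending column and row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing required column(s): {missing}")
    df = _with_record_ids(df)
    ds = TreeDataset(records=df, transform_state="raw", provenance=str(path))
    return ds.validate()


def save_dataset(ds: TreeDataset, path) -> None:
    """Write a dataset in the same CSV dialect :func:`load_dataset` reads.

    Floats are written with 17 significant digits, so load(save(ds))
    reproduces every value bit-exactly.
    """
    ds.records.to_csv(path, index=False, float_format="%.17g")


def dataset_to_csv(ds: TreeDataset) -> str:
    buf = io.StringIO()
    save_dataset(ds, buf)
    return buf.getvalue()


def log_transform(ds: TreeDataset) -> TreeDataset:
    """Return a copy with every predictor and ``w`` replaced by its natural log.

    Only defined for raw datasets with strictly positive values everywhere;
    a zero ``hc`` raises rather than silently offsetting, because an invisible
    +1 shift would change every downstream distance.
    """
    if ds.transform_state != "raw":
        raise ValueError(f"dataset already transformed (state={ds.transform_state!r})")
    df = ds.records.copy()
    for col in REQUIRED_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        if np.any(vals <= 0):
            row = int(np.flatnonzero(vals <= 0)[0])
            raise DatasetValidationError(
                f"cannot log-transform non-positive value in '{col}' at row {row}"
            )
        df[col] = np.log(vals)
    return TreeDataset(records=df, transform_state="log", provenance=ds.provenance)


def subsample(ds: TreeDataset, target_n: int, seed: int) -> TreeDataset:
    """Seeded simple random sample without replacement, original order kept.

    The same ``(dataset, target_n, seed)`` always yields the same records, in
    their original relative order, on any platform (PCG64 generator).
    """
    if not 2 <= target_n <= ds.n:
        raise ValueError(f"target_n must be in [2, {ds.n}], got {target_n}")
    if target_n == ds.n:
        return replace(ds, provenance=ds.provenance)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(ds.n, size=target_n, replace=False))
    df = ds.records.iloc[idx].reset_index(drop=True)
    return TreeDataset(
        records=df,
        transform_state=ds.transform_state,
        provenance=f"{ds.provenance} | subsample(n={target_n}, seed={seed})",
    )


def extract_features(ds: TreeDataset, subset) -> tuple[np.ndarray, np.ndarray]:
    """Project the dataset onto a predictor subset.

    Returns ``(X, y)`` with ``X`` of shape ``(n, len(subset))`` in canonical
    column order and ``y`` the biomass vector, both in record order.
    """
    subset = canonical_subset(subset)
    X = ds.records.loc[:, list(subset)].to_numpy(dtype=float)
    y = ds.records[RESPONSE].to_numpy(dtype=float)
    return X, y
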