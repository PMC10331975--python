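"""Shared data model and I/O for ordinal response matrices and background factors.

The central object is a :class:`ResponseMatrix`: persons × items ordinal
observations on a 1..K+1 external scale (internally recoded to 0..K, the
convention of rating-scale Rasch formulas).  Background characteristics used
for differential-item-functioning scans live in a :class:`FactorTable`, and
all protocol decision thresholds are collected in :class:`AnalysisConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ResponseMatrix",
    "FactorTable",
    "AnalysisConfig",
    "InputError",
    "read_responses",
    "write_responses",
    "read_factors",
    "classify_enps",
    "marginal_frequencies",
]


class InputError(ValueError):
    """Raised for malformed or out-of-contract input data."""


ENPS_CLASSES = ("detractor", "passive", "promoter")


def classify_enps(score: int) -> str:
    """Map a 0-10 employee-net-promoter raw score to its class.

    9-10 -> ``promoter``, 7-8 -> ``passive``, 0-6 -> ``detractor``.
    """
    s = int(score)
    if s != score or not 0 <= s <= 10:
        raise InputError(f"eNPS score must be an integer in [0, 10], got {score!r}")
    if s >= 9:
        return "promoter"
    if s >= 7:
        return "passive"
    return "detractor"


@dataclass(frozen=True)
class ResponseMatrix:
    """Persons × items ordinal observations.

    Parameters
    ----------
    values
        N×L integer matrix of category codes on the external 1..n_categories
        scale.  Cells under ``missing_mask`` are ignored (their stored value
        is arbitrary but kept in-range).
    persons, items
        Unique identifiers for rows and columns.
    n_categories
        Number of rating-scale categories (5 for the safety-climate survey).
    missing_mask
        N×L booleans, True where the observation is missing.
    """

    values: np.ndarray
    persons: tuple[str, ...]
    items: tuple[str, ...]
    n_categories: int = 5
    missing_mask: np.ndarray | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=int)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise InputError("response values must be a 2-D matrix")
        n, l = values.shape
        if n < 2 or l < 2:
            raise InputError(f"need at least 2 persons and 2 items, got {n}×{l}")
        persons = tuple(str(p) for p in self.persons)
        items = tuple(str(i) for i in self.items)
        object.__setattr__(self, "persons", persons)
        object.__setattr__(self, "items", items)
        if len(persons) != n or len(items) != l:
            raise InputError("identifier count does not match matrix shape")
        if len(set(persons)) != n:
            raise InputError("duplicate person identifiers")
        if len(set(items)) != l:
            raise InputError("duplicate item identifiers")
        if self.n_categories < 2:
            raise InputError("need at least 2 categories")
        mask = self.missing_mask
        if mask is None:
            mask = np.zeros_like(values, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != values.shape:
                raise InputError("missing_mask shape mismatch")
        object.__setattr__(self, "missing_mask", mask)
        observed = values[~mask]
        if observed.size and (observed.min() < 1 or observed.max() > self.n_categories):
            bad = np.argwhere(~mask & ((values < 1) | (values > self.n_categories)))[0]
            raise InputError(
                f"category code out of range [1, {self.n_categories}] at "
                f"person {persons[bad[0]]!r}, item {items[bad[1]]!r}"
            )

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def max_category(self) -> int:
        """K, the top internal category (n_categories - 1)."""
        return self.n_categories - 1

    def coded(self) -> np.ma.MaskedArray:
        """Responses recoded to the internal 0..K scale, missing cells masked."""
        return np.ma.MaskedArray(self.values - 1, mask=self.missing_mask)

    def subset_items(self, keep: Sequence[str]) -> "ResponseMatrix":
        keep = [str(k) for k in keep]
        unknown = set(keep) - set(self.items)
        if unknown:
            raise InputError(f"unknown item identifiers: {sorted(unknown)}")
        idx = [self.items.index(k) for k in keep]
        return ResponseMatrix(
            self.values[:, idx],
            self.persons,
            tuple(keep),
            self.n_categories,
            self.missing_mask[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.persons), columns=list(self.items))
        df = df.astype("Int64")
        df[pd.DataFrame(self.missing_mask, index=df.index, columns=df.columns)] = pd.NA
        df.index.name = "person"
        return df


@dataclass(frozen=True)
class FactorTable:
    """Background factors per person, aligned with a ResponseMatrix.

    Columns are categorical; ``enps_raw`` (0-10) is optional, and when present
    ``enps_class`` is derived deterministically via :func:`classify_enps`.
    """

    table: pd.DataFrame

    FACTORS = ("gender", "age_group", "employee_type", "tenure_band", "enps_class")

    def __post_init__(self):
        df = self.table.copy()
        if df.index.name != "person":
            if "person" in df.columns:
                df = df.set_index("person")
            else:
                raise InputError("factor table needs a 'person' column or index")
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise InputError("duplicate person identifiers in factor table")
        if "enps_raw" in df.columns:
            derived = df["enps_raw"].map(
                lambda s: classify_enps(s) if pd.notna(s) else pd.NA
            )
            if "enps_class" in df.columns:
                given = df["enps_class"]
                ok = given.isna() | (given == derived)
                if not ok.all():
                    bad = df.index[~ok][0]
                    raise InputError(
                        f"enps_class contradicts enps_raw for person {bad!r}"
                    )
            df["enps_class"] = derived
        object.__setattr__(self, "table", df)

    def factor_names(self) -> list[str]:
        return [f for f in self.FACTORS if f in self.table.columns]

    def levels(self, factor: str) -> list[str]:
        col = self.table[factor].dropna()
        return sorted(col.unique())

    def aligned_to(self, m: ResponseMatrix) -> pd.DataFrame:
        """Left-join onto the response matrix persons (persons without factors
        carry NA and are excluded from DIF only)."""
        unknown = set(self.table.index) - set(m.persons)
        if unknown:
            raise InputError(
                f"factor table persons not in response matrix: {sorted(unknown)[:5]}"
            )
        return self.table.reindex(list(m.persons))


@dataclass
class AnalysisConfig:
    """Decision thresholds for the five-step validation protocol.

    Defaults are the protocol's published criteria: category outfit < 2.0,
    residual correlation < 0.7 (shared variance < 50%), item infit in
    [0.7, 1.3], ≥50% variance explained with first-contrast eigenvalue < 2.0,
    person misfit flag = infit ≥ 1.4 together with z ≥ 2 on at most 5% of the
    sample, separation ≥ 2.0, reliability ≥ 0.7, and Bonferroni-adjusted
    DIF alpha 0.01.
    """

    category_outfit_max: float = 2.0
    residual_corr_max: float = 0.7
    item_infit_lo: float = 0.7
    item_infit_hi: float = 1.3
    variance_explained_min: float = 50.0
    first_contrast_eigen_max: float = 2.0
    person_infit_max: float = 1.4
    person_z_max: float = 2.0
    person_misfit_budget: float = 0.05
    separation_min: float = 2.0
    reliability_min: float = 0.7
    dif_alpha: float = 0.01
    dif_min_group_size: int = 10
    dif_min_stratum_size: int = 10
    index_items: tuple[str, ...] | None = None
    exclude_ceiling_from_index_corr: bool = False
    random_seed: int = 0

    def __post_init__(self):
        positives = [
            self.category_outfit_max,
            self.residual_corr_max,
            self.item_infit_lo,
            self.item_infit_hi,
            self.variance_explained_min,
            self.first_contrast_eigen_max,
            self.person_infit_max,
            self.person_z_max,
            self.person_misfit_budget,
            self.separation_min,
            self.reliability_min,
            self.dif_alpha,
        ]
        if any(not (v > 0) for v in positives):
            raise InputError("all criterion thresholds must be strictly positive")
        if not self.item_infit_lo < self.item_infit_hi:
            raise InputError("item_infit_lo must be < item_infit_hi")
        if self.index_items is not None:
            self.index_items = tuple(str(i) for i in self.index_items)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise InputError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["index_items"] is not None:
            d["index_items"] = list(d["index_items"])
        return d


def read_responses(
    path: str | Path,
    n_categories: int = 5,
    allow_missing: bool = False,
    sep: str = ",",
) -> ResponseMatrix:
    """Read a delimited response matrix.

    Layout: one header row (first column the person-identifier column name,
    the rest item identifiers), then one row per person.  Blank cells are
    missing and only accepted with ``allow_missing=True`` — the survey
    platform enforced complete responses, so the strict default mirrors that.
    """
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise InputError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 2 or df.shape[0] < 2:
        raise InputError(f"{path}: need at least 2 persons and 2 items")
    persons = [str(p) for p in df.index]
    items = [str(c) for c in df.columns]
    values = np.zeros(df.shape, dtype=int)
    mask = np.zeros(df.shape, dtype=bool)
    for r, person in enumerate(persons):
        for c, item in enumerate(items):
            cell = df.iat[r, c]
            if pd.isna(cell) or str(cell).strip() == "":
                if not allow_missing:
                    raise InputError(
                        f"{path}: missing response at person {person!r}, item {item!r}"
                    )
                mask[r, c] = True
                values[r, c] = 1
                continue
            try:
                code = int(str(cell).strip())
            except ValueError:
                raise InputError(
                    f"{path}: non-integer code {cell!r} at person {person!r}, "
                    f"item {item!r}"
                ) from None
            if not 1 <= code <= n_categories:
                raise InputError(
                    f"{path}: code {code} outside [1, {n_categories}] at "
                    f"person {person!r}, item {item!r}"
                )
            values[r, c] = code
    return ResponseMatrix(values, tuple(persons), tuple(items), n_categories, mask)


def write_responses(m: ResponseMatrix, path: str | Path, sep: str = ",") -> None:
    """Write a response matrix in the layout :func:`read_responses` reads."""
    m.to_frame().to_csv(path, sep=sep, na_rep="")


def read_factors(path: str | Path, sep: str = ",") -> FactorTable:
    df = pd.read_csv(path, sep=sep, dtype={"person": str})
    if "person" not in df.columns:
        raise InputError(f"{path}: factor table needs a 'person' column")
    return FactorTable(df)


def marginal_frequencies(m: ResponseMatrix) -> pd.DataFrame:
    """Per-item category counts (items × categories, external 1..K+1 labels).

    Each row sums to the item's number of non-missing observations.
    """
    counts = np.zeros((m.n_items, m.n_categories), dtype=int)
    coded = m.coded()
    for i in range(m.n_items):
        col = coded[:, i].compressed()
        counts[i] = np.bincount(col, minlength=m.n_categories)
    return pd.DataFrame(
        counts,
        index=list(m.items),
        columns=[str(k) for k in range(1, m.n_categories + 1)],
    )


def config_to_json(cfg: AnalysisConfig) -> str:
    return json.dumps(cfg.to_dict(), indent=2, sort_keys=True)
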