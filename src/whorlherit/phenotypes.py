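"""Ordinal whorl phenotypes, paternal half-sib families, and informativeness filters.

Phenotypes are ordered categories (whorl count 1..4; whorl position
low/medium/high).  Because heritability of a categorical trait is estimated
from contrasts within paternal half-sib families, small families and
families monomorphic for the trait are uninformative and are filtered out
before model fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree

logger = logging.getLogger(__name__)

TRAIT_NAMES = ("whorl_number", "whorl_position")

#: ordinal codes for whorl position, ordered by vertical position
POSITION_CODES = {"low": 1, "medium": 2, "high": 3}

#: sentinel returned by classify_position for multi-whorl horses, which are
#: excluded from the position trait (position is defined for one whorl only)
MULTIPLE = "multiple"


class PhenotypeError(ValueError):
    """Raised for invalid phenotype data or filter configurations."""


def classify_position(raw_label: str) -> int | None:
    """Map a raw position label to its ordinal code: low=1, medium=2, high=3.

    ``"multiple"`` returns None — multi-whorl horses carry no single
    position and are excluded from the position trait.  Labels are
    case-insensitive; anything else raises.
    """
    label = raw_label.strip().lower()
    if label == MULTIPLE:
        return None
    if label not in POSITION_CODES:
        raise PhenotypeError(f"unrecognized position label {raw_label!r}")
    return POSITION_CODES[label]


class TraitDataset:
    """Phenotyped individuals with sex code and ordinal category Y in 1..C.

    Categories are recoded to contiguous 1..C on construction;
    ``category_labels`` maps each code back to its original label.
    """

    def __init__(self, trait_name: str, observations: pd.DataFrame,
                 category_labels: Mapping[int, object] | None = None):
        df = observations.copy().reset_index(drop=True)
        required = {"id", "sex", "category"}
        if missing := required - set(df.columns):
            raise PhenotypeError(f"observations lack columns: {sorted(missing)}")
        if df.empty:
            raise PhenotypeError("empty phenotype dataset")
        dup = df["id"][df["id"].duplicated()]
        if not dup.empty:
            raise PhenotypeError(f"duplicate phenotyped individual {dup.iloc[0]!r}")
        cats = df["category"].to_numpy()
        if not np.issubdtype(np.asarray(cats).dtype, np.integer):
            raise PhenotypeError("categories must be integers (use classify_position for labels)")
        if cats.min() < 1:
            raise PhenotypeError(f"category {cats.min()} out of domain; codes begin at 1")
        observed = np.unique(cats)
        recode = {int(c): i + 1 for i, c in enumerate(observed)}
        if category_labels is None:
            category_labels = {int(c): int(c) for c in observed}
        df["category"] = df["category"].map(recode).astype(int)
        self.trait_name = trait_name
        self.observations = df
        self.n_categories = len(observed)
        self.category_labels = {
            recode[int(c)]: category_labels.get(int(c), int(c)) for c in observed
        }

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def ids(self) -> list[str]:
        return self.observations["id"].tolist()

    @property
    def categories(self) -> np.ndarray:
        return self.observations["category"].to_numpy()

    def subset(self, keep_mask: np.ndarray) -> "TraitDataset":
        sub = self.observations.loc[keep_mask]
        return TraitDataset(
            self.trait_name,
            sub,
            category_labels={c: self.category_labels.get(c, c)
                             for c in np.unique(sub["category"])},
        )


def read_phenotypes(path, trait_name: str, delimiter: str | None = None) -> TraitDataset:
    """Read a phenotype CSV with columns id, sex, and category (or label).

    Integer ``category`` columns are validated and recoded to contiguous
    1..C; a textual column (raw position labels high/medium/low/multiple)
    is mapped through :func:`classify_position`, with multi-whorl rows
    dropped (logged).
    """
    if trait_name not in TRAIT_NAMES:
        raise PhenotypeError(f"unknown trait {trait_name!r}; expected one of {TRAIT_NAMES}")
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c",
                     dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    if "category" not in df.columns and "label" in df.columns:
        df = df.rename(columns={"label": "category"})
    if missing := {"id", "sex", "category"} - set(df.columns):
        raise PhenotypeError(f"phenotype file {path} lacks columns: {sorted(missing)}")
    df["sex"] = df["sex"].str.strip().str.upper()
    raw = df["category"].str.strip()
    labels: Mapping[int, object] | None = None
    if raw.str.fullmatch(r"-?\d+").all():
        df["category"] = raw.astype(int)
    else:
        codes = raw.map(classify_position)
        n_multi = int(codes.isna().sum())
        if n_multi:
            logger.info("dropped %d multi-whorl horse(s) from the position trait", n_multi)
        df = df.loc[codes.notna()].copy()
        df["category"] = codes.loc[codes.notna()].astype(int)
        labels = {v: k for k, v in POSITION_CODES.items()}
    return TraitDataset(trait_name, df[["id", "sex", "category"]], category_labels=labels)


@dataclass
class HalfSibFamily:
    """Offspring sharing one sire; sire_id is None for unknown-sire singletons."""

    sire_id: str | None
    member_ids: list[str]
    category_counts: dict[int, int]

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def is_monomorphic(self) -> bool:
        return sum(v > 0 for v in self.category_counts.values()) == 1


def build_halfsib_families(data: TraitDataset, ped: Pedigree) -> list[HalfSibFamily]:
    """Group phenotyped individuals into paternal half-sib families.

    One family per distinct known sire; individuals whose sire is unknown
    each form a singleton family.
    """
    missing = [i for i in data.ids if i not in ped]
    if missing:
        raise PhenotypeError(f"phenotyped individual(s) missing from pedigree: {missing[:10]}")
    groups: dict[object, HalfSibFamily] = {}
    for iid, cat in zip(data.ids, data.categories):
        sire = ped.sire_of(iid)
        key = ("sire", sire) if sire is not None else ("singleton", iid)
        fam = groups.get(key)
        if fam is None:
            fam = groups[key] = HalfSibFamily(sire, [], {})
        fam.member_ids.append(iid)
        fam.category_counts[int(cat)] = fam.category_counts.get(int(cat), 0) + 1
    return list(groups.values())


@dataclass
class FilterConfig:
    """Informativeness filters applied before fitting.

    The study used min_family_size 20 for whorl position and 10 for whorl
    number, and dropped families monomorphic for the trait.
    """

    min_family_size: int = 1
    drop_monomorphic_families: bool = True
    retained_categories: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.min_family_size < 1:
            raise PhenotypeError("min_family_size must be >= 1")
        if self.retained_categories is not None:
            self.retained_categories = frozenset(int(c) for c in self.retained_categories)


@dataclass
class ExclusionReport:
    """Per-rule exclusion counts; retained + excluded equals the input count."""

    n_input: int
    excluded_category: int
    excluded_small_family: int
    excluded_monomorphic: int
    n_retained: int

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "excluded_by_category_restriction": self.excluded_category,
            "excluded_in_small_families": self.excluded_small_family,
            "excluded_in_monomorphic_families": self.excluded_monomorphic,
            "retained": self.n_retained,
        }


def apply_filters(
    data: TraitDataset,
    families: Sequence[HalfSibFamily],
    cfg: FilterConfig,
) -> tuple[TraitDataset, ExclusionReport]:
    """Apply category restriction, family-size, and monomorphism filters.

    Rules run in order: (c) drop individuals outside retained_categories,
    (a) drop all members of paternal half-sib families smaller than
    min_family_size, (b) drop all members of families monomorphic for the
    trait.  Family sizes and monomorphism are re-evaluated on the
    category-restricted data, since restriction changes both.
    """
    df = data.observations
    sire_of: dict[str, object] = {}
    for fam in families:
        for iid in fam.member_ids:
            sire_of[iid] = fam.sire_id if fam.sire_id is not None else ("singleton", iid)
    missing = [i for i in df["id"] if i not in sire_of]
    if missing:
        raise PhenotypeError(f"families do not cover individual(s): {missing[:10]}")
    fam_key = df["id"].map(sire_of)
    cat = df["category"]

    if cfg.retained_categories is not None:
        keep_c = cat.isin(cfg.retained_categories)
    else:
        keep_c = pd.Series(True, index=df.index)
    n_c = int((~keep_c).sum())

    sizes = fam_key[keep_c].value_counts()
    keep_a = keep_c & fam_key.map(sizes).fillna(0).ge(cfg.min_family_size)
    n_a = int((keep_c & ~keep_a).sum())

    if cfg.drop_monomorphic_families:
        nuniq = df.loc[keep_a].groupby(fam_key[keep_a])["category"].nunique()
        keep_b = keep_a & fam_key.map(nuniq).fillna(0).ge(2)
    else:
        keep_b = keep_a
    n_b = int((keep_a & ~keep_b).sum())

    report = ExclusionReport(
        n_input=len(df),
        excluded_category=n_c,
        excluded_small_family=n_a,
        excluded_monomorphic=n_b,
        n_retained=int(keep_b.sum()),
    )
    if report.n_retained == 0:
        raise PhenotypeError("filters removed every observation")
    filtered = TraitDataset(
        data.trait_name,
        df.loc[keep_b],
        category_labels={c: data.category_labels.get(c, c)
                         for c in np.unique(df.loc[keep_b, "category"])},
    )
    return filtered, report


@dataclass
class FrequencyTable:
    """Per-category counts and percentages (rounded half-up to 2 decimals)."""

    labels: list[object]
    counts: list[int]
    percentages: list[float]
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": self.labels, "count": self.counts, "percentage": self.percentages}
        )

    @classmethod
    def from_counts(cls, counts: Mapping[object, int]) -> "FrequencyTable":
        labels = list(counts.keys())
        values = [int(counts[k]) for k in labels]
        total = sum(values)
        if total <= 0:
            raise PhenotypeError("frequency table requires a positive total count")
        pct = [
            float(
                (Decimal(100 * v) / Decimal(total)).quantize(
                    Decimal("0.01"), rounding=ROUND_HALF_UP
                )
            )
            for v in values
        ]
        return cls(labels=labels, counts=values, percentages=pct, total=total)


def frequency_table(data: TraitDataset) -> FrequencyTable:
    """Per-category count and percentage table for an ordinal trait dataset."""
    cats, counts = np.unique(data.categories, return_counts=True)
    return FrequencyTable.from_counts(
        {data.category_labels.get(int(c), int(c)): int(n) for c, n in zip(cats, counts)}
    )
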