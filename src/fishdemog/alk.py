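"""Age-length keys: building from aged fish and assigning ages to unaged fish.

An age-length key (ALK) tabulates, per length bin, the proportion of aged
fish in each age class. Ages are then assigned to measured-but-unaged fish by
sampling (or deterministically allocating) from the proportion row of their
length bin — the standard device for transferring ages from a subsampled aged
collection to a large length-frequency sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .records import FishRecord

__all__ = [
    "AgeLengthKey",
    "build_alk",
    "assign_ages",
    "age_frequency",
]

POOLED = "pooled"


@dataclass
class AgeLengthKey:
    """Per-stratum matrix of age proportions by length bin.

    ``bin_edges`` are left-closed/right-open cm boundaries; ``counts`` and
    ``props`` are (n_bins, n_ages) with ``ages`` labelling the columns.
    Non-empty rows of ``props`` sum to 1.
    """

    stratum: tuple | str
    bin_edges: np.ndarray
    ages: np.ndarray
    counts: np.ndarray
    props: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.ages = np.asarray(self.ages, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.props is None:
            totals = self.counts.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore"):
                self.props = np.where(totals > 0, self.counts / totals, 0.0)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def row_is_empty(self) -> np.ndarray:
        return self.counts.sum(axis=1) == 0

    def bin_index(self, tl_cm: float) -> int:
        """Index of the length bin holding ``tl_cm`` (may be out of range)."""
        width = self.bin_edges[1] - self.bin_edges[0]
        return int(np.floor((tl_cm - self.bin_edges[0]) / width))

    def to_frame(self) -> pd.DataFrame:
        idx = pd.IntervalIndex.from_breaks(self.bin_edges, closed="left", name="tl_cm")
        return pd.DataFrame(self.props, index=idx, columns=self.ages)


def _stratum_key(rec: FishRecord, by: str):
    if by == "pooled":
        return POOLED
    if by == "sex":
        return (rec.sex,)
    if by == "morph":
        return (rec.morph,)
    if by == "sex_morph":
        return (rec.sex, rec.morph)
    raise ValueError(f"unknown stratification {by!r}")


def build_alk(aged: Iterable[FishRecord], bin_cm: float = 1.0,
              by: str = "pooled") -> dict:
    """Build age-length keys from directly aged fish.

    Parameters
    ----------
    aged : records with ``age_yr`` set (direct readings or simulated truth)
    bin_cm : length-bin width in cm (left-closed, right-open bins)
    by : {"pooled", "sex", "morph", "sex_morph"}

    Returns a dict mapping stratum key to :class:`AgeLengthKey`.
    """
    if bin_cm <= 0:
        raise ValueError("bin_cm must be positive")
    groups: dict = {}
    for rec in aged:
        if rec.age_yr is None:
            continue
        if rec.age_source not in (None, "read", "simulated"):
            continue  # never build a key from key-assigned ages
        groups.setdefault(_stratum_key(rec, by), []).append(rec)
    if not groups:
        raise ValueError("no aged records to build a key from")
    keys = {}
    for stratum, recs in groups.items():
        tl = np.array([r.tl_cm for r in recs])
        age = np.array([r.age_yr for r in recs], dtype=int)
        lo = np.floor(tl.min() / bin_cm) * bin_cm
        hi = np.floor(tl.max() / bin_cm) * bin_cm + bin_cm
        edges = np.arange(lo, hi + bin_cm / 2, bin_cm)
        ages = np.arange(age.min(), age.max() + 1)
        counts = np.zeros((len(edges) - 1, len(ages)))
        bin_idx = np.clip(((tl - lo) / bin_cm).astype(int), 0, len(edges) - 2)
        for b, a in zip(bin_idx, age - age.min()):
            counts[b, a] += 1
        keys[stratum] = AgeLengthKey(stratum=stratum, bin_edges=edges,
                                     ages=ages, counts=counts)
    return keys


@dataclass
class AssignmentReport:
    """Bookkeeping from an ALK age-assignment pass."""

    n_assigned: int = 0
    n_borrowed_bin: int = 0  # used a nearest populated bin (<= 2 bins away)
    unassigned: list = field(default_factory=list)  # fish_ids out of key range


def _resolve_row(key: AgeLengthKey, tl_cm: float, max_borrow: int = 2):
    """Proportion row for a length, borrowing a nearby bin when empty.

    Returns (row, borrowed) or (None, False) if no populated bin lies within
    ``max_borrow`` bins of the fish's own bin.
    """
    b = key.bin_index(tl_cm)
    empty = key.row_is_empty()
    if 0 <= b < key.n_bins and not empty[b]:
        return key.props[b], False
    for off in range(1, max_borrow + 1):
        for cand in (b - off, b + off):
            if 0 <= cand < key.n_bins and not empty[cand]:
                return key.props[cand], True
    return None, False


def assign_ages(unaged: Iterable[FishRecord], keys: dict, seed: int | None = None,
                by: str | None = None, method: str = "stochastic"):
    """Assign ages to unaged fish from their stratum's age-length key.

    ``method="stochastic"`` draws each fish's age from its length bin's
    proportion row (seeded); ``method="fractional"`` allocates fish within
    each (stratum, bin) deterministically in proportion to the row (largest
    remainder), useful for fully reproducible pipelines without a seed.

    Fish whose length lies more than 2 bins outside the populated range of
    the key are left unaged and reported. Only age fields change; length, sex
    and morph are untouched.

    Returns ``(records, report)`` where records is a new list (inputs are not
    mutated) and report is an :class:`AssignmentReport`.
    """
    if method not in ("stochastic", "fractional"):
        raise ValueError(f"unknown method {method!r}")
    unaged = list(unaged)
    if by is None:
        by = "pooled" if POOLED in keys else "sex_morph"
    rng = np.random.default_rng(seed)
    report = AssignmentReport()
    out: list[FishRecord] = [None] * len(unaged)

    if method == "fractional":
        # group fish by (stratum, resolved row) and allocate deterministically
        buckets: dict = {}
        for i, rec in enumerate(unaged):
            stratum = _stratum_key(rec, by)
            if stratum not in keys:
                raise KeyError(f"no age-length key for stratum {stratum!r}")
            key = keys[stratum]
            row, borrowed = _resolve_row(key, rec.tl_cm)
            if row is None:
                report.unassigned.append(rec.fish_id)
                out[i] = replace(rec)
                continue
            if borrowed:
                report.n_borrowed_bin += 1
            buckets.setdefault((stratum, key.bin_index(rec.tl_cm)), []).append((i, row))
        for (_, _), members in sorted(buckets.items()):
            row = members[0][1]
            key_ages = keys[_stratum_key(unaged[members[0][0]], by)].ages
            m = len(members)
            ideal = row * m
            alloc = np.floor(ideal).astype(int)
            remainder = ideal - alloc
            short = m - alloc.sum()
            for j in np.argsort(-remainder)[:short]:
                alloc[j] += 1
            ages_out = np.repeat(key_ages, alloc)
            # stable order: fish sorted by length get ages sorted ascending
            order = sorted(range(m), key=lambda j: unaged[members[j][0]].tl_cm)
            for rank, j in enumerate(order):
                i = members[j][0]
                out[i] = replace(unaged[i], age_yr=int(ages_out[rank]),
                                 age_source="alk_assigned")
                report.n_assigned += 1
    else:
        for i, rec in enumerate(unaged):
            stratum = _stratum_key(rec, by)
            if stratum not in keys:
                raise KeyError(f"no age-length key for stratum {stratum!r}")
            key = keys[stratum]
            row, borrowed = _resolve_row(key, rec.tl_cm)
            if row is None:
                report.unassigned.append(rec.fish_id)
                out[i] = replace(rec)
                continue
            if borrowed:
                report.n_borrowed_bin += 1
            age = int(rng.choice(key.ages, p=row))
            out[i] = replace(rec, age_yr=age, age_source="alk_assigned")
            report.n_assigned += 1
    return out, report


def age_frequency(records: Iterable[FishRecord]) -> pd.Series:
    """Dense counts per integer age from min to max observed (interior zeros kept)."""
    ages = [r.age_yr for r in records]
    if any(a is None for a in ages):
        raise ValueError("all records must be aged before building an age frequency")
    if not ages:
        return pd.Series(dtype=int, name="count")
    ages = np.asarray(ages, dtype=int)
    idx = np.arange(ages.min(), ages.max() + 1)
    counts = pd.Series(0, index=idx, name="count")
    vals, n = np.unique(ages, return_counts=True)
    counts.loc[vals] = n
    counts.index.name = "age"
    return counts
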