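"""Experimental design: item rosters, bundle enumeration, trial schedules.

The default design mirrors a three-day valuation study: 40 unique consumer
items (half food, half trinkets), 20 presented per day (10 shared across all
days plus 10 fresh), every within-day pair — including self-pairs — forming
the day's 210 bundles, and an in-scanner choice task of 5 runs x 62 trials
per day (each item once per run, the 210 bundles split evenly across runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

FOOD = "food"
TRINKET = "trinket"
CATEGORIES = (FOOD, TRINKET)

BUNDLE_TYPES = ("food", "trinket", "mixed", "same_item")


class DesignError(ValueError):
    """Raised for infeasible design configurations."""


@dataclass(frozen=True)
class Bundle:
    """An unordered pair of items (canonical order: left_item <= right_item)."""

    left_item: int
    right_item: int
    bundle_type: str

    def __post_init__(self) -> None:
        if self.left_item > self.right_item:
            raise DesignError("Bundle items must be in canonical order")
        if self.bundle_type not in BUNDLE_TYPES:
            raise DesignError(f"unknown bundle_type {self.bundle_type!r}")


@dataclass
class StimulusCatalog:
    """Item identities, categories and the day rosters they appear on."""

    items: pd.DataFrame  # columns: item_id, category
    day_rosters: dict[int, list[int]] = field(default_factory=dict)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_days(self) -> int:
        return len(self.day_rosters)

    def category_of(self, item_id: int) -> str:
        row = self.items.loc[self.items.item_id == item_id, "category"]
        if row.empty:
            raise KeyError(f"unknown item {item_id}")
        return row.iloc[0]


def build_item_roster(
    n_total: int = 40,
    n_shared: int = 10,
    n_new_per_day: int = 10,
    n_days: int = 3,
    seed: int = 0,
) -> StimulusCatalog:
    """Build the stimulus catalog with shared and day-specific items.

    Each day's roster holds ``n_shared + n_new_per_day`` items with an even
    food/trinket split; the shared subset appears on all days.
    """
    if n_total != n_shared + n_days * n_new_per_day:
        raise DesignError(
            f"n_total={n_total} must equal n_shared + n_days*n_new_per_day "
            f"= {n_shared + n_days * n_new_per_day}"
        )
    per_day = n_shared + n_new_per_day
    if n_shared % 2 or n_new_per_day % 2:
        if per_day > 1:  # single-item degenerate roster allowed
            raise DesignError("even category split requires even shared/new counts")
    rng = np.random.default_rng(seed)

    item_ids = np.arange(n_total)
    # Alternate categories so every contiguous even-sized block is balanced.
    categories = [CATEGORIES[i % 2] for i in range(n_total)]
    items = pd.DataFrame({"item_id": item_ids, "category": categories})

    shared = list(item_ids[:n_shared])
    rosters: dict[int, list[int]] = {}
    cursor = n_shared
    for day in range(1, n_days + 1):
        fresh = list(item_ids[cursor : cursor + n_new_per_day])
        cursor += n_new_per_day
        roster = shared + fresh
        rng.shuffle(roster)
        rosters[day] = roster
    return StimulusCatalog(items=items, day_rosters=rosters)


def enumerate_bundles(
    day_roster: list[int], catalog: StimulusCatalog | None = None
) -> list[Bundle]:
    """All unordered item pairs plus self-pairs for one day's roster.

    For an n-item roster this yields n(n-1)/2 + n bundles (210 for n=20).
    """
    if len(set(day_roster)) != len(day_roster):
        raise DesignError("duplicate item ids in roster")
    if not day_roster:
        raise DesignError("empty roster")

    def btype(i: int, j: int) -> str:
        if i == j:
            return "same_item"
        if catalog is None:
            return "mixed"
        ci, cj = catalog.category_of(i), catalog.category_of(j)
        return ci if ci == cj else "mixed"

    bundles = [Bundle(i, i, "same_item") for i in sorted(day_roster)]
    for i, j in combinations(sorted(day_roster), 2):
        bundles.append(Bundle(i, j, btype(i, j)))
    return bundles


def compute_reference_amounts(
    wtp: pd.DataFrame, subject_id: int, day: int
) -> tuple[float, float]:
    """Per-category reference money: the subject's median WTP bid that day.

    Items are choosed against the median item bid and bundles against the
    median bundle bid; even counts take the midpoint of the two central
    order statistics.
    """
    sel = wtp[(wtp.subject_id == subject_id) & (wtp.day == day)]
    item_bids = sel.loc[sel.trial_type == "item", "bid"]
    bundle_bids = sel.loc[sel.trial_type == "bundle", "bid"]
    if item_bids.empty or bundle_bids.empty:
        raise DesignError(
            f"subject {subject_id} day {day}: empty item or bundle bid set"
        )
    return float(item_bids.median()), float(bundle_bids.median())


def build_trial_schedule(
    catalog: StimulusCatalog, wtp: pd.DataFrame, seed: int = 0, n_runs: int = 5
) -> pd.DataFrame:
    """Interleaved choice-task schedule for every subject in the WTP table.

    Per day: ``n_runs`` runs; each roster item appears once per run; the
    day's bundles are partitioned evenly at random across runs; item and
    bundle trials are shuffled together within a run. Reference amounts are
    the per-category medians of that subject/day's bids.

    Returns a tidy frame with one row per trial (columns: subject_id, day,
    run, trial_index, trial_type, item_id, left_item, right_item,
    bundle_type, item_side, reference_amount).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for subject_id in sorted(wtp.subject_id.unique()):
        for day, roster in catalog.day_rosters.items():
            sel = wtp[(wtp.subject_id == subject_id) & (wtp.day == day)]
            _check_bids_present(sel, roster, catalog, subject_id, day)
            item_ref, bundle_ref = compute_reference_amounts(wtp, subject_id, day)
            bundles = enumerate_bundles(roster, catalog)
            if len(bundles) % n_runs:
                raise DesignError(
                    f"{len(bundles)} bundles not divisible into {n_runs} runs"
                )
            per_run = len(bundles) // n_runs
            order = rng.permutation(len(bundles))
            for run in range(1, n_runs + 1):
                chunk = [bundles[k] for k in order[(run - 1) * per_run : run * per_run]]
                trials = [("item", i, None) for i in roster] + [
                    ("bundle", None, b) for b in chunk
                ]
                rng.shuffle(trials)
                sides = _balanced_sides(len(trials), rng)
                for t, (kind, item, bundle) in enumerate(trials, start=1):
                    rows.append(
                        {
                            "subject_id": subject_id,
                            "day": day,
                            "run": run,
                            "trial_index": t,
                            "trial_type": kind,
                            "item_id": item if kind == "item" else pd.NA,
                            "left_item": bundle.left_item if bundle else pd.NA,
                            "right_item": bundle.right_item if bundle else pd.NA,
                            "bundle_type": bundle.bundle_type if bundle else pd.NA,
                            "item_side": sides[t - 1],
                            "reference_amount": item_ref
                            if kind == "item"
                            else bundle_ref,
                        }
                    )
    return pd.DataFrame(rows)


def _balanced_sides(n: int, rng: np.random.Generator) -> list[str]:
    sides = ["left", "right"] * (n // 2) + (["left"] if n % 2 else [])
    rng.shuffle(sides)
    return sides


def _check_bids_present(sel, roster, catalog, subject_id, day) -> None:
    have_items = set(sel.loc[sel.trial_type == "item", "item_id"].dropna().astype(int))
    missing = [i for i in roster if i not in have_items]
    if missing:
        raise DesignError(
            f"subject {subject_id} day {day}: missing item bids for {missing[:5]}"
        )
    have_pairs = {
        (int(l), int(r))
        for l, r in zip(
            sel.loc[sel.trial_type == "bundle", "left_item"].dropna(),
            sel.loc[sel.trial_type == "bundle", "right_item"].dropna(),
        )
    }
    for b in enumerate_bundles(roster, catalog):
        if (b.left_item, b.right_item) not in have_pairs:
            raise DesignError(
                f"subject {subject_id} day {day}: missing bundle bid "
                f"({b.left_item},{b.right_item})"
            )
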