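"""Cafe menu registry.

The assessment protocol draws customer orders from a fixed catalogue of
cafe food and beverage items.  The packaged default catalogue holds 31
food items (savoury and sweet) and 9 beverages.  A subset of items are
*fillers*: they are never orderable and appear only in the food-counter
lineup, where they act as recognition distractors.

Items may carry optional ``recognition_meta`` — survey-derived
recognisability fractions.  This metadata is purely descriptive and never
influences sampling or scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

from .errors import CapacityError, FixtureFormatError

CATEGORIES = ("savoury_food", "sweet_food", "beverage")

__all__ = ["MenuItem", "Menu", "load_default_menu", "load_menu", "sample_order_items"]


@dataclass(frozen=True)
class MenuItem:
    """A single catalogue entry.

    Parameters
    ----------
    item_id : str
        Stable short token, unique within a menu.
    display_name : str
        Human-readable name shown to respondents.
    category : str
        One of ``savoury_food``, ``sweet_food``, ``beverage``.
    is_filler : bool
        Fillers are counter-only distractors and never orderable.
    recognition_meta : mapping, optional
        Survey recognisability fractions (keys among ``overall``,
        ``younger``, ``older``; values in [0, 1]).  Documentation only.
    """

    item_id: str
    display_name: str
    category: str
    is_filler: bool = False
    recognition_meta: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise FixtureFormatError(
                f"item {self.item_id!r}: category {self.category!r} is not one of {CATEGORIES}"
            )
        if self.recognition_meta is not None:
            for k, v in self.recognition_meta.items():
                if not (0.0 <= float(v) <= 1.0):
                    raise FixtureFormatError(
                        f"item {self.item_id!r}: recognition_meta[{k!r}] = {v} outside [0, 1]"
                    )

    @property
    def is_food(self) -> bool:
        return self.category in ("savoury_food", "sweet_food")

    @property
    def is_beverage(self) -> bool:
        return self.category == "beverage"


@dataclass(frozen=True)
class Menu:
    """Ordered collection of :class:`MenuItem` with unique ids."""

    items: tuple[MenuItem, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FixtureFormatError(f"duplicate item_id values in menu: {dupes}")

    def __iter__(self) -> Iterator[MenuItem]:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> MenuItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def __contains__(self, item_id: str) -> bool:
        return any(it.item_id == item_id for it in self.items)

    @property
    def foods(self) -> tuple[MenuItem, ...]:
        return tuple(it for it in self.items if it.is_food)

    @property
    def beverages(self) -> tuple[MenuItem, ...]:
        return tuple(it for it in self.items if it.is_beverage)

    @property
    def fillers(self) -> tuple[MenuItem, ...]:
        return tuple(it for it in self.items if it.is_filler)

    def orderable(self, category_group: str) -> tuple[MenuItem, ...]:
        """Non-filler items of a category group (``food`` or ``beverage``)."""
        if category_group == "food":
            return tuple(it for it in self.foods if not it.is_filler)
        if category_group == "beverage":
            return tuple(it for it in self.beverages if not it.is_filler)
        raise ValueError(f"unknown category group {category_group!r}")


_REQUIRED_FIELDS = ("item_id", "display_name", "category")


def _item_from_record(rec: object, index: int) -> MenuItem:
    if not isinstance(rec, dict):
        raise FixtureFormatError(f"menu record {index} is not an object")
    for f in _REQUIRED_FIELDS:
        if f not in rec:
            raise FixtureFormatError(f"menu record {index} missing field {f!r}")
    return MenuItem(
        item_id=str(rec["item_id"]),
        display_name=str(rec["display_name"]),
        category=rec["category"],
        is_filler=bool(rec.get("is_filler", False)),
        recognition_meta=rec.get("recognition_meta"),
    )


def load_menu(path: str | Path) -> Menu:
    """Load a menu from a JSON array of item records."""
    with open(path, encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FixtureFormatError(f"menu fixture is not valid JSON: {exc}") from exc
    if not isinstance(raw, list):
        raise FixtureFormatError("menu fixture must be a JSON array of item records")
    return Menu(tuple(_item_from_record(rec, i) for i, rec in enumerate(raw)))


def load_default_menu() -> Menu:
    """Load the packaged default cafe catalogue (31 foods, 9 beverages)."""
    ref = resources.files("cafescreen.data").joinpath("menu.json")
    with resources.as_file(ref) as path:
        return load_menu(path)


def sample_order_items(
    menu: Menu,
    n_food: int,
    n_drink: int,
    rng: np.random.Generator,
) -> list[MenuItem]:
    """Draw distinct, non-filler order items from the menu.

    Sampling is without replacement within each category group, so the
    returned items are distinct.  Identical generator state yields an
    identical selection.

    Raises
    ------
    CapacityError
        If the menu does not hold enough non-filler items of a group.
    """
    picked: list[MenuItem] = []
    for group, n in (("food", n_food), ("beverage", n_drink)):
        pool = menu.orderable(group)
        if n > len(pool):
            raise CapacityError(
                f"requested {n} {group} items but only {len(pool)} non-filler "
                f"{group} items are available"
            )
        if n > 0:
            idx = rng.choice(len(pool), size=n, replace=False)
            picked.extend(pool[i] for i in idx)
    return picked
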