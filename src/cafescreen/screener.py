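"""Reference cognitive screener (TICS-M style) scoring and classification.

A 23-item telephone-style screener with a 39-point maximum, covering
orientation, attention/working memory (serial subtraction and counting
backwards), language, and immediate plus delayed recall of a 10-word
list.  Totals at or below 21 classify the respondent as showing
possible cognitive impairment.

The published instrument fixes the item count, the maximum, the domains
and the cutoff, but not the per-item point allocation; the packaged
default form is therefore a documented stand-in allocation (10
orientation points, 8 attention/working-memory, 5 language, 10
immediate-word, 6 delayed-recall) and can be replaced by any JSON form
with the same structural invariants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import FixtureFormatError, FormMismatchError, PointRangeError

__all__ = [
    "SCREENER_MAX",
    "IMPAIRMENT_CUTOFF",
    "DOMAINS",
    "ScreenerItem",
    "ScreenerForm",
    "ScreenerResponse",
    "load_default_form",
    "load_form",
    "score_screener",
    "classify_impairment",
]

SCREENER_MAX = 39
IMPAIRMENT_CUTOFF = 21
N_ITEMS = 23
DOMAINS = (
    "orientation",
    "attention_working_memory",
    "language",
    "memory_immediate",
    "memory_delayed",
)


@dataclass(frozen=True)
class ScreenerItem:
    item_id: str
    domain: str
    max_points: int

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise FixtureFormatError(
                f"screener item {self.item_id!r}: domain {self.domain!r} "
                f"is not one of {DOMAINS}"
            )
        if self.max_points < 1:
            raise FixtureFormatError(
                f"screener item {self.item_id!r}: max_points must be >= 1"
            )


@dataclass(frozen=True)
class ScreenerForm:
    """Ordered screener items; exactly 23 items summing to 39 points."""

    items: tuple[ScreenerItem, ...]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(ids) != len(set(ids)):
            raise FixtureFormatError("screener form has duplicate item ids")
        if len(self.items) != N_ITEMS:
            raise FixtureFormatError(
                f"screener form must have exactly {N_ITEMS} items, got {len(self.items)}"
            )
        total = sum(it.max_points for it in self.items)
        if total != SCREENER_MAX:
            raise FixtureFormatError(
                f"screener form max points must sum to {SCREENER_MAX}, got {total}"
            )

    @property
    def max_total(self) -> int:
        return sum(it.max_points for it in self.items)

    def item(self, item_id: str) -> ScreenerItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)


#: per-item earned points, keyed by item_id
ScreenerResponse = Mapping[str, int]


def load_form(path: str | Path) -> ScreenerForm:
    """Load a screener form from a JSON array of item records."""
    with open(path, encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FixtureFormatError(f"screener form is not valid JSON: {exc}") from exc
    if not isinstance(raw, list):
        raise FixtureFormatError("screener form must be a JSON array of item records")
    items = []
    for i, rec in enumerate(raw):
        for f in ("item_id", "domain", "max_points"):
            if f not in rec:
                raise FixtureFormatError(f"screener item record {i} missing field {f!r}")
        items.append(ScreenerItem(str(rec["item_id"]), rec["domain"], int(rec["max_points"])))
    return ScreenerForm(tuple(items))


def load_default_form() -> ScreenerForm:
    """Load the packaged default 23-item, 39-point form."""
    ref = resources.files("cafescreen.data").joinpath("screener_form.json")
    with resources.as_file(ref) as path:
        return load_form(path)


def score_screener(form: ScreenerForm, response: ScreenerResponse) -> int:
    """Sum earned points over the form; total lies in [0, 39].

    The response must cover every form item exactly once; earned points
    may not exceed an item's maximum.
    """
    form_ids = {it.item_id for it in form.items}
    resp_ids = set(response)
    if resp_ids != form_ids:
        missing = sorted(form_ids - resp_ids)
        extra = sorted(resp_ids - form_ids)
        raise FormMismatchError(
            f"response does not match form (missing items: {missing}, extra: {extra})"
        )
    total = 0
    for it in form.items:
        earned = int(response[it.item_id])
        if not (0 <= earned <= it.max_points):
            raise PointRangeError(
                f"item {it.item_id!r}: earned {earned} outside [0, {it.max_points}]"
            )
        total += earned
    return total


def classify_impairment(total: int) -> bool:
    """True iff the screener total indicates possible cognitive impairment (<= 21)."""
    if not (0 <= total <= SCREENER_MAX):
        raise PointRangeError(
            f"screener total {total} outside [0, {SCREENER_MAX}]"
        )
    return total <= IMPAIRMENT_CUTOFF
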