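"""Five-level task protocol and ground-truth session scripts.

The assessment ladder has five levels of increasing memory load: 2, 4,
6, 8 and 16 ordered items.  Levels 1–4 are food-only; at level 5 each of
eight customers orders one food and one drink.  Customers sit at up to
four tables of two, and every level interposes a ~120 s distraction task
between immediate and delayed recall.

:func:`generate_script` expands a protocol into the ground truth of one
session: which item each customer ordered, where they sit, and the
counter lineup (ordered items plus filler-first distractors) shown at
the delayed-recognition phase.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import CapacityError, FixtureFormatError
from .menu import Menu, MenuItem, sample_order_items

__all__ = [
    "LevelConfig",
    "ProtocolConfig",
    "Order",
    "LevelScript",
    "SessionScript",
    "default_protocol",
    "load_protocol",
    "generate_script",
]

#: (n_food_orders, n_drink_orders) for the default levels 1..5
DEFAULT_LOADS = ((2, 0), (4, 0), (6, 0), (8, 0), (8, 8))
DEFAULT_DISTRACTION_SECONDS = 120.0
DEFAULT_COUNTER_DISTRACTORS = 4
MAX_TABLES = 4
CUSTOMERS_PER_TABLE = 2


@dataclass(frozen=True)
class LevelConfig:
    """Memory load and layout of one level."""

    level: int
    n_food_orders: int
    n_drink_orders: int
    n_tables: int
    customers_per_table: int = CUSTOMERS_PER_TABLE
    distraction_seconds: float = DEFAULT_DISTRACTION_SECONDS
    n_counter_distractors: int = DEFAULT_COUNTER_DISTRACTORS

    def __post_init__(self) -> None:
        if self.level < 1:
            raise FixtureFormatError(f"level index must be >= 1, got {self.level}")
        if self.n_drink_orders not in (0, self.n_food_orders):
            # every customer orders the same shape: food only, or food + drink
            raise FixtureFormatError(
                f"level {self.level}: n_drink_orders must be 0 or equal to "
                f"n_food_orders, got {self.n_drink_orders}"
            )
        if self.n_tables * self.customers_per_table < self.n_customers:
            raise FixtureFormatError(
                f"level {self.level}: {self.n_tables} tables x "
                f"{self.customers_per_table} seats cannot hold {self.n_customers} customers"
            )
        if self.distraction_seconds <= 0:
            raise FixtureFormatError(
                f"level {self.level}: distraction_seconds must be positive"
            )

    @property
    def n_customers(self) -> int:
        """One ordering customer per food order."""
        return self.n_food_orders

    @property
    def n_items(self) -> int:
        """Total ordered items (foods + drinks) — the level's memory load."""
        return self.n_food_orders + self.n_drink_orders


@dataclass(frozen=True)
class ProtocolConfig:
    """Full session protocol: levels, discontinuation threshold, tutorial flag."""

    levels: tuple[LevelConfig, ...]
    discontinuation_threshold: float = 0.5
    include_tutorial: bool = True

    def __post_init__(self) -> None:
        expected = list(range(1, len(self.levels) + 1))
        if [lv.level for lv in self.levels] != expected:
            raise FixtureFormatError(
                "levels must be strictly ordered by level index starting at 1"
            )
        if not (0.0 < self.discontinuation_threshold < 1.0):
            raise FixtureFormatError("discontinuation_threshold must lie in (0, 1)")

    def level(self, index: int) -> LevelConfig:
        return self.levels[index - 1]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def max_total_points(self) -> int:
        """Ceiling of the grand total: 5 unit-point metrics per ordered item."""
        from .scoring import N_METRICS

        return N_METRICS * sum(lv.n_items for lv in self.levels)

    def config_hash(self) -> str:
        """Short stable hash of the protocol, embedded in output headers."""
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def default_protocol() -> ProtocolConfig:
    """The default five-level ladder: 2/4/6/8/16 items, 120 s distraction."""
    levels = []
    for i, (nf, nd) in enumerate(DEFAULT_LOADS, start=1):
        n_tables = min(MAX_TABLES, math.ceil(nf / CUSTOMERS_PER_TABLE))
        levels.append(LevelConfig(level=i, n_food_orders=nf, n_drink_orders=nd, n_tables=n_tables))
    return ProtocolConfig(levels=tuple(levels))


def load_protocol(path: str | Path) -> ProtocolConfig:
    """Load a protocol from a JSON document mirroring :class:`ProtocolConfig`."""
    with open(path, encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FixtureFormatError(f"protocol config is not valid JSON: {exc}") from exc
    if not isinstance(raw, dict) or "levels" not in raw:
        raise FixtureFormatError("protocol config must be an object with a 'levels' array")
    levels = tuple(LevelConfig(**lv) for lv in raw["levels"])
    kwargs = {k: raw[k] for k in ("discontinuation_threshold", "include_tutorial") if k in raw}
    return ProtocolConfig(levels=levels, **kwargs)


@dataclass(frozen=True)
class Order:
    """One customer's order: a food item and, at drink levels, a drink."""

    order_id: str
    level: int
    table_index: int  # 1-based
    customer_index: int  # 1-based within table
    food_item: str
    drink_item: Optional[str] = None

    @property
    def item_ids(self) -> tuple[str, ...]:
        return (self.food_item,) if self.drink_item is None else (self.food_item, self.drink_item)

    @property
    def seat(self) -> tuple[int, int]:
        return (self.table_index, self.customer_index)


@dataclass(frozen=True)
class LevelScript:
    """Ground truth of one level: orders and the counter lineup."""

    config: LevelConfig
    orders: tuple[Order, ...]
    counter_lineup: tuple[str, ...]

    @property
    def level(self) -> int:
        return self.config.level

    @property
    def ordered_item_ids(self) -> tuple[str, ...]:
        return tuple(i for o in self.orders for i in o.item_ids)

    def seat_of(self, item_id: str) -> tuple[int, int]:
        """True (table, customer) destination of an ordered item."""
        for o in self.orders:
            if item_id in o.item_ids:
                return o.seat
        raise KeyError(item_id)


@dataclass(frozen=True)
class SessionScript:
    """Deterministic ground truth of a whole session."""

    protocol: ProtocolConfig
    levels: tuple[LevelScript, ...]
    seed: int

    def level(self, index: int) -> LevelScript:
        return self.levels[index - 1]


def _counter_lineup(
    menu: Menu,
    ordered: Sequence[MenuItem],
    n_distractors: int,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    """Ordered items plus distractors, fillers first, shuffled."""
    ordered_ids = {it.item_id for it in ordered}
    fillers = [it for it in menu.fillers if it.item_id not in ordered_ids]
    unused = [
        it for it in menu.items
        if not it.is_filler and it.item_id not in ordered_ids
    ]
    pool = fillers + unused
    if n_distractors > len(pool):
        raise CapacityError(
            f"requested {n_distractors} counter distractors but only "
            f"{len(pool)} unused items remain"
        )
    take = list(fillers[:n_distractors])
    n_more = n_distractors - len(take)
    if n_more > 0:
        idx = rng.choice(len(unused), size=n_more, replace=False)
        take.extend(unused[i] for i in idx)
    lineup = [it.item_id for it in ordered] + [it.item_id for it in take]
    perm = rng.permutation(len(lineup))
    return tuple(lineup[i] for i in perm)


def generate_script(menu: Menu, protocol: ProtocolConfig, seed: int) -> SessionScript:
    """Expand a protocol into a ground-truth session script.

    The same ``(menu, protocol, seed)`` triple always yields an identical
    script.  Order items are distinct within a level; customers are
    assigned to seats filling tables in order.
    """
    rng = np.random.default_rng(seed)
    level_scripts = []
    for cfg in protocol.levels:
        items = sample_order_items(menu, cfg.n_food_orders, cfg.n_drink_orders, rng)
        foods = [it for it in items if it.is_food]
        drinks = [it for it in items if it.is_beverage]
        orders = []
        for c in range(cfg.n_customers):
            table = c // cfg.customers_per_table + 1
            seat = c % cfg.customers_per_table + 1
            orders.append(
                Order(
                    order_id=f"L{cfg.level}O{c + 1}",
                    level=cfg.level,
                    table_index=table,
                    customer_index=seat,
                    food_item=foods[c].item_id,
                    drink_item=drinks[c].item_id if cfg.n_drink_orders else None,
                )
            )
        lineup = _counter_lineup(menu, items, cfg.n_counter_distractors, rng)
        level_scripts.append(LevelScript(config=cfg, orders=tuple(orders), counter_lineup=lineup))
    return SessionScript(protocol=protocol, levels=tuple(level_scripts), seed=seed)
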