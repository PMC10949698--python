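"""Session scoring: per-level metric points, subdomain totals, grand total.

Each ordered item can earn one point on each of five metrics:

* **immediate recall** — the item was reported to the chef right after
  presentation;
* **delayed recall** — the item was re-reported after the distraction
  interlude;
* **delayed recognition** — the item was picked out of the counter
  lineup;
* **table (spatial)** — the item was delivered to the correct table;
* **customer** — the item was delivered to the correct seat.

With the default five-level ladder (2/4/6/8/16 items) the level maxima
are 10, 20, 30, 40 and 80 points, each subdomain column sums to 36, the
two serving columns combine to 72, and the grand total ranges 0–180.

Wrong or extra claims are never penalised — they simply earn nothing —
and duplicate claims are collapsed, so each ordered item is credited at
most once per metric.

Four *accuracies* feed the discontinuation rule: immediate, delayed and
recognition accuracy are points over the level maximum; serving accuracy
counts an item only when **both** table and customer are correct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ResponseReferenceError
from .protocol import LevelConfig, LevelScript, SessionScript
from .session import ResponseSet, SessionLog

__all__ = [
    "N_METRICS",
    "MetricPoints",
    "LevelScore",
    "SessionScore",
    "score_level",
    "accuracies",
    "score_session",
]

#: unit-point metrics per ordered item
N_METRICS = 5


@dataclass(frozen=True)
class MetricPoints:
    """Points earned on each metric within one level."""

    immediate: int
    delayed: int
    recognition: int
    table: int
    customer: int

    @property
    def total(self) -> int:
        return self.immediate + self.delayed + self.recognition + self.table + self.customer


@dataclass(frozen=True)
class LevelScore:
    """Score of one level: metric points, the per-metric maximum, accuracies.

    ``n_served_correct`` counts items delivered to the correct table AND
    the correct customer; it drives the serving accuracy used by the
    discontinuation rule.
    """

    level: int
    points: MetricPoints
    max_per_metric: int
    n_served_correct: int

    @property
    def total(self) -> int:
        return self.points.total

    @property
    def max_total(self) -> int:
        return N_METRICS * self.max_per_metric

    @property
    def accuracy_immediate(self) -> float:
        return self.points.immediate / self.max_per_metric

    @property
    def accuracy_delayed(self) -> float:
        return self.points.delayed / self.max_per_metric

    @property
    def accuracy_recognition(self) -> float:
        return self.points.recognition / self.max_per_metric

    @property
    def accuracy_serving(self) -> float:
        return self.n_served_correct / self.max_per_metric


def accuracies(level_score: LevelScore) -> tuple[float, float, float, float]:
    """The four fractions (immediate, delayed, recognition, serving)."""
    return (
        level_score.accuracy_immediate,
        level_score.accuracy_delayed,
        level_score.accuracy_recognition,
        level_score.accuracy_serving,
    )


@dataclass(frozen=True)
class SessionScore:
    """Whole-session score: per-level scores, subdomain totals, grand total."""

    per_level: tuple[LevelScore, ...]
    immediate_total: int
    delayed_total: int
    recognition_total: int
    table_total: int
    customer_total: int
    grand_total: int
    levels_played: int
    total_minutes: float

    @property
    def spatial_combined_total(self) -> int:
        """Serving subdomain reported as table + customer points combined."""
        return self.table_total + self.customer_total

    def as_row(self) -> dict:
        """Flat record for tabular export."""
        return {
            "levels_played": self.levels_played,
            "immediate_total": self.immediate_total,
            "delayed_total": self.delayed_total,
            "recognition_total": self.recognition_total,
            "table_total": self.table_total,
            "customer_total": self.customer_total,
            "spatial_combined_total": self.spatial_combined_total,
            "grand_total": self.grand_total,
            "total_minutes": self.total_minutes,
        }


def _zero_level_score(cfg: LevelConfig) -> LevelScore:
    return LevelScore(
        level=cfg.level,
        points=MetricPoints(0, 0, 0, 0, 0),
        max_per_metric=cfg.n_items,
        n_served_correct=0,
    )


def score_level(level_script: LevelScript, responses: ResponseSet) -> LevelScore:
    """Score one level's responses against its ground truth.

    Recall and recognition claims are matched by item-id set
    intersection with the ordered items; serving is checked per item
    against the ordering customer's true seat.
    """
    if responses.level != level_script.level:
        raise ResponseReferenceError(
            f"responses are for level {responses.level}, script level is "
            f"{level_script.level}"
        )
    ordered = set(level_script.ordered_item_ids)
    imm = len(set(responses.immediate_recall) & ordered)
    dly = len(set(responses.delayed_recall) & ordered)
    rec = len(set(responses.counter_selection) & ordered)
    table_pts = customer_pts = both = 0
    for item_id, (t, c) in responses.service.items():
        if item_id not in ordered:
            continue
        true_t, true_c = level_script.seat_of(item_id)
        t_ok, c_ok = t == true_t, c == true_c
        table_pts += t_ok
        customer_pts += c_ok
        both += t_ok and c_ok
    return LevelScore(
        level=level_script.level,
        points=MetricPoints(imm, dly, rec, table_pts, customer_pts),
        max_per_metric=level_script.config.n_items,
        n_served_correct=both,
    )


def score_session(script: SessionScript, log: SessionLog) -> SessionScore:
    """Score a full session log against its generating script.

    Levels never reached (after discontinuation) contribute zero points
    but still count toward the maxima, so the grand total remains on the
    full 0–180 scale under the default protocol.
    """
    if log.script_seed != script.seed or log.protocol_hash != script.protocol.config_hash():
        raise ResponseReferenceError(
            "session log does not match the script (seed or protocol hash differ)"
        )
    per_level: list[LevelScore] = []
    for lvl in script.levels:
        rs = log.responses.get(lvl.level)
        if rs is None:
            per_level.append(_zero_level_score(lvl.config))
        else:
            per_level.append(score_level(lvl, rs))
    total_minutes = (log.events[-1].timestamp / 60.0) if log.events else 0.0
    return SessionScore(
        per_level=tuple(per_level),
        immediate_total=sum(ls.points.immediate for ls in per_level),
        delayed_total=sum(ls.points.delayed for ls in per_level),
        recognition_total=sum(ls.points.recognition for ls in per_level),
        table_total=sum(ls.points.table for ls in per_level),
        customer_total=sum(ls.points.customer for ls in per_level),
        grand_total=sum(ls.total for ls in per_level),
        levels_played=log.levels_played,
        total_minutes=total_minutes,
    )
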