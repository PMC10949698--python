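"""Synthetic respondents: latent-ability agents and cohort generation.

No respondent model accompanies the assessment itself, so this module
supplies an invented one whose only job is to exercise the full
screening-validation pipeline with plausible, controllable behaviour.
Every formula below is a modelling convenience, not an empirical claim.

An agent holds a latent ability ``theta`` in [0, 1] and, per ordered
item in a level with ``k`` total items:

* encodes the item with probability
  ``p_imm = clip(theta * exp(-lambda * max(0, k - 2)), 0, 1)`` —
  an exponential memory-load penalty beyond the easiest (2-item) level;
* reports it at immediate recall iff encoded;
* retains it to delayed recall with probability ``rho`` given encoding
  (multiplicative forgetting over the distraction delay);
* picks it at the counter if it was recalled at delay **or**, failing
  that, with probability ``gamma * p_imm`` — recognition superiority:
  cued recognition rescues items recall lost;
* delivers it to the correct (table, customer) with probability
  ``beta`` given it was picked, otherwise to a uniformly random wrong
  seat (imperfect item-table-customer binding).

Each scored phase is attempted with probability ``attempt_probability``.

All Bernoulli draws are made from a pre-laid uniform grid whose shape
depends only on the script, never on the parameters.  Under common
random numbers, raising ``theta`` therefore never lowers any score
component (stochastic monotonicity), and recognition picks are a
superset of delayed recalls by construction.

A cohort draws agent parameters per group (the *older* preset has lower
mean ability and a steeper load penalty than the *younger* one — a
direction choice, not a fitted magnitude) and links a noisy 0-39
reference-screener score to the same latent ability:
``screener = clip(round(mu0 + mu1 * theta + N(0, sigma)), 0, 39)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional

import numpy as np
import pandas as pd

from .errors import CohortSpecError
from .menu import Menu
from .protocol import ProtocolConfig, SessionScript, generate_script
from .session import Phase, ResponseSet, run_scripted_session
from .screener import IMPAIRMENT_CUTOFF, SCREENER_MAX

__all__ = [
    "AgentProfile",
    "GroupPreset",
    "ScreenerLink",
    "CohortSpec",
    "simulate_responses",
    "simulate_session",
    "simulate_cohort",
    "COHORT_COLUMNS",
]


def _check_unit(name: str, value: float) -> float:
    if not (0.0 <= value <= 1.0):
        raise CohortSpecError(f"{name} must lie in [0, 1], got {value}")
    return float(value)


@dataclass(frozen=True)
class AgentProfile:
    """Latent parameters of one simulated respondent."""

    theta: float
    load_sensitivity: float = 0.03
    retention: float = 0.88
    recognition_boost: float = 0.70
    binding_fidelity: float = 0.82
    attempt_probability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_unit("theta", self.theta)
        _check_unit("retention", self.retention)
        _check_unit("recognition_boost", self.recognition_boost)
        _check_unit("binding_fidelity", self.binding_fidelity)
        _check_unit("attempt_probability", self.attempt_probability)
        if self.load_sensitivity < 0:
            raise CohortSpecError(
                f"load_sensitivity must be >= 0, got {self.load_sensitivity}"
            )


def simulate_responses(
    script: SessionScript,
    agent: AgentProfile,
    rng: np.random.Generator,
) -> list[ResponseSet]:
    """Generate one agent's responses for every level of a script.

    Deterministic given ``(script, agent, rng state)``.  Responses are
    produced for all levels; the session engine decides how many are
    actually played.
    """
    out: list[ResponseSet] = []
    for lvl in script.levels:
        cfg = lvl.config
        k = cfg.n_items
        p_imm = float(np.clip(agent.theta * np.exp(-agent.load_sensitivity * max(0, k - 2)), 0.0, 1.0))
        # fixed-shape draws: 4 attempt uniforms, then 4 uniforms + 1
        # wrong-seat uniform per item, regardless of parameter values
        u_att = rng.random(4)
        u = rng.random((k, 5))
        attempted = {
            ph: bool(u_att[j] < agent.attempt_probability)
            for j, ph in enumerate(
                (Phase.IMMEDIATE_RECALL, Phase.DELAYED_RECALL,
                 Phase.COUNTER_SELECTION, Phase.SERVICE)
            )
        }
        items = lvl.ordered_item_ids
        encoded = [u[i, 0] < p_imm for i in range(k)]
        delayed = [encoded[i] and u[i, 1] < agent.retention for i in range(k)]
        picked = [
            delayed[i] or u[i, 2] < agent.recognition_boost * p_imm for i in range(k)
        ]
        immediate_claims = tuple(items[i] for i in range(k) if encoded[i])
        delayed_claims = tuple(items[i] for i in range(k) if delayed[i])
        picks = tuple(items[i] for i in range(k) if picked[i])
        service: dict[str, tuple[int, int]] = {}
        if attempted[Phase.COUNTER_SELECTION] and attempted[Phase.SERVICE]:
            all_seats = [
                (t, c)
                for t in range(1, cfg.n_tables + 1)
                for c in range(1, cfg.customers_per_table + 1)
            ]
            for i in range(k):
                if not picked[i]:
                    continue
                true_seat = lvl.seat_of(items[i])
                if u[i, 3] < agent.binding_fidelity:
                    service[items[i]] = true_seat
                else:
                    wrong = [s for s in all_seats if s != true_seat]
                    service[items[i]] = wrong[int(u[i, 4] * len(wrong))]
        out.append(
            ResponseSet(
                level=lvl.level,
                immediate_recall=immediate_claims if attempted[Phase.IMMEDIATE_RECALL] else (),
                delayed_recall=delayed_claims if attempted[Phase.DELAYED_RECALL] else (),
                counter_selection=picks if attempted[Phase.COUNTER_SELECTION] else (),
                service=service,
            )
        )
    return out


def simulate_session(script: SessionScript, agent: AgentProfile):
    """Simulate responses and play them through the session engine."""
    rng = np.random.default_rng(agent.seed)
    responses = simulate_responses(script, agent, rng)
    return run_scripted_session(script, responses)


@dataclass(frozen=True)
class GroupPreset:
    """Mean/SD pairs for drawing agent parameters within a group.

    Draws are normal, clipped to each parameter's legal range.
    """

    theta: tuple[float, float]
    load_sensitivity: tuple[float, float]
    retention: tuple[float, float]
    recognition_boost: tuple[float, float]
    binding_fidelity: tuple[float, float]
    attempt_probability: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            mean, sd = getattr(self, f.name)
            if sd < 0:
                raise CohortSpecError(f"{f.name} SD must be >= 0, got {sd}")

    def draw(self, rng: np.random.Generator, seed: int) -> AgentProfile:
        def trunc(pair, lo=0.0, hi=1.0):
            mean, sd = pair
            return float(np.clip(rng.normal(mean, sd) if sd > 0 else mean, lo, hi))

        return AgentProfile(
            theta=trunc(self.theta),
            load_sensitivity=trunc(self.load_sensitivity, 0.0, np.inf),
            retention=trunc(self.retention),
            recognition_boost=trunc(self.recognition_boost),
            binding_fidelity=trunc(self.binding_fidelity),
            attempt_probability=trunc(self.attempt_probability),
            seed=seed,
        )


#: direction-only presets: older adults get lower mean ability and a
#: steeper memory-load penalty than younger adults
YOUNGER_PRESET = GroupPreset(
    theta=(0.80, 0.08),
    load_sensitivity=(0.02, 0.01),
    retention=(0.92, 0.04),
    recognition_boost=(0.70, 0.08),
    binding_fidelity=(0.88, 0.05),
)
OLDER_PRESET = GroupPreset(
    theta=(0.62, 0.12),
    load_sensitivity=(0.05, 0.02),
    retention=(0.85, 0.06),
    recognition_boost=(0.70, 0.08),
    binding_fidelity=(0.78, 0.07),
)


@dataclass(frozen=True)
class ScreenerLink:
    """Linear map from latent ability to a noisy 0-39 screener score."""

    intercept: float = 18.0
    slope: float = 18.0
    noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise CohortSpecError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def draw(self, theta: float, rng: np.random.Generator) -> int:
        raw = self.intercept + self.slope * theta + (
            rng.normal(0.0, self.noise_sd) if self.noise_sd > 0 else 0.0
        )
        return int(np.clip(np.rint(raw), 0, SCREENER_MAX))


@dataclass(frozen=True)
class CohortSpec:
    """Composition and parameter distributions of a simulated cohort."""

    n_younger: int = 56
    n_older: int = 75
    younger: GroupPreset = field(default_factory=lambda: YOUNGER_PRESET)
    older: GroupPreset = field(default_factory=lambda: OLDER_PRESET)
    screener_link: ScreenerLink = field(default_factory=ScreenerLink)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_younger < 0 or self.n_older < 0:
            raise CohortSpecError("group sizes must be non-negative")


COHORT_COLUMNS = [
    "agent_id", "group", "true_theta",
    "levels_played", "immediate_total", "delayed_total", "recognition_total",
    "table_total", "customer_total", "spatial_combined_total", "grand_total",
    "total_minutes", "screener_score", "impaired_flag",
]


def _agent_seeds(
    master_seed: int, agent_index: int
) -> tuple[int, np.random.Generator, np.random.Generator]:
    """Stable per-agent seeding from (master_seed, agent index).

    Independent of iteration order: each agent's stream is derived from
    a :class:`numpy.random.SeedSequence` keyed on both values.
    """
    ss = np.random.SeedSequence(entropy=(int(master_seed), int(agent_index)))
    script_seed = int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)
    param_ss, behaviour_ss = ss.spawn(2)
    return script_seed, np.random.default_rng(param_ss), np.random.default_rng(behaviour_ss)


def simulate_cohort(
    spec: CohortSpec,
    menu: Menu,
    protocol: ProtocolConfig,
) -> pd.DataFrame:
    """Simulate a two-group cohort and return one record per agent.

    Each agent plays an independently scripted session (own script seed
    derived from the master seed), is scored by the session scorer, and
    receives a reference-screener score linked to the same latent
    ability.  The impairment flag applies the screener's <= 21 cutoff.
    """
    from .scoring import score_session

    rows = []
    groups = [("younger", spec.n_younger, spec.younger), ("older", spec.n_older, spec.older)]
    agent_index = 0
    for group_name, n, preset in groups:
        for _ in range(n):
            script_seed, param_rng, behaviour_rng = _agent_seeds(spec.master_seed, agent_index)
            agent = preset.draw(param_rng, seed=script_seed)
            script = generate_script(menu, protocol, seed=script_seed)
            responses = simulate_responses(script, agent, behaviour_rng)
            log = run_scripted_session(script, responses)
            score = score_session(script, log)
            screener = spec.screener_link.draw(agent.theta, param_rng)
            row = {
                "agent_id": f"agent_{agent_index:04d}",
                "group": group_name,
                "true_theta": agent.theta,
                "screener_score": screener,
                "impaired_flag": screener <= IMPAIRMENT_CUTOFF,
            }
            row.update(score.as_row())
            rows.append(row)
            agent_index += 1
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
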