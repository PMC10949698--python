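# cafescreen

A headless, scriptable engine for a virtual-café cognitive screening
task, for researchers who want to study or extend gamified memory
screening without a 3D application or human participants.

The task places a respondent in a café with up to four tables of two
customers. Each of five levels presents a growing set of orders (2, 4,
6, 8 and 16 items; level 5 adds drinks), and the respondent must

1. report the orders to the chef (**immediate recall**),
2. survive a ~120 s napkin-sorting interlude (**distraction**),
3. re-record the orders (**delayed recall**),
4. pick the ordered dishes from a counter lineup that includes
   never-ordered filler items (**delayed recognition**), and
5. deliver each dish to the right table and customer
   (**spatial / serving memory**).

Each ordered item earns one point per metric — immediate, delayed,
recognition, table and customer — so the level maxima are 10/20/30/40/80
and the grand total *S* ranges 0–180, with subdomain totals of 36 each
(72 for the two serving columns combined). A session is **discontinued**
when a level's accuracy falls strictly below 50 % on all four task
metrics (serving counts an item only when table *and* customer are both
correct).

Around that engine the package provides:

- a **menu registry** (31 foods, 9 beverages, counter-only fillers),
- a **session state machine** with timestamped JSONL event logs,
- a **latent-ability respondent simulator**: an agent with ability
  θ ∈ [0, 1] encodes an item with probability
  `p = clip(θ·exp(−λ·max(0, k−2)), 0, 1)` at memory load *k*, retains it
  to delayed recall with probability ρ, recognises with a γ-boosted
  second chance, and binds item→table→customer with fidelity β,
- a **reference screener** (23 items, 39 points, impairment cutoff
  ≤ 21) whose score shares the agent's latent ability, and
- the **validation statistics** used to compare the two instruments:
  group summaries, Welch *t*, Fisher exact, Pearson *r*, and Cohen's κ
  with the conventional agreement bands.

## Worked example

```python
import cafescreen as cs

menu = cs.load_default_menu()
protocol = cs.default_protocol()

# one perfect session
script = cs.generate_script(menu, protocol, seed=7)
log = cs.run_scripted_session(script, [cs.ResponseSet.perfect(lv) for lv in script.levels])
score = cs.score_session(script, log)
print("grand total:", score.grand_total, "/", protocol.max_total_points)
print("levels played:", score.levels_played, "| minutes:", round(score.total_minutes, 1))

# a middling simulated respondent
agent = cs.AgentProfile(theta=0.55, seed=11)
sim_log = cs.simulate_session(script, agent)
sim_score = cs.score_session(script, sim_log)
print("simulated agent:", sim_score.grand_total, "points,",
      sim_score.levels_played, "levels,", sim_log.outcome.status)

# a synthetic validation cohort
spec = cs.CohortSpec(n_younger=56, n_older=75, master_seed=42)
cohort = cs.simulate_cohort(spec, menu, protocol)
print(cohort.groupby("group")["grand_total"].mean().round(1))
r = cs.pearson_r(cohort["grand_total"], cohort["screener_score"])
print(f"module~screener r = {r.statistic:.3f}, p = {r.p_value:.4g}")
```

prints

```
grand total: 180 / 180
levels played: 5 | minutes: 22.3
simulated agent: 101 points, 5 levels, completed
group
older       68.3
younger    127.1
Name: grand_total, dtype: float64
module~screener r = 0.445, p = 9.737e-08
```

A flawless respondent reaches the 180-point ceiling in ~22 simulated
minutes. The θ = 0.55 agent completes all five levels but loses points
as the memory load grows. In the synthetic cohort the younger group
outscores the older one and the module score correlates positively with
the reference screener — these are direction-only properties of the
simulator's presets, not estimates of any real cohort's magnitudes.

## Command line

```bash
cafescreen simulate --n-younger 56 --n-older 75 --seed 42 --out runs/demo
cafescreen score runs/demo/*.jsonl --out runs/demo/scores.csv
cafescreen analyze --cohort runs/demo/cohort.csv --out runs/demo/report
cafescreen play --seed 0          # interactive text-mode session
cafescreen screener score --responses my_marks.json
cafescreen menu list
```

All randomness flows from `--seed`; outputs embed the package version,
seed and protocol hash, and `--no-timestamp` makes reruns byte-identical.

## Layout

- `src/cafescreen/` — `menu`, `protocol`, `session`, `scoring`,
  `simulate`, `screener`, `stats`, `report`, `io`, `cli`
- `docs/methods.md` — model, scoring and design notes
- `tests/` — unit, property and end-to-end suites
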