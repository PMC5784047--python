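"""Artificial-life ecosystem: foraging agents evolving quantity comparison.

A toroidal grid of cells each holding a food quantity in {0..9} is populated
by a fixed number of agents, each controlled by a small recurrent neural
network whose weights and hidden-layer size are genetically encoded. An
agent senses the food quantity of the four cells in its field of view (the
current cell plus the row of three cells directly ahead); each quantity n is
delivered as a 9-unit binary vector with n randomly chosen active units, a
coding scheme that sidesteps object-size normalization. Four effector units
select among turn-left, turn-right, move-forward and eat.

Evolution is a steady-state genetic algorithm: at every ecosystem iteration
two parents are sampled at random and the weaker of the two (by lifetime
food-collection rate) is replaced by their child (uniform per-gene crossover
plus small Gaussian mutation). No lifetime learning occurs.

Evolved agents are assayed in a walled 3x3 arena: the agent starts at the
centre facing the top row, whose left and right corners are baited with two
distinct quantities; a trial ends when the agent walks onto a baited corner,
and choosing the larger quantity counts as correct. Response time is the
number of time-steps until selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

N_SENSE_CELLS = 4
UNITS_PER_CELL = 9
N_INPUT = N_SENSE_CELLS * UNITS_PER_CELL   # 36 sensory units
N_ACTIONS = 4
ACTION_NAMES = ("turn_left", "turn_right", "forward", "eat")
#: heading order N, E, S, W; rows grow downward.
_DELTA = np.array([[-1, 0], [0, 1], [1, 0], [0, -1]])


@dataclass(frozen=True)
class EvoConfig:
    """Ecosystem, controller and genetic-algorithm parameters."""

    grid_side: int = 100
    n_agents: int = 200
    food_max: int = 9
    hidden_min: int = 2
    hidden_max: int = 20
    weight_init_scale: float = 0.3
    #: slow regrowth keeps food locally scarce, so collection rate rewards
    #: steering toward richer sensed cells rather than blind lane-grazing
    regrow_delay: int = 1000
    burn_in: int = 500              # steps before an agent can be a parent
    mutation_sigma: float = 0.05
    mutation_rate: float = 0.01
    size_mutation_rate: float = 0.02
    weight_clip: float = 10.0


def encode_food(n: int, rng: np.random.Generator) -> np.ndarray:
    """9-unit binary vector with exactly ``n`` randomly placed active units."""
    if not (0 <= n <= UNITS_PER_CELL):
        raise ValueError(f"food quantity must be in [0, {UNITS_PER_CELL}]")
    vec = np.zeros(UNITS_PER_CELL)
    on = rng.choice(UNITS_PER_CELL, size=int(n), replace=False)
    vec[on] = 1.0
    return vec


def _encode_batch(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Batched :func:`encode_food`: values (...,) -> bits (..., 9)."""
    keys = rng.random(values.shape + (UNITS_PER_CELL,), dtype=np.float32)
    order = np.argsort(keys, axis=-1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order,
                      np.broadcast_to(np.arange(UNITS_PER_CELL), order.shape),
                      axis=-1)
    return (ranks < values[..., None]).astype(np.float64)


def collection_rate(food_collected: float, steps: int) -> float:
    """Fitness primitive: food units collected per time-step."""
    if steps <= 0:
        raise ValueError("window must cover at least one time-step")
    return food_collected / steps


# ---------------------------------------------------------------------------
# population (struct-of-arrays for vectorized simulation)
# ---------------------------------------------------------------------------

@dataclass
class Population:
    """Genomes and state of all agents, stored as dense padded arrays.

    Weight arrays are padded to ``hidden_max`` units; ``hidden_size`` gives
    each agent's active hidden-layer width and inactive units are masked to
    zero activation, so crossover between different-size genomes is a plain
    per-gene mix of the padded arrays.
    """

    w_in: np.ndarray        # (A, Hmax, 36)
    w_rec: np.ndarray       # (A, Hmax, Hmax), asymmetric
    w_out: np.ndarray       # (A, 4, Hmax)
    b_hid: np.ndarray       # (A, Hmax)
    b_out: np.ndarray       # (A, 4)
    hidden_size: np.ndarray  # (A,)
    pos: np.ndarray         # (A, 2)
    heading: np.ndarray     # (A,)
    h: np.ndarray           # (A, Hmax) recurrent state
    collected: np.ndarray   # (A,) float
    age: np.ndarray         # (A,) int

    @classmethod
    def random(cls, config: EvoConfig, rng: np.random.Generator) -> "Population":
        a, hm = config.n_agents, config.hidden_max
        s = config.weight_init_scale
        return cls(
            w_in=rng.normal(0, s, (a, hm, N_INPUT)),
            w_rec=rng.normal(0, s, (a, hm, hm)),
            w_out=rng.normal(0, s, (a, N_ACTIONS, hm)),
            b_hid=rng.normal(0, s, (a, hm)),
            b_out=rng.normal(0, s, (a, N_ACTIONS)),
            hidden_size=rng.integers(config.hidden_min, config.hidden_max + 1,
                                     size=a),
            pos=rng.integers(0, config.grid_side, size=(a, 2)),
            heading=rng.integers(0, 4, size=a),
            h=np.zeros((a, hm)),
            collected=np.zeros(a),
            age=np.zeros(a, dtype=np.int64),
        )

    @property
    def size(self) -> int:
        return len(self.hidden_size)

    def unit_mask(self) -> np.ndarray:
        return (np.arange(self.w_in.shape[1])[None, :]
                < self.hidden_size[:, None]).astype(float)

    def fitness(self) -> np.ndarray:
        """Lifetime food-collection rate; zero for newborn agents."""
        return self.collected / np.maximum(self.age, 1)


class Agent:
    """Single-agent view onto a :class:`Population` (for inspection/tests)."""

    def __init__(self, population: Population, index: int):
        self.population = population
        self.index = int(index)

    def __getattr__(self, name):
        pop = object.__getattribute__(self, "population")
        if hasattr(pop, name):
            return getattr(pop, name)[self.index]
        raise AttributeError(name)

    @property
    def n_hidden(self) -> int:
        return int(self.population.hidden_size[self.index])

    def fitness(self, window: int | None = None) -> float:
        pop = self.population
        steps = int(pop.age[self.index]) if window is None else int(window)
        if window is not None and pop.age[self.index] < window:
            raise ValueError("agent has not lived through the window")
        return collection_rate(float(pop.collected[self.index]), steps)


def _tiebreak_argmax(scores: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Argmax along the last axis with uniform random tie-breaking."""
    best = scores.max(axis=-1, keepdims=True)
    is_best = scores == best
    keys = rng.random(scores.shape, dtype=np.float32)
    keys[~is_best] = -1.0
    return keys.argmax(axis=-1)


# ---------------------------------------------------------------------------
# ecosystem
# ---------------------------------------------------------------------------

@dataclass
class Ecosystem:
    """Grid world plus population plus the random stream driving both."""

    grid: np.ndarray
    population: Population
    config: EvoConfig
    rng: np.random.Generator
    iteration: int = 0
    _refill: list = field(default_factory=list, repr=False)
    _pending: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def initialize(cls, config: EvoConfig = EvoConfig(),
                   seed=None) -> "Ecosystem":
        rng = np.random.default_rng(seed)
        grid = rng.integers(0, config.food_max + 1,
                            size=(config.grid_side, config.grid_side)
                            ).astype(np.int64)
        eco = cls(grid=grid, population=Population.random(config, rng),
                  config=config, rng=rng)
        eco._refill = [[] for _ in range(config.regrow_delay)]
        eco._pending = np.zeros(config.grid_side ** 2, dtype=bool)
        return eco

    def _schedule_refill(self, flat_cells) -> None:
        """Queue emptied cells for regrowth (once per depletion)."""
        fresh = [int(c) for c in np.atleast_1d(flat_cells)
                 if not self._pending[int(c)]]
        if fresh:
            self._pending[fresh] = True
            slot = self.iteration % self.config.regrow_delay
            self._refill[slot].extend(fresh)

    def agent(self, index: int) -> Agent:
        return Agent(self.population, index)


def _fov_cells(pos: np.ndarray, heading: np.ndarray) -> np.ndarray:
    """Field-of-view coordinates: current, front-left, front, front-right."""
    ahead = _DELTA[heading]
    left = _DELTA[(heading + 3) % 4]
    right = _DELTA[(heading + 1) % 4]
    return np.stack(
        [pos, pos + ahead + left, pos + ahead, pos + ahead + right], axis=-2
    )


def sense(ecosystem: Ecosystem, agent: Agent) -> np.ndarray:
    """36-unit sensory vector for one agent (stochastic food encoding)."""
    cells = _fov_cells(agent.pos[None], np.asarray([agent.heading]))[0]
    cells = cells % ecosystem.config.grid_side
    values = ecosystem.grid[cells[:, 0], cells[:, 1]]
    return np.concatenate([encode_food(int(v), ecosystem.rng) for v in values])


def step_agent(agent: Agent, sensory_input: np.ndarray,
               ecosystem: Ecosystem | None = None,
               rng: np.random.Generator | None = None) -> str:
    """One recurrent update followed by action selection for a single agent.

    If an ecosystem is supplied the action is applied to it: forward moves
    (toroidal wrap), turns change heading, and eat transfers the current
    cell's food to the agent's collected total and empties the cell.
    """
    pop, i = agent.population, agent.index
    if rng is None:
        rng = ecosystem.rng if ecosystem is not None else np.random.default_rng()
    mask = (np.arange(pop.w_in.shape[1]) < pop.hidden_size[i]).astype(float)
    pre = (pop.w_in[i] @ np.asarray(sensory_input, dtype=float)
           + pop.w_rec[i] @ pop.h[i] + pop.b_hid[i])
    h = np.tanh(pre) * mask
    pop.h[i] = h
    scores = pop.w_out[i] @ h + pop.b_out[i]
    action = int(_tiebreak_argmax(scores[None], rng)[0])
    if ecosystem is not None:
        side = ecosystem.config.grid_side
        if action == 0:
            pop.heading[i] = (pop.heading[i] - 1) % 4
        elif action == 1:
            pop.heading[i] = (pop.heading[i] + 1) % 4
        elif action == 2:
            pop.pos[i] = (pop.pos[i] + _DELTA[pop.heading[i]]) % side
        else:
            r, c = pop.pos[i]
            pop.collected[i] += ecosystem.grid[r, c]
            ecosystem.grid[r, c] = 0
            ecosystem._schedule_refill(int(r) * side + int(c))
    return ACTION_NAMES[action]


def _crossover_mutate(a: np.ndarray, b: np.ndarray, cfg: EvoConfig,
                      rng: np.random.Generator) -> np.ndarray:
    child = np.where(rng.random(a.shape) < 0.5, a, b)
    hit = rng.random(child.shape) < cfg.mutation_rate
    child = child + hit * rng.normal(0.0, cfg.mutation_sigma, child.shape)
    if not np.isfinite(child).all():
        warnings.warn("non-finite genome values after mutation; clamped")
        child = np.nan_to_num(child, nan=0.0,
                              posinf=cfg.weight_clip, neginf=-cfg.weight_clip)
    return np.clip(child, -cfg.weight_clip, cfg.weight_clip)


def _ga_replacement(eco: Ecosystem) -> None:
    pop, cfg, rng = eco.population, eco.config, eco.rng
    eligible = np.flatnonzero(pop.age >= cfg.burn_in)
    if len(eligible) < 2:
        return
    i, j = rng.choice(eligible, size=2, replace=False)
    fit = pop.fitness()
    loser = i if fit[i] < fit[j] else j
    for arr in (pop.w_in, pop.w_rec, pop.w_out, pop.b_hid, pop.b_out):
        arr[loser] = _crossover_mutate(arr[i], arr[j], cfg, rng)
    hs = int(pop.hidden_size[i] if rng.random() < 0.5 else pop.hidden_size[j])
    if rng.random() < cfg.size_mutation_rate:
        hs += int(rng.choice([-1, 1]))
    pop.hidden_size[loser] = np.clip(hs, cfg.hidden_min, cfg.hidden_max)
    pop.h[loser] = 0.0
    pop.heading[loser] = rng.integers(0, 4)
    pop.collected[loser] = 0.0
    pop.age[loser] = 0


def update(eco: Ecosystem) -> None:
    """One ecosystem iteration: refill, sense/act for every agent, one GA event."""
    pop, cfg, rng = eco.population, eco.config, eco.rng
    side = cfg.grid_side

    # scheduled regrowth: cells eaten exactly regrow_delay iterations ago
    slot = eco.iteration % cfg.regrow_delay
    due = eco._refill[slot]
    if due:
        cells = np.asarray(due)
        eco.grid.ravel()[cells] = rng.integers(
            0, cfg.food_max + 1, size=len(due))
        eco._pending[cells] = False
        eco._refill[slot] = []

    cells = _fov_cells(pop.pos, pop.heading) % side
    values = eco.grid[cells[..., 0], cells[..., 1]]
    x = _encode_batch(values, rng).reshape(pop.size, N_INPUT)
    pre = (np.einsum("ahi,ai->ah", pop.w_in, x)
           + np.einsum("ahk,ak->ah", pop.w_rec, pop.h) + pop.b_hid)
    pop.h = np.tanh(pre) * pop.unit_mask()
    scores = np.einsum("aoh,ah->ao", pop.w_out, pop.h) + pop.b_out
    actions = _tiebreak_argmax(scores, rng)

    turn = (actions == 1).astype(int) - (actions == 0).astype(int)
    pop.heading = (pop.heading + turn) % 4
    fwd = actions == 2
    pop.pos[fwd] = (pop.pos[fwd] + _DELTA[pop.heading[fwd]]) % side

    eaters = np.flatnonzero(actions == 3)
    if len(eaters):
        # one transfer per cell: a random eater wins when agents share a cell
        perm = rng.permutation(eaters)
        flat = pop.pos[perm, 0] * side + pop.pos[perm, 1]
        uniq, first = np.unique(flat, return_index=True)
        gains = eco.grid.ravel()[uniq]
        pop.collected[perm[first]] += gains
        eco.grid.ravel()[uniq] = 0
        # every grazed cell regrows once after the delay; the pending flag
        # stops repeated eating from queueing extra refills
        eco._schedule_refill(uniq)

    pop.age += 1
    _ga_replacement(eco)
    eco.iteration += 1


def evolve(eco: Ecosystem, iterations: int,
           trace_every: int = 500) -> pd.DataFrame:
    """Run the ecosystem, returning a mean/max fitness trace."""
    rows = []
    for _ in range(iterations):
        update(eco)
        if eco.iteration % trace_every == 0:
            fit = eco.population.fitness()
            rows.append({"iteration": eco.iteration,
                         "mean_fitness": float(fit.mean()),
                         "max_fitness": float(fit.max())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 3x3 comparison test battery
# ---------------------------------------------------------------------------

def _battery_pairs(values: Sequence[int]) -> np.ndarray:
    vals = list(values)
    return np.array([(a, b) for a in vals for b in vals if a != b])


def comparison_battery(population: Population,
                       agent_indices: Sequence[int] | None = None,
                       values: Sequence[int] = range(1, 10),
                       repetitions: int = 50, step_cap: int = 50,
                       rng: np.random.Generator | None = None,
                       chunk: int = 10) -> pd.DataFrame:
    """Run the full 3x3 quantity-comparison battery on network agents.

    Every ordered pair of distinct quantities is administered ``repetitions``
    times per agent (9 values -> 72 pairs -> 3600 trials at 50 repetitions).
    Trials exceeding ``step_cap`` steps without a choice are marked timeout
    and excluded from accuracy summaries downstream.
    """
    if rng is None:
        rng = np.random.default_rng()
    if agent_indices is None:
        agent_indices = np.arange(population.size)
    agent_indices = np.asarray(agent_indices)
    pairs = _battery_pairs(values)
    reps = int(repetitions)
    n_t = len(pairs) * reps
    left_val = np.repeat(pairs[:, 0], reps)
    right_val = np.repeat(pairs[:, 1], reps)

    frames = []
    for lo in range(0, len(agent_indices), chunk):
        sel = agent_indices[lo:lo + chunk]
        frames.append(
            _battery_chunk(population, sel, left_val, right_val,
                           step_cap, rng)
        )
    out = pd.concat(frames, ignore_index=True)
    return out


def _battery_chunk(pop: Population, sel: np.ndarray, left_val: np.ndarray,
                   right_val: np.ndarray, step_cap: int,
                   rng: np.random.Generator) -> pd.DataFrame:
    a_c, n_t = len(sel), len(left_val)
    hm = pop.w_in.shape[1]
    w_in, w_rec = pop.w_in[sel], pop.w_rec[sel]
    w_out, b_hid, b_out = pop.w_out[sel], pop.b_hid[sel], pop.b_out[sel]
    mask = (np.arange(hm)[None, :] < pop.hidden_size[sel][:, None]
            ).astype(float)[:, None, :]
    lv = np.broadcast_to(left_val, (a_c, n_t))
    rv = np.broadcast_to(right_val, (a_c, n_t))

    pos = np.ones((a_c, n_t, 2), dtype=np.int64)      # centre (1,1)
    heading = np.zeros((a_c, n_t), dtype=np.int64)    # facing the top row
    h = np.zeros((a_c, n_t, hm))
    done = np.zeros((a_c, n_t), dtype=bool)
    rt = np.zeros((a_c, n_t), dtype=np.int64)
    chose_left = np.zeros((a_c, n_t), dtype=bool)

    for step in range(1, step_cap + 1):
        cells = _fov_cells(pos, heading)
        inside = ((cells[..., 0] >= 0) & (cells[..., 0] < 3)
                  & (cells[..., 1] >= 0) & (cells[..., 1] < 3))
        at_left = inside & (cells[..., 0] == 0) & (cells[..., 1] == 0)
        at_right = inside & (cells[..., 0] == 0) & (cells[..., 1] == 2)
        values = (at_left * lv[..., None] + at_right * rv[..., None])
        x = _encode_batch(values, rng).reshape(a_c, n_t, N_INPUT)
        pre = (np.einsum("ahi,ati->ath", w_in, x)
               + np.einsum("ahk,atk->ath", w_rec, h)
               + b_hid[:, None, :])
        h_new = np.tanh(pre) * mask
        scores = (np.einsum("aoh,ath->ato", w_out, h_new)
                  + b_out[:, None, :])
        actions = _tiebreak_argmax(scores, rng)

        active = ~done
        h[active] = h_new[active]
        turn = (actions == 1).astype(int) - (actions == 0).astype(int)
        heading[active] = (heading + turn)[active] % 4
        fwd = (actions == 2) & active
        target = pos + _DELTA[heading]
        legal = ((target[..., 0] >= 0) & (target[..., 0] < 3)
                 & (target[..., 1] >= 0) & (target[..., 1] < 3))
        move = fwd & legal
        pos[move] = target[move]

        sel_left = active & (pos[..., 0] == 0) & (pos[..., 1] == 0)
        sel_right = active & (pos[..., 0] == 0) & (pos[..., 1] == 2)
        newly = sel_left | sel_right
        rt[newly] = step
        chose_left[sel_left] = True
        done |= newly
        if done.all():
            break

    correct = np.where(chose_left, lv > rv, rv > lv)
    records = {
        "agent": np.repeat(sel, n_t),
        "left_value": np.tile(left_val, a_c),
        "right_value": np.tile(right_val, a_c),
        "chosen": np.where(done.ravel(),
                           np.where(chose_left.ravel(), "left", "right"),
                           "none"),
        "correct": np.where(done.ravel(), correct.ravel(), False),
        "rt": np.where(done.ravel(), rt.ravel(), -1),
        "timeout": ~done.ravel(),
    }
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# hand-coded reference policies
# ---------------------------------------------------------------------------

def _fov_counts(obs: np.ndarray) -> np.ndarray:
    """Recover the four sensed quantities from a 36-unit observation."""
    return np.asarray(obs).reshape(N_SENSE_CELLS, UNITS_PER_CELL).sum(axis=1)


class RandomPolicy:
    """Uniformly random action at every step (chance baseline)."""

    def reset(self):
        pass

    def act(self, obs, rng: np.random.Generator) -> int:
        return int(rng.integers(N_ACTIONS))


class GreedyComparisonPolicy:
    """Walks straight to the larger of the two sensed corner quantities."""

    def __init__(self):
        self.plan: list[int] = []

    def reset(self):
        self.plan = []

    def act(self, obs, rng: np.random.Generator) -> int:
        if not self.plan:
            counts = _fov_counts(obs)
            if counts[1] >= counts[3]:       # front-left holds more
                self.plan = [0, 2, 1, 2]     # left, forward, right, forward
            else:
                self.plan = [1, 2, 0, 2]
        return self.plan.pop(0)


class GreedyForagerPolicy:
    """Eats in place, else steers toward the richest visible cell."""

    def __init__(self):
        self.plan: list[int] = []

    def reset(self):
        self.plan = []

    def act(self, obs, rng: np.random.Generator) -> int:
        if self.plan:
            return self.plan.pop(0)
        counts = _fov_counts(obs)
        if counts[0] > 0:
            return 3                          # eat
        front = counts[1:]
        if front.max() > 0:
            best = int(front.argmax())
            if best == 1:                     # straight ahead
                return 2
            if best == 0:                     # front-left detour
                self.plan = [2, 1, 2]
                return 0
            self.plan = [2, 0, 2]             # front-right detour
            return 1
        return int(rng.choice([0, 1, 2, 2]))  # explore, biased forward


def policy_comparison_battery(policy, values: Sequence[int] = range(1, 10),
                              repetitions: int = 50, step_cap: int = 50,
                              rng: np.random.Generator | None = None
                              ) -> pd.DataFrame:
    """Run the 3x3 battery for a hand-coded policy object."""
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for a, b in _battery_pairs(values):
        for _ in range(int(repetitions)):
            policy.reset()
            pos = np.array([1, 1])
            heading = 0
            chosen, rtime = "none", -1
            for step in range(1, step_cap + 1):
                cells = _fov_cells(pos[None], np.asarray([heading]))[0]
                vals = np.zeros(N_SENSE_CELLS, dtype=int)
                for k, (r, c) in enumerate(cells):
                    if (r, c) == (0, 0):
                        vals[k] = a
                    elif (r, c) == (0, 2):
                        vals[k] = b
                obs = np.concatenate([encode_food(int(v), rng) for v in vals])
                action = policy.act(obs, rng)
                if action == 0:
                    heading = (heading - 1) % 4
                elif action == 1:
                    heading = (heading + 1) % 4
                elif action == 2:
                    tgt = pos + _DELTA[heading]
                    if 0 <= tgt[0] < 3 and 0 <= tgt[1] < 3:
                        pos = tgt
                if tuple(pos) == (0, 0):
                    chosen, rtime = "left", step
                    break
                if tuple(pos) == (0, 2):
                    chosen, rtime = "right", step
                    break
            correct = (a > b) if chosen == "left" else (b > a)
            rows.append({"agent": -1, "left_value": a, "right_value": b,
                         "chosen": chosen,
                         "correct": bool(correct) if chosen != "none" else False,
                         "rt": rtime, "timeout": chosen == "none"})
    return pd.DataFrame(rows)


def simulate_foraging(policy, steps: int, config: EvoConfig = EvoConfig(),
                      seed=None) -> float:
    """Single-policy foraging run on a fresh grid; returns collection rate."""
    rng = np.random.default_rng(seed)
    side = config.grid_side
    grid = rng.integers(0, config.food_max + 1, size=(side, side)).astype(int)
    refill = [[] for _ in range(config.regrow_delay)]
    pos = rng.integers(0, side, size=2)
    heading = int(rng.integers(0, 4))
    policy.reset()
    collected = 0.0
    for t in range(steps):
        slot = t % config.regrow_delay
        for cell in refill[slot]:
            grid.ravel()[cell] = rng.integers(0, config.food_max + 1)
        refill[slot] = []
        cells = _fov_cells(pos[None], np.asarray([heading]))[0] % side
        vals = grid[cells[:, 0], cells[:, 1]]
        obs = np.concatenate([encode_food(int(v), rng) for v in vals])
        action = policy.act(obs, rng)
        if action == 0:
            heading = (heading - 1) % 4
        elif action == 1:
            heading = (heading + 1) % 4
        elif action == 2:
            pos = (pos + _DELTA[heading]) % side
        else:
            collected += grid[pos[0], pos[1]]
            grid[pos[0], pos[1]] = 0
            refill[slot].append(int(pos[0]) * side + int(pos[1]))
    return collection_rate(collected, steps)


# ---------------------------------------------------------------------------
# behavioural and neural summaries
# ---------------------------------------------------------------------------

def distance_size_effects(trials: pd.DataFrame
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy/RT by numerical distance, and accuracy by pair magnitude.

    Timeout trials are excluded. Distance = |left - right|; magnitude =
    max(left, right).
    """
    if len(trials) == 0:
        raise ValueError("trials must be nonempty")
    valid = trials[~trials["timeout"]].copy()
    valid["distance"] = (valid["left_value"] - valid["right_value"]).abs()
    valid["size"] = valid[["left_value", "right_value"]].max(axis=1)
    by_distance = (
        valid.groupby("distance")
        .agg(accuracy=("correct", "mean"), mean_rt=("rt", "mean"),
             n_trials=("correct", "size"))
        .reset_index()
    )
    by_size = (
        valid.groupby("size")
        .agg(accuracy=("correct", "mean"), n_trials=("correct", "size"))
        .reset_index()
    )
    return by_distance, by_size


def chance_proportion(trials: pd.DataFrame, level: float = 0.95) -> float:
    """Fraction of agents whose accuracy is within a binomial CI of 0.5."""
    z = sp_stats.norm.ppf(0.5 + level / 2)
    flags = []
    for _, sub in trials[~trials["timeout"]].groupby("agent"):
        n = len(sub)
        if n == 0:
            flags.append(True)
            continue
        half_width = z * np.sqrt(0.25 / n)
        flags.append(abs(sub["correct"].mean() - 0.5) <= half_width)
    return float(np.mean(flags))


def analyze_hidden_units(population: Population, index: int,
                         probe_values: Sequence[int] = range(1, 10),
                         repetitions: int = 100, settle_steps: int = 2,
                         rho_threshold: float = 0.9,
                         rng: np.random.Generator | None = None
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Quantity tuning of one agent's hidden units (summation-coding check).

    The probe presents quantity ``n`` in the front cell of the field of view
    (other cells empty), lets the recurrent state settle for a few steps from
    rest, and records the hidden activations, averaged over stochastic
    encodings. Units are classified monotone increasing/decreasing when the
    Spearman rank correlation of their mean profile with quantity exceeds
    the threshold.

    Returns (profile table, curves) where curves is (n_values, n_hidden).
    """
    if rng is None:
        rng = np.random.default_rng()
    w_in = population.w_in[index]
    w_rec = population.w_rec[index]
    b_hid = population.b_hid[index]
    hm = w_in.shape[0]
    mask = (np.arange(hm) < population.hidden_size[index]).astype(float)
    values = np.asarray(list(probe_values))
    curves = np.zeros((len(values), hm))
    for vi, n in enumerate(values):
        acc = np.zeros(hm)
        for _ in range(int(repetitions)):
            h = np.zeros(hm)
            for _s in range(settle_steps):
                x = np.zeros(N_INPUT)
                x[2 * UNITS_PER_CELL:3 * UNITS_PER_CELL] = encode_food(int(n),
                                                                       rng)
                h = np.tanh(w_in @ x + w_rec @ h + b_hid) * mask
            acc += h
        curves[vi] = acc / repetitions

    rows = []
    active = int(population.hidden_size[index])
    for u in range(active):
        curve = curves[:, u]
        if np.allclose(curve, curve[0]):
            rho = 0.0
        else:
            rho = float(sp_stats.spearmanr(values, curve).statistic)
        if rho >= rho_threshold:
            cls = "monotone_increasing"
        elif rho <= -rho_threshold:
            cls = "monotone_decreasing"
        else:
            cls = "none"
        rows.append({"unit": u, "spearman_rho": rho, "profile": cls})
    return pd.DataFrame(rows), curves[:, :active]
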