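"""Operant reinforcement schedules and agent session simulation.

Encodes the task structures of a rodent reward-seeking protocol —
fixed-ratio (FR) and progressive-ratio (PR) lever pressing, within-session
demand tasks with stepped unit prices, and a go/no-go impulse-control task —
and simulates Poisson-pressing agents under them to produce
:class:`~rewardseek.events.TrialEvents` streams.

The PR requirement progression is near-logarithmic: trial ``i`` requires
``round(5*exp(0.2*i)) - 5`` presses, which yields
1, 2, 4, 6, 9, 12, 15, 20, 25, 32, 40, 50, 62, 77, 95, 118 for the first
16 trials.  A PR session terminates at the first 10-minute window in which
no reward is obtained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .events import TrialEvents

PR_TASKS = ("food_PR", "remi_PR")
DEMAND_TASKS = ("food_demand", "remi_demand")
TASK_NAMES = (
    "food_FR",
    "food_PR",
    "food_demand",
    "remi_FR",
    "remi_PR",
    "remi_demand",
    "go_nogo_p1",
    "go_nogo_p2",
)

#: Descending food demand unit prices (presses per pellet), one per 10-min bin.
FOOD_DEMAND_PRICES = (180, 90, 45, 15, 5)
#: Ascending remifentanil demand unit prices (presses per infusion).
REMI_DEMAND_PRICES = (6, 10, 16, 25, 40, 63, 100, 158)

#: Seconds without a reward after which a PR session terminates.
PR_NO_REWARD_TIMEOUT = 600.0


def pr_requirement_sequence(n_trials: int) -> list[int]:
    """Progressive-ratio response requirements for the first ``n_trials``.

    Uses the generating rule ``round(5*exp(0.2*i)) - 5`` (half away from
    zero), which reproduces the printed 16-entry progression exactly and
    extends it smoothly beyond trial 16.

    Parameters
    ----------
    n_trials
        Number of requirements to return; must be >= 1.
    """
    if not isinstance(n_trials, (int, np.integer)) or n_trials < 1:
        raise ValueError(f"n_trials must be a positive integer, got {n_trials!r}")
    out = []
    for i in range(1, n_trials + 1):
        x = 5.0 * math.exp(0.2 * i)
        out.append(int(math.floor(x + 0.5)) - 5)  # half-away-from-zero for x > 0
    return out


def demand_price_schedule(task_name: str) -> list[int]:
    """Printed unit-price progression for a demand task.

    ``food_demand`` prices descend (to avoid early-session satiation);
    ``remi_demand`` prices ascend.
    """
    if task_name == "food_demand":
        return list(FOOD_DEMAND_PRICES)
    if task_name == "remi_demand":
        return list(REMI_DEMAND_PRICES)
    raise ValueError(f"not a demand task: {task_name!r}")


@dataclass(frozen=True)
class ScheduleSpec:
    """Parameters of one operant task session.

    ``ratio_progression`` is the response requirement per trial (FR/PR) or
    per price bin (demand tasks).  ``timeout`` is the post-reward timeout
    during which presses have no consequence.  ``no_reward_timeout`` is the
    PR termination window (10 min).
    """

    task_name: str
    session_length: float
    ratio_progression: tuple[int, ...]
    bin_length: float | None = None
    timeout: float = 2.0
    cue_duration: float = 2.0
    reward_delay: float = 2.0
    no_reward_timeout: float = PR_NO_REWARD_TIMEOUT

    def __post_init__(self) -> None:
        if self.task_name not in TASK_NAMES:
            raise ValueError(f"unknown task {self.task_name!r}")
        if self.session_length <= 0:
            raise ValueError("session_length must be > 0")
        prog = np.asarray(self.ratio_progression)
        if len(prog) and prog.min() <= 0:
            raise ValueError("ratio_progression entries must be strictly positive")
        if self.task_name in PR_TASKS and len(prog) > 1 and np.any(np.diff(prog) < 0):
            raise ValueError("PR progression must be non-decreasing")
        if self.task_name == "food_demand" and np.any(np.diff(prog) >= 0):
            raise ValueError("food demand progression must be strictly decreasing")

    @classmethod
    def for_task(cls, task_name: str, **overrides) -> "ScheduleSpec":
        """Canonical schedule for a named task, with optional overrides."""
        if task_name in PR_TASKS:
            base = cls(
                task_name=task_name,
                session_length=7200.0,
                ratio_progression=tuple(pr_requirement_sequence(40)),
            )
        elif task_name == "food_demand":
            base = cls(
                task_name=task_name,
                session_length=5 * 600.0,
                ratio_progression=tuple(FOOD_DEMAND_PRICES),
                bin_length=600.0,
            )
        elif task_name == "remi_demand":
            base = cls(
                task_name=task_name,
                session_length=8 * 600.0,
                ratio_progression=tuple(REMI_DEMAND_PRICES),
                bin_length=600.0,
            )
        elif task_name in ("food_FR", "remi_FR"):
            base = cls(
                task_name=task_name,
                session_length=2700.0,
                ratio_progression=tuple([5] * 200),
            )
        elif task_name in ("go_nogo_p1", "go_nogo_p2"):
            base = cls(
                task_name=task_name,
                session_length=64 * 45.0,
                ratio_progression=(1,),
                cue_duration=5.0,
            )
        else:
            raise ValueError(f"unknown task {task_name!r}")
        return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class AgentParams:
    """Poisson-pressing agent: simulation scaffolding, not a behavioral model.

    ``press_rate`` is the homogeneous rate of active lever presses
    (presses/s); the agent quits once the current response requirement
    exceeds ``persistence_limit``.
    """

    press_rate: float
    persistence_limit: float = math.inf

    def __post_init__(self) -> None:
        if self.press_rate < 0:
            raise ValueError("press_rate must be >= 0")


def simulate_pr_session(
    agent: AgentParams, schedule: ScheduleSpec, seed: int
) -> TrialEvents:
    """Simulate one progressive-ratio session.

    The agent emits active presses as a homogeneous Poisson process while a
    trial is live (pressing is suspended during the post-reward timeout).
    Completing the current ratio triggers the reward-predictive cue, with
    reward delivered ``schedule.reward_delay`` seconds after cue onset.  The
    session ends at the first 10-minute window with no reward, or at the
    session-length cap.  Deterministic given (agent, schedule, seed).
    """
    if schedule.task_name not in PR_TASKS:
        raise ValueError(f"not a PR task: {schedule.task_name}")
    rng = np.random.default_rng(seed)
    recs: list[tuple[float, str, int]] = []
    t = 0.0
    last_reward = 0.0
    trial = 1
    cap = schedule.session_length
    window = schedule.no_reward_timeout

    def requirement(i: int) -> int:
        if i <= len(schedule.ratio_progression):
            return int(schedule.ratio_progression[i - 1])
        return pr_requirement_sequence(i)[-1]

    end_time = None
    while True:
        req = requirement(trial)
        deadline = min(last_reward + window, cap)
        if agent.press_rate == 0 or req > agent.persistence_limit:
            end_time = deadline
            break
        recs.append((t, "trial_start", trial))
        presses_done = 0
        quit_trial = False
        while presses_done < req:
            t_next = t + rng.exponential(1.0 / agent.press_rate)
            if t_next > deadline:
                quit_trial = True
                t = deadline
                break
            t = t_next
            recs.append((t, "active_press", trial))
            presses_done += 1
        if quit_trial:
            recs.append((t, "trial_end", trial))
            end_time = t
            break
        cue_on = t
        reward_t = cue_on + schedule.reward_delay
        if reward_t > cap:
            recs.append((min(cue_on, cap), "trial_end", trial))
            end_time = cap
            break
        recs.append((cue_on, "cue_on", trial))
        recs.append((cue_on + schedule.cue_duration, "cue_off", trial))
        kind = "infusion" if schedule.task_name == "remi_PR" else "reward"
        recs.append((reward_t, kind, trial))
        recs.append((reward_t, "trial_end", trial))
        last_reward = reward_t
        t = reward_t + schedule.timeout  # pressing resumes after timeout
        trial += 1
        if t >= cap:
            end_time = cap
            break
    recs.sort(key=lambda r: (r[0], r[2]))
    return TrialEvents.from_records(recs, session_length=float(end_time))


@dataclass(frozen=True)
class GoNogoPlan:
    """One pseudorandomized go/no-go session plan.

    64 trials, 32 go and 32 no-go, ordered pseudorandomly in blocks of
    10–11 trials with near-balanced class quotas per block.  Go cues last
    5 s; no-go cues last 5 s in phase 1 and 10 s in phase 2.  Mean
    inter-trial interval is 40 s.
    """

    trial_types: tuple[str, ...]
    cue_duration_go: float
    cue_duration_nogo: float
    mean_iti: float = 40.0
    block_sizes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.trial_types) != 64:
            raise ValueError("a session plan has exactly 64 trials")
        n_go = sum(t == "go" for t in self.trial_types)
        if n_go != 32:
            raise ValueError("a session plan has exactly 32 go and 32 no-go trials")
        if self.block_sizes and sum(self.block_sizes) != 64:
            raise ValueError("block sizes must sum to 64")


def gonogo_session_plan(phase: int, seed: int) -> GoNogoPlan:
    """Draw a pseudorandomized 64-trial go/no-go plan for a phase.

    Blocks of 10–11 trials each carry a near-even go/no-go quota
    (quota imbalances alternate so the session totals 32/32); trial order
    is shuffled within blocks.
    """
    if phase not in (1, 2):
        raise ValueError(f"phase must be 1 or 2, got {phase!r}")
    rng = np.random.default_rng(seed)
    sizes = [11, 11, 11, 11, 10, 10]
    rng.shuffle(sizes)
    # odd blocks alternate which class gets the extra trial
    odd_parity = rng.integers(0, 2)
    trial_types: list[str] = []
    odd_seen = 0
    for size in sizes:
        if size % 2 == 0:
            n_go = size // 2
        else:
            n_go = size // 2 + ((odd_seen + odd_parity) % 2)
            odd_seen += 1
        block = ["go"] * n_go + ["nogo"] * (size - n_go)
        rng.shuffle(block)
        trial_types.extend(block)
    return GoNogoPlan(
        trial_types=tuple(trial_types),
        cue_duration_go=5.0,
        cue_duration_nogo=5.0 if phase == 1 else 10.0,
        block_sizes=tuple(sizes),
    )
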