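"""W-maze spatial alternation task: states, reward delivery, trial taxonomy.

The track has three arms. Arms 1 and 3 are the outer arms, arm 2 is the
center arm. A correct visit sequence alternates outer arms through the
center (e.g. 2-3-2-1-2). The agent/animal state is the pair
``(previous arm, current arm)``; a START sentinel marks the beginning of a
session, giving a 13-entry state space: the 3x3 (previous x current) arm
pairs, the three (START, arm) states reachable on the first visit of a
session, and the (START, START) state the session begins in. The three
diagonal (arm, arm) pairs exist in the table but are never visited because
revisiting the current arm is forbidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ARMS = (1, 2, 3)
OUTER_ARMS = (1, 3)
CENTER_ARM = 2
START = 0  # sentinel for "session just started"

N_STATES = 13
N_ARMS = 3

INBOUND = "inbound"
OUTBOUND = "outbound"

#: All 13 (previous, current) pairs in index order.  Ordering: the nine
#: arm/arm pairs row-major by (previous, current), then (START, arm) for
#: arm = 1, 2, 3, then (START, START) last.
STATES = tuple(
    [(p, c) for p in ARMS for c in ARMS]
    + [(START, c) for c in ARMS]
    + [(START, START)]
)


def state_index(previous: int, current: int, *, strict: bool = True) -> int:
    """Map a (previous, current) pair to its row in the 13-state table.

    With ``strict=True`` (default) the three diagonal (arm, arm) pairs are
    rejected, since the task forbids revisiting the current arm and those
    states can never occur in a trajectory. Pass ``strict=False`` when
    indexing the full propensity/value tables.
    """
    if previous == START and current == START:
        return 12
    if previous == START:
        if current not in ARMS:
            raise ValueError(f"invalid current arm {current!r}")
        return 9 + (current - 1)
    if previous not in ARMS or current not in ARMS:
        raise ValueError(f"invalid state ({previous!r}, {current!r})")
    if strict and previous == current:
        raise ValueError(
            f"state ({previous}, {current}) is unreachable: revisiting the "
            "current arm is forbidden"
        )
    return (previous - 1) * 3 + (current - 1)


def is_reachable(previous: int, current: int) -> bool:
    """True for the 10 states a trajectory can actually occupy."""
    if previous == START:
        return current == START or current in ARMS
    return previous in ARMS and current in ARMS and previous != current


@dataclass
class TaskState:
    """Agent location: current arm and the immediately preceding arm."""

    previous: int
    current: int

    def __post_init__(self) -> None:
        if not is_reachable(self.previous, self.current):
            raise ValueError(
                f"inadmissible state ({self.previous}, {self.current})"
            )

    @property
    def index(self) -> int:
        return state_index(self.previous, self.current)


@dataclass
class SessionHistory:
    """Within-session visit record used by the reward rule.

    Tracks, per outer arm, the visit index of its most recent visit this
    session (-1 if unvisited). Resets at every session boundary.
    """

    visits: list = field(default_factory=list)
    _last_visit: dict = field(default_factory=lambda: {1: -1, 3: -1})

    def record(self, arm: int) -> None:
        if arm not in ARMS:
            raise ValueError(f"invalid arm {arm!r}")
        if arm in OUTER_ARMS:
            self._last_visit[arm] = len(self.visits)
        self.visits.append(arm)

    @property
    def last_outer(self) -> int | None:
        """Most recently visited outer arm this session, or None."""
        t1, t3 = self._last_visit[1], self._last_visit[3]
        if t1 < 0 and t3 < 0:
            return None
        return 1 if t1 > t3 else 3

    def correct_outer_arms(self) -> tuple[int, ...]:
        """Outer arm(s) that would be rewarded from the center arm.

        The less recently visited of arms 1 and 3 this session; both if
        neither outer arm has been visited yet (the session's first-visit
        exception).
        """
        t1, t3 = self._last_visit[1], self._last_visit[3]
        if t1 < 0 and t3 < 0:
            return OUTER_ARMS
        return (1,) if t1 < t3 else (3,)


def reward_rule(
    state: TaskState,
    history: SessionHistory,
    choice: int,
    *,
    reward_first_center: bool = True,
) -> int:
    """Reward delivered for visiting ``choice`` from ``state``.

    From any arm other than the center (including the session start
    position), reward is delivered at the center arm. From the center arm,
    reward is delivered at the less recently visited outer arm this session;
    if the center was the session's first visit, either outer arm is
    rewarded. ``reward_first_center`` controls whether a session-start visit
    to the center arm is itself rewarded (the delivery rule is silent on
    this trial; see package docs).
    """
    if choice not in ARMS:
        raise ValueError(f"invalid arm {choice!r}")
    if state.current in ARMS and choice == state.current:
        raise ValueError(f"revisit of arm {choice} is forbidden")
    if state.current == START:
        return int(choice == CENTER_ARM and reward_first_center)
    if state.current != CENTER_ARM:
        return int(choice == CENTER_ARM)
    return int(choice in history.correct_outer_arms())


def classify_trial(state: TaskState, choice: int, reward: int) -> tuple[str, int]:
    """Return ``(trial_type, is_error)`` for a visit.

    Inbound trials start at an outer arm or at the session-start position;
    the correct response is the center arm. Outbound trials start at the
    center arm; the correct response is the less recently visited outer arm
    (so an outbound error is exactly an unrewarded outbound visit). A
    session's first visit that is not to the center arm counts as an inbound
    error; an inbound error is determined by the rule (choice is not the
    center arm), so a session-start center visit is never an error
    regardless of reward bookkeeping.
    """
    if choice not in ARMS:
        raise ValueError(f"invalid arm {choice!r}")
    if state.current == CENTER_ARM:
        return OUTBOUND, int(reward == 0)
    return INBOUND, int(choice != CENTER_ARM)
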