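"""Probabilistic primitives of the indel process.

The simulation follows a Gillespie scheme along a branch whose length is
measured in expected substitutions per site.  For a sequence of current
length ``n`` there are ``n + 1`` insertion slots (before the first
character, between adjacent characters, and after the last), giving a
sequence-wise insertion rate ``R_ins = (n + 1) * r_ins``.  Deletions are
edge-corrected: a deletion of length ``S`` may start up to ``S - 1``
positions before the first character, so its start is drawn uniformly from
``n + S - 1`` locations and ``R_del = r_del * (n + S - 1)``.  With this
correction every character is deleted with probability ``S / (n + S - 1)``
per deletion event.  Waiting times between events are exponential with
rate ``lambda = R_ins + R_del``; the event is an insertion with
probability ``R_ins / lambda``.

Coordinate convention: characters of the current sequence are 1-based and
a virtual anchor occupies position 0.  An insertion position ``q`` means
"after character q" (``q = 0``: before the first character).  Deletion
events are emitted already clipped to the in-range form (1-based start,
effective length >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional

import numpy as np

__all__ = [
    "LengthDistribution",
    "IndelParams",
    "IndelEvent",
    "BranchSimState",
    "length_pmf",
    "mean_indel_length",
    "sample_indel_length",
    "sequence_rates",
    "sample_waiting_time",
    "classify_event",
    "sample_insertion_position",
    "sample_deletion_event",
    "simulate_branch_events",
]

INSERTION = "insertion"
DELETION = "deletion"


class ConfigurationError(ValueError):
    """Invalid model or distribution parameters."""


@dataclass(frozen=True)
class LengthDistribution:
    """Truncated indel length distribution on ``{1, ..., M}``.

    Parameters
    ----------
    family:
        ``"zipf"`` (mass proportional to ``k**-a``) or ``"geometric"``
        (mass proportional to ``p * (1 - p)**(k - 1)``), renormalized over
        the truncated support.
    parameter:
        Zipf exponent ``a > 0`` or geometric success probability
        ``0 < p <= 1``.
    truncation:
        The truncation point ``M`` (positive integer).
    inclusive:
        If True (default) the support is ``{1, ..., M}``; if False the
        support is ``{1, ..., M - 1}`` (exclusive upper bound).
    """

    family: Literal["zipf", "geometric"]
    parameter: float
    truncation: int
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("zipf", "geometric"):
            raise ConfigurationError(f"unknown length distribution family {self.family!r}")
        if int(self.truncation) != self.truncation or self.truncation < 1:
            raise ConfigurationError("truncation must be a positive integer")
        if not self.inclusive and self.truncation < 2:
            raise ConfigurationError("exclusive truncation needs M >= 2")
        if self.family == "zipf" and not self.parameter > 0:
            raise ConfigurationError("zipf exponent must be > 0")
        if self.family == "geometric" and not 0 < self.parameter <= 1:
            raise ConfigurationError("geometric probability must be in (0, 1]")

    @property
    def max_length(self) -> int:
        """Largest length in the support."""
        return int(self.truncation) if self.inclusive else int(self.truncation) - 1

    def pmf(self) -> np.ndarray:
        return length_pmf(self)

    def mean(self) -> float:
        return mean_indel_length(self)


def length_pmf(dist: LengthDistribution) -> np.ndarray:
    """Probability mass over lengths ``1..max_length`` (index 0 is length 1)."""
    k = np.arange(1, dist.max_length + 1, dtype=float)
    if dist.family == "zipf":
        mass = k ** (-dist.parameter)
    else:
        p = dist.parameter
        mass = p * (1.0 - p) ** (k - 1.0)
    return mass / mass.sum()


def mean_indel_length(dist: LengthDistribution) -> float:
    pmf = length_pmf(dist)
    k = np.arange(1, dist.max_length + 1, dtype=float)
    return float((k * pmf).sum())


def sample_indel_length(dist: LengthDistribution, rng: np.random.Generator) -> int:
    """Inverse-transform draw from the truncated length distribution."""
    cdf = _length_cdf(dist)
    return int(np.searchsorted(cdf, rng.random(), side="right")) + 1


# Per-distribution CDF cache; LengthDistribution is frozen/hashable.
_CDF_CACHE: dict[LengthDistribution, np.ndarray] = {}


def _length_cdf(dist: LengthDistribution) -> np.ndarray:
    cdf = _CDF_CACHE.get(dist)
    if cdf is None:
        cdf = np.cumsum(length_pmf(dist))
        cdf[-1] = 1.0
        _CDF_CACHE[dist] = cdf
    return cdf


@dataclass(frozen=True)
class IndelParams:
    """Per-site indel rates and length distribution(s).

    ``insertion_length`` / ``deletion_length`` default to the shared
    ``length_dist`` when not given.
    """

    insertion_rate: float
    deletion_rate: float
    length_dist: Optional[LengthDistribution] = None
    insertion_length: Optional[LengthDistribution] = None
    deletion_length: Optional[LengthDistribution] = None

    def __post_init__(self) -> None:
        if self.insertion_rate < 0 or self.deletion_rate < 0:
            raise ConfigurationError("indel rates must be nonnegative")
        if self.insertion_length is None:
            object.__setattr__(self, "insertion_length", self.length_dist)
        if self.deletion_length is None:
            object.__setattr__(self, "deletion_length", self.length_dist)
        if self.insertion_rate > 0 and self.insertion_length is None:
            raise ConfigurationError("insertion length distribution required")
        if self.deletion_rate > 0 and self.deletion_length is None:
            raise ConfigurationError("deletion length distribution required")


@dataclass(frozen=True)
class IndelEvent:
    """A single insertion or deletion in current-sequence coordinates.

    For insertions ``position`` is the slot ``q`` in ``0..n`` ("after
    character q").  For deletions ``position`` is the 1-based first deleted
    character and ``length`` the effective (clipped) deletion length;
    ``drawn`` keeps the pre-clipping draw from the length distribution.
    ``time`` is the cumulative waiting time along the branch.
    """

    kind: str
    position: int
    length: int
    time: float
    drawn: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in (INSERTION, DELETION):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("event length must be >= 1")
        if self.drawn is None:
            object.__setattr__(self, "drawn", self.length)


@dataclass
class BranchSimState:
    """Mutable state of a branch simulation (mostly for introspection)."""

    n_cur: int
    t_remaining: float
    k: int = 0
    rng: Optional[np.random.Generator] = field(default=None, repr=False)


def sequence_rates(
    n_cur: int, params: IndelParams, S_candidate: int
) -> tuple[float, float, float]:
    """Sequence-wise rates ``(R_ins, R_del, lambda)`` at length ``n_cur``.

    ``S_candidate`` is the candidate deletion length drawn for this
    Gillespie step; it widens the deletion start range by ``S - 1`` slots.
    An empty sequence cannot lose characters, so ``R_del = 0`` when
    ``n_cur == 0``.
    """
    if n_cur < 0 or S_candidate < 1:
        raise ValueError("n_cur must be >= 0 and S_candidate >= 1")
    r_ins = (n_cur + 1) * params.insertion_rate
    r_del = params.deletion_rate * (n_cur + S_candidate - 1) if n_cur > 0 else 0.0
    return r_ins, r_del, r_ins + r_del


def sample_waiting_time(lam: float, rng: np.random.Generator) -> float:
    if lam <= 0:
        raise ValueError("total rate must be positive")
    return rng.exponential(1.0 / lam)


def classify_event(R_ins: float, R_del: float, rng: np.random.Generator) -> str:
    if R_ins + R_del <= 0:
        raise ValueError("both rates are zero")
    return INSERTION if rng.random() < R_ins / (R_ins + R_del) else DELETION


def sample_insertion_position(n_cur: int, rng: np.random.Generator) -> int:
    """Uniform slot in ``{0, ..., n_cur}``; 0 = before the first character."""
    return int(rng.integers(0, n_cur + 1))


def sample_deletion_event(
    n_cur: int, S: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Edge-corrected deletion start, clipped to the sequence.

    The raw start is uniform over the ``n_cur + S - 1`` integers
    ``{2 - S, ..., n_cur}``; the returned event is the intersection of
    ``[start, start + S - 1]`` with ``[1, n_cur]``.
    """
    if n_cur < 1:
        raise ValueError("cannot delete from an empty sequence")
    raw = int(rng.integers(2 - S, n_cur + 1))
    start = max(raw, 1)
    end = min(raw + S - 1, n_cur)
    return start, end - start + 1


def simulate_branch_events(
    n0: int,
    branch_length: float,
    params: IndelParams,
    rng: np.random.Generator,
) -> tuple[list[IndelEvent], int]:
    """Gillespie stream of indel events along one branch.

    At every step one candidate deletion length is drawn first (it enters
    ``R_del`` and hence the waiting time) and discarded if the event turns
    out to be an insertion.  An event whose cumulative time would exceed
    the branch length is discarded and the branch ends.  Events are
    emitted in coordinates of the sequence as it exists at that moment and
    are consumed identically by all engines.

    Returns the ordered event list and the final sequence length.
    """
    if n0 < 0 or branch_length < 0:
        raise ValueError("n0 and branch_length must be nonnegative")
    events: list[IndelEvent] = []
    n = int(n0)
    t = 0.0
    while True:
        S_cand = (
            sample_indel_length(params.deletion_length, rng)
            if params.deletion_rate > 0 and n > 0
            else 1
        )
        R_ins, R_del, lam = sequence_rates(n, params, S_cand)
        if lam <= 0:
            break
        t += sample_waiting_time(lam, rng)
        if t > branch_length:
            break
        if classify_event(R_ins, R_del, rng) == INSERTION:
            q = sample_insertion_position(n, rng)
            S = sample_indel_length(params.insertion_length, rng)
            events.append(IndelEvent(INSERTION, q, S, t))
            n += S
        else:
            start, eff = sample_deletion_event(n, S_cand, rng)
            events.append(IndelEvent(DELETION, start, eff, t, drawn=S_cand))
            n -= eff
    return events, n


def iter_branch_events(
    n0: int, branch_length: float, params: IndelParams, rng: np.random.Generator
) -> Iterator[IndelEvent]:
    """Convenience generator over :func:`simulate_branch_events`."""
    events, _ = simulate_branch_events(n0, branch_length, params, rng)
    return iter(events)
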