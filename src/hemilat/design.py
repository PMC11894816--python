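"""Counterbalanced mini-block stimulus designs.

A localizer run presents mini-blocks of stimulus categories (plus rest
blocks, treated like any other condition) back to back.  The block order is
fully counterbalanced: every ordered pair of distinct conditions occurs as
an adjacent pair exactly once per run.  Such an order is an Eulerian circuit
on the complete directed graph over conditions, which exists for any k >= 2
because every vertex has equal in- and out-degree (k - 1).  A run with k
conditions therefore has k*(k-1) + 1 blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionSpec",
    "Block",
    "StimulusDesign",
    "build_block_design",
    "counterbalanced_sequence",
]

REST = "rest"


@dataclass(frozen=True)
class AcquisitionSpec:
    """Timing parameters of the block-design acquisition.

    Defaults follow a 5-run localizer: TR 2 s, 6 s mini-blocks of 12
    stimuli, 10 s lead-in for scanner steady state and 14 s tail for the
    BOLD response to return to baseline.
    """

    n_runs: int = 5
    tr_seconds: float = 2.0
    block_duration_seconds: float = 6.0
    stimuli_per_block: int = 12
    lead_in_seconds: float = 10.0
    tail_seconds: float = 14.0
    include_rest: bool = True

    def __post_init__(self) -> None:
        for name in ("tr_seconds", "block_duration_seconds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lead_in_seconds < 0 or self.tail_seconds < 0:
            raise ValueError("lead-in and tail must be nonnegative")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    def run_duration_seconds(self, n_blocks: int) -> float:
        return self.lead_in_seconds + n_blocks * self.block_duration_seconds + self.tail_seconds

    def n_timepoints(self, n_blocks: int) -> int:
        return int(np.ceil(self.run_duration_seconds(n_blocks) / self.tr_seconds))


@dataclass(frozen=True)
class Block:
    condition: str
    onset_seconds: float
    duration_seconds: float


@dataclass
class StimulusDesign:
    """Per-run ordered block schedules."""

    runs: list[list[Block]] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for run in self.runs:
            for b in run:
                seen.setdefault(b.condition, None)
        return list(seen)

    def validate_counterbalance(self) -> None:
        """Assert every ordered condition pair is adjacent exactly once per run."""
        for i, run in enumerate(self.runs):
            conds = sorted({b.condition for b in run})
            counts: dict[tuple[str, str], int] = {}
            for a, b in zip(run[:-1], run[1:]):
                counts[(a.condition, b.condition)] = counts.get((a.condition, b.condition), 0) + 1
            for a in conds:
                for b in conds:
                    if a == b:
                        continue
                    if counts.get((a, b), 0) != 1:
                        raise ValueError(
                            f"run {i}: ordered pair ({a}, {b}) adjacent "
                            f"{counts.get((a, b), 0)} times, expected 1"
                        )


def counterbalanced_sequence(conditions: list[str], rng: np.random.Generator) -> list[str]:
    """Random Eulerian circuit on the complete digraph over ``conditions``.

    Hierholzer's algorithm with randomized edge choice and start vertex;
    every valid counterbalanced order has positive probability.
    """
    k = len(conditions)
    if k < 2:
        raise ValueError("need at least 2 conditions to counterbalance")
    # out-neighbour lists, shuffled once; consumed from the end
    remaining: dict[int, list[int]] = {}
    for u in range(k):
        nbrs = [v for v in range(k) if v != u]
        rng.shuffle(nbrs)
        remaining[u] = nbrs

    start = int(rng.integers(k))
    circuit: list[int] = []
    stack = [start]
    while stack:
        u = stack[-1]
        if remaining[u]:
            stack.append(remaining[u].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    assert len(circuit) == k * (k - 1) + 1
    return [conditions[i] for i in circuit]


def build_block_design(
    acq: AcquisitionSpec,
    conditions: list[str],
    seed: int | np.random.Generator,
) -> StimulusDesign:
    """Build an ``acq.n_runs``-run design, each run independently counterbalanced.

    ``conditions`` are the stimulus categories; a rest condition is appended
    when ``acq.include_rest`` and participates in the counterbalancing like
    any other condition.  Blocks are back to back: block i starts at
    lead_in + i * block_duration.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    all_conditions = list(conditions)
    if acq.include_rest and REST not in all_conditions:
        all_conditions = all_conditions + [REST]
    if len(all_conditions) < 2:
        raise ValueError("need at least 2 conditions (including rest)")

    runs: list[list[Block]] = []
    for _ in range(acq.n_runs):
        order = counterbalanced_sequence(all_conditions, rng)
        run = [
            Block(
                condition=c,
                onset_seconds=acq.lead_in_seconds + i * acq.block_duration_seconds,
                duration_seconds=acq.block_duration_seconds,
            )
            for i, c in enumerate(order)
        ]
        runs.append(run)
    return StimulusDesign(runs=runs)
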