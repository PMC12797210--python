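"""Branch-level indel bookkeeping with an ordered block list.

A block ``(start, length, insertion)`` records a run of contiguous,
undisturbed parent positions — the original part (OP) beginning at the
parent coordinate ``start`` with ``length`` positions — followed by
``insertion`` characters added along the current branch (the added part,
AP).  A virtual anchor occupies parent position 0 and is counted inside
the first block, so a fresh branch over a parent of length ``n0`` starts
as the single block ``(0, n0 + 1, 0)``; insertions before the first
character live in the anchor block's AP.

Event coordinates: the current sequence is addressed through anchored
element indices (anchor = element 0, characters = elements ``1..n``).
An insertion at slot ``q`` goes immediately after anchored element ``q``;
a deletion starting at character ``p`` removes anchored elements
``p..p + S - 1``.  Locating an event scans the list, subtracting each
block's total ``T_i = L_i + I_i`` — O(b) per event, b the block count.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

from .evo_model import DELETION, INSERTION, IndelEvent

__all__ = [
    "Block",
    "initial_block_sequence",
    "current_length",
    "locate_block",
    "split_block",
    "apply_insertion_blocks",
    "apply_deletion_blocks",
    "apply_event_blocks",
    "evolve_branch_blocks",
    "blocks_to_recipe",
]


class Block(NamedTuple):
    start: int
    length: int
    insertion: int

    @property
    def total(self) -> int:
        return self.length + self.insertion


class CoordinateError(IndexError):
    """Event coordinates outside the current sequence."""


def initial_block_sequence(n0: int) -> list[Block]:
    """Single block covering the anchor plus the whole parent sequence."""
    if n0 < 0:
        raise ValueError("sequence length must be nonnegative")
    return [Block(0, n0 + 1, 0)]


def current_length(blocks: list[Block]) -> int:
    """Number of real characters (anchor excluded)."""
    return sum(b.total for b in blocks) - 1


def locate_block(
    blocks: list[Block], q: int, visits: list | None = None
) -> tuple[int, int]:
    """Find the block holding anchored element ``q``.

    Returns ``(block index, residual offset)`` where the residual is the
    element's 0-based offset within the block (OP first, AP after).
    ``visits``, when given, collects the number of blocks scanned.
    """
    if q < 0:
        raise CoordinateError(f"negative coordinate {q}")
    seen = 0
    for j, b in enumerate(blocks):
        seen += 1
        if q < b.total:
            if visits is not None:
                visits.append(seen)
            return j, q
        q -= b.total
    raise CoordinateError("coordinate beyond sequence end")


def split_block(block: Block, keep: int, new_ap: int) -> tuple[Block, Block]:
    """Split a block's OP, the prefix keeping ``keep`` OP elements.

    The prefix carries a fresh AP of ``new_ap`` characters; the suffix
    inherits the block's old AP.  This is the primitive behind an
    insertion that lands inside an OP.
    """
    if not 1 <= keep < block.length:
        raise ValueError(f"prefix must keep 1..{block.length - 1} OP elements")
    prefix = Block(block.start, keep, new_ap)
    suffix = Block(block.start + keep, block.length - keep, block.insertion)
    return prefix, suffix


def apply_insertion_blocks(blocks: list[Block], q: int, S: int) -> list[Block]:
    """Insert ``S`` characters immediately after anchored element ``q``.

    Inside an OP (before its last element) the block splits, the prefix
    carrying the new AP; at or after the last OP element the insertion
    merges into the block's AP.  Blocks after the event are untouched.
    """
    if S < 1:
        raise ValueError("insertion length must be >= 1")
    j, o = locate_block(blocks, q)
    b = blocks[j]
    if o < b.length - 1:
        prefix, suffix = split_block(b, o + 1, S)
        return blocks[:j] + [prefix, suffix] + blocks[j + 1 :]
    return blocks[:j] + [Block(b.start, b.length, b.insertion + S)] + blocks[j + 1 :]


def apply_deletion_blocks(blocks: list[Block], start: int, S: int) -> list[Block]:
    """Delete ``S`` characters beginning at character ``start`` (1-based).

    The deletion may span several blocks: boundary blocks are trimmed or
    split, fully covered blocks are dropped, and an AP orphaned by the
    loss of its whole OP is appended to the nearest surviving preceding
    block's AP (the anchor block always survives, so a home exists).
    """
    if S < 1:
        raise ValueError("deletion length must be >= 1")
    if start < 1:
        raise CoordinateError("the anchor cannot be deleted")
    if start + S - 1 > current_length(blocks):
        raise CoordinateError("deletion extends beyond sequence end")
    j, o = locate_block(blocks, start)
    out = list(blocks[:j])
    remaining = S
    a = o  # within-block offset of the first deleted element
    while remaining > 0:
        b = blocks[j]
        take = min(remaining, b.total - a)
        op_left = min(a, b.length)
        op_right = max(0, b.length - (a + take))
        ap_deleted = max(0, (a + take) - max(a, b.length))
        ap_left = b.insertion - ap_deleted
        if op_right > 0:
            # deletion ends inside the OP: suffix keeps the old AP
            if op_left > 0:
                out.append(Block(b.start, op_left, 0))
            out.append(Block(b.start + op_left + take, op_right, ap_left))
        elif op_left > 0:
            out.append(Block(b.start, op_left, ap_left))
        elif ap_left > 0:
            # OP fully deleted, AP survives: reattach to the previous block
            prev = out[-1]
            out[-1] = Block(prev.start, prev.length, prev.insertion + ap_left)
        remaining -= take
        a = 0
        j += 1
    out.extend(blocks[j:])
    return out


def apply_event_blocks(blocks: list[Block], event: IndelEvent) -> list[Block]:
    if event.kind == INSERTION:
        return apply_insertion_blocks(blocks, event.position, event.length)
    return apply_deletion_blocks(blocks, event.position, event.length)


def evolve_branch_blocks(
    n0: int, events: Iterable[IndelEvent], op_counter: list | None = None
) -> list[Block]:
    """Fold the branch's event stream into a block sequence.

    ``op_counter``, when given, collects the blocks visited per event
    (locate scan plus rebuilt tail), the O(b) work term.
    """
    blocks = initial_block_sequence(n0)
    for ev in events:
        if op_counter is not None:
            visits: list = []
            try:
                locate_block(blocks, ev.position, visits)
            except CoordinateError:
                pass
            op_counter.append(visits[0] if visits else len(blocks))
        blocks = apply_event_blocks(blocks, ev)
    return blocks


def blocks_to_recipe(blocks: list[Block]) -> list[tuple]:
    """Canonical branch recipe (see naive_engine.sequence_to_recipe).

    The anchor is excluded; adjacent copy runs over contiguous parent
    positions and adjacent insert runs are merged, so structurally
    different but equivalent block decompositions map to one recipe.
    """
    recipe: list[tuple] = []

    def add_copy(start: int, length: int) -> None:
        if length <= 0:
            return
        if recipe and recipe[-1][0] == "C" and recipe[-1][1] + recipe[-1][2] == start:
            recipe[-1] = ("C", recipe[-1][1], recipe[-1][2] + length)
        else:
            recipe.append(("C", start, length))

    def add_insert(length: int) -> None:
        if length <= 0:
            return
        if recipe and recipe[-1][0] == "I":
            recipe[-1] = ("I", recipe[-1][1] + length)
        else:
            recipe.append(("I", length))

    for i, b in enumerate(blocks):
        if i == 0:
            if b.start != 0:
                raise ValueError("first block must start at the anchor")
            add_copy(1, b.length - 1)
        else:
            add_copy(b.start, b.length)
        add_insert(b.insertion)
    return recipe
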