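"""Reference engine: every event is applied directly to an explicit sequence.

The evolving sequence is a Python list whose elements are position
identities, not residues: ancestral positions are the integers
``1..n0`` and every inserted character receives a fresh token from a
monotone counter.  Residues are attached only at alignment assembly, so
engine equivalence can be checked on homology rather than just length.

Cost is O(n) per event (list splicing), O(k(n + k)) per branch — this
engine is the correctness oracle for the block engines, not a fast path.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .evo_model import DELETION, INSERTION, IndelEvent, IndelParams, simulate_branch_events

__all__ = [
    "TokenGenerator",
    "apply_event_naive",
    "evolve_branch_naive",
    "evolve_tree_naive",
    "sequence_to_recipe",
]


class TokenGenerator:
    """Monotone counter handing out globally unique insertion tokens.

    Tokens are negative integers so they can never collide with ancestral
    position labels (positive integers).
    """

    def __init__(self) -> None:
        self._next = -1

    def take(self, count: int) -> list[int]:
        start = self._next
        self._next -= count
        return list(range(start, start - count, -1))


def apply_event_naive(
    seq: list, event: IndelEvent, tokens: TokenGenerator, ops: list | None = None
) -> list:
    """Apply one event to an explicit sequence, returning a new list.

    Insertion position ``q`` means after the q-th element (q = 0: front);
    deletions remove elements ``start..start + length - 1`` (1-based).
    """
    n = len(seq)
    if event.kind == INSERTION:
        q = event.position
        if not 0 <= q <= n:
            raise IndexError(f"insertion slot {q} out of range for length {n}")
        out = seq[:q] + tokens.take(event.length) + seq[q:]
    else:
        start, length = event.position, event.length
        if not (1 <= start and start + length - 1 <= n):
            raise IndexError(
                f"deletion [{start}, {start + length - 1}] out of range for length {n}"
            )
        out = seq[: start - 1] + seq[start - 1 + length :]
    if ops is not None:
        # element-copy cost of rebuilding the list, the O(n) term of §-style
        # naive complexity accounting
        ops.append(len(out))
    return out


def evolve_branch_naive(
    parent: Sequence, events: Iterable[IndelEvent], tokens: TokenGenerator | None = None
) -> list:
    """Fold of :func:`apply_event_naive` over an ordered event stream."""
    if tokens is None:
        tokens = TokenGenerator()
    seq = list(parent)
    for ev in events:
        seq = apply_event_naive(seq, ev, tokens)
    return seq


def evolve_tree_naive(tree, n0: int, params: IndelParams, rng_for_branch) -> dict:
    """Simulate indels over a whole tree with the naive engine.

    Parameters
    ----------
    tree:
        A :class:`evosim.cli_io.SimTree` (or any object with the same
        ``root`` / ``preorder_branches()`` interface).
    rng_for_branch:
        Callable mapping a branch index to a seeded ``numpy`` Generator,
        so the event streams are identical across engines and traversal
        orders.

    Returns a dict mapping node id to its explicit sequence; the root
    holds the labels ``1..n0``.
    """
    if n0 < 0:
        raise ValueError("root length must be nonnegative")
    tokens = TokenGenerator()
    seqs = {tree.root.id: list(range(1, n0 + 1))}
    for branch_index, (parent, child, blen) in enumerate(tree.preorder_branches()):
        if blen < 0:
            raise ValueError(f"negative branch length on branch to node {child.id}")
        parent_seq = seqs[parent.id]
        events, n_final = simulate_branch_events(
            len(parent_seq), blen, params, rng_for_branch(branch_index)
        )
        child_seq = evolve_branch_naive(parent_seq, events, tokens)
        assert len(child_seq) == n_final
        seqs[child.id] = child_seq
    return seqs


def sequence_to_recipe(parent: Sequence, child: Sequence) -> list[tuple]:
    """Express a child explicit sequence relative to its parent.

    Returns the canonical branch recipe: an ordered list of
    ``("C", start, length)`` items (copy parent positions
    ``start..start+length-1``, 1-based) and ``("I", length)`` items
    (insert ``length`` fresh characters), with maximal runs.
    """
    index_of = {id_: i + 1 for i, id_ in enumerate(parent)}
    recipe: list[tuple] = []
    for el in child:
        pos = index_of.get(el)
        if pos is None:
            if recipe and recipe[-1][0] == "I":
                recipe[-1] = ("I", recipe[-1][1] + 1)
            else:
                recipe.append(("I", 1))
        else:
            if (
                recipe
                and recipe[-1][0] == "C"
                and recipe[-1][1] + recipe[-1][2] == pos
            ):
                recipe[-1] = ("C", recipe[-1][1], recipe[-1][2] + 1)
            else:
                recipe.append(("C", pos, 1))
    return recipe
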