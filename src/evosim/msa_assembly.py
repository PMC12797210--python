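"""True-alignment assembly via a super-sequence of all positions ever created.

The super-sequence is a doubly linked list holding one element for every
position that ever existed during the simulation: the root characters
plus every insertion, in alignment order.  Each tree node keeps a
"pointer sequence" — its characters as ordered references into the
super-sequence — built block-by-block from the branch record while the
tree is traversed in preorder.  Insertions splice fresh elements into
the super-sequence immediately after the element preceding them in the
child, so positional homology is preserved exactly.

After the traversal, elements referenced by at least one emitted row get
their column flag set; flagged elements become alignment columns and
unflagged ones (characters deleted everywhere) produce no column, which
keeps the alignment free of gap-only columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import count
from typing import Iterable, Iterator, Optional, Sequence

from .block_list_engine import Block

__all__ = [
    "SuperElement",
    "SuperSequence",
    "Alignment",
    "init_super_sequence",
    "child_pointer_sequence",
    "recipe_to_blocks",
    "mark_columns",
    "assemble_alignment",
]

GAP = "-"
PLACEHOLDER = "N"


class SuperElement:
    __slots__ = ("id", "prev", "next", "flag")

    def __init__(self, id_: int) -> None:
        self.id = id_
        self.prev: Optional[SuperElement] = None
        self.next: Optional[SuperElement] = None
        self.flag = False

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<pos {self.id}{'*' if self.flag else ''}>"


class SuperSequence:
    """Ordered master template; ids are unique and creation-ordered."""

    def __init__(self, n0: int = 0) -> None:
        self._head = SuperElement(-1)  # sentinels, never exposed
        self._tail = SuperElement(-2)
        self._head.next = self._tail
        self._tail.prev = self._head
        self._ids = count(1)
        self.insert_run_after(None, n0)

    def __iter__(self) -> Iterator[SuperElement]:
        el = self._head.next
        while el is not self._tail:
            yield el
            el = el.next

    def __len__(self) -> int:
        return sum(1 for _ in self)

    def insert_run_after(self, anchor: Optional[SuperElement], n: int) -> list[SuperElement]:
        """Splice ``n`` fresh elements right after ``anchor`` (None: front)."""
        left = anchor if anchor is not None else self._head
        return self._splice(left, n)

    def insert_run_before(self, element: SuperElement, n: int) -> list[SuperElement]:
        return self._splice(element.prev, n)

    def _splice(self, left: SuperElement, n: int) -> list[SuperElement]:
        run = [SuperElement(next(self._ids)) for _ in range(n)]
        right = left.next
        for el in run:
            el.prev = left
            left.next = el
            left = el
        left.next = right
        right.prev = left
        return run

    def clear_flags(self) -> None:
        for el in self:
            el.flag = False


def init_super_sequence(n0: int) -> tuple[SuperSequence, list[SuperElement]]:
    """Super-sequence seeded with the root's ``n0`` positions.

    Returns the super-sequence and the root's pointer sequence.
    """
    if n0 < 0:
        raise ValueError("root length must be nonnegative")
    sup = SuperSequence(n0)
    return sup, list(sup)


def child_pointer_sequence(
    parent: Sequence[SuperElement],
    blocks: Sequence[Block],
    sup: SuperSequence,
) -> list[SuperElement]:
    """Pointer sequence of a child node from its branch's block record.

    For each block in order the parent references covered by the OP
    (anchor excluded) are copied, then ``insertion`` fresh super-sequence
    elements are spliced in immediately after the last copied reference
    (before the region's first parent reference when nothing has been
    copied yet) and appended.  O(n') per branch.
    """
    child: list[SuperElement] = []
    n_parent = len(parent)
    for i, b in enumerate(blocks):
        if i == 0:
            if b.start != 0:
                raise ValueError("first block must start at the anchor")
            lo, hi = 0, b.length - 1
        else:
            lo, hi = b.start - 1, b.start - 1 + b.length
        if hi > n_parent:
            raise ValueError(
                f"block {b} reaches parent position {hi}, parent has {n_parent}"
            )
        child.extend(parent[lo:hi])
        if b.insertion:
            if child:
                run = sup.insert_run_after(child[-1], b.insertion)
            elif parent:
                run = sup.insert_run_before(parent[0], b.insertion)
            else:
                run = sup.insert_run_after(None, b.insertion)
            child.extend(run)
    return child


def recipe_to_blocks(recipe: Iterable[tuple]) -> list[Block]:
    """Canonical block sequence from a branch recipe.

    The recipe is the engine-agnostic list of ``("C", start, length)`` /
    ``("I", length)`` items; contiguous copies merge into one OP.
    """
    blocks = [Block(0, 1, 0)]
    for item in recipe:
        if item[0] == "C":
            _, start, length = item
            last = blocks[-1]
            if last.insertion == 0 and last.start + last.length == start:
                blocks[-1] = Block(last.start, last.length + length, 0)
            else:
                blocks.append(Block(start, length, 0))
        elif item[0] == "I":
            last = blocks[-1]
            blocks[-1] = Block(last.start, last.length, last.insertion + item[1])
        else:
            raise ValueError(f"unknown recipe item {item!r}")
    return blocks


def mark_columns(
    sup: SuperSequence, emitted_rows: Iterable[Sequence[SuperElement]]
) -> None:
    """Flag exactly the elements referenced by at least one emitted row."""
    sup.clear_flags()
    for row in emitted_rows:
        for el in row:
            el.flag = True


@dataclass
class Alignment:
    """Gapped character matrix over the flagged super-sequence columns."""

    names: list[str]
    rows: list[str]

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def degapped(self, name: str) -> str:
        return self.row(name).replace(GAP, "")

    def __iter__(self):
        return iter(zip(self.names, self.rows))


def assemble_alignment(
    sup: SuperSequence,
    rows: dict[str, Sequence[SuperElement]],
    placeholder: str = PLACEHOLDER,
) -> Alignment:
    """Template alignment: one column per flagged element, in order.

    Cells are ``placeholder`` where the row references the column's
    element and ``-`` otherwise.  Flags must already be computed for the
    chosen row set (see :func:`mark_columns`).
    """
    col_of: dict[int, int] = {}
    for el in sup:
        if el.flag:
            col_of[el.id] = len(col_of)
    width = len(col_of)
    names, texts = [], []
    for name, refs in rows.items():
        cells = [GAP] * width
        for el in refs:
            c = col_of.get(el.id)
            if c is not None:
                cells[c] = placeholder
        names.append(name)
        texts.append("".join(cells))
    return Alignment(names, texts)
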