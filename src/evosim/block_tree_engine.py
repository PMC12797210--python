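"""AVL order-statistic storage of blocks: O(log b) locate per event.

Blocks are held in an AVL tree in sequence order.  No explicit keys are
stored — every event shifts downstream coordinates, so the tree is
addressed through two subtree aggregates maintained at each node:

* ``count`` — number of blocks in the subtree (rank addressing), and
* ``total`` — sum of block totals ``T_i = L_i + I_i`` (element-offset
  addressing; the root's total is current length + 1, anchor included).

Locating the block holding anchored element ``q`` descends once from the
root comparing ``q`` against left-subtree totals; block-level edits are
rank-based inserts/removals with standard AVL rebalancing.  One tree is
built per branch, and the in-order traversal always equals the block
list the sequential engine would hold.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .block_list_engine import Block, CoordinateError, split_block
from .evo_model import DELETION, INSERTION, IndelEvent

__all__ = ["AvlBlockTree", "avl_from_blocks", "evolve_branch_avl"]


class _Node:
    __slots__ = ("block", "left", "right", "height", "count", "total")

    def __init__(self, block: Block) -> None:
        self.block = block
        self.left: Optional[_Node] = None
        self.right: Optional[_Node] = None
        self.height = 1
        self.count = 1
        self.total = block.total


def _h(n: Optional[_Node]) -> int:
    return n.height if n else 0


def _c(n: Optional[_Node]) -> int:
    return n.count if n else 0


def _t(n: Optional[_Node]) -> int:
    return n.total if n else 0


def _update(n: _Node) -> None:
    n.height = 1 + max(_h(n.left), _h(n.right))
    n.count = 1 + _c(n.left) + _c(n.right)
    n.total = n.block.total + _t(n.left) + _t(n.right)


def _rot_left(n: _Node) -> _Node:
    r = n.right
    n.right, r.left = r.left, n
    _update(n)
    _update(r)
    return r


def _rot_right(n: _Node) -> _Node:
    l = n.left
    n.left, l.right = l.right, n
    _update(n)
    _update(l)
    return l


def _rebalance(n: _Node) -> _Node:
    _update(n)
    bal = _h(n.left) - _h(n.right)
    if bal > 1:
        if _h(n.left.left) < _h(n.left.right):
            n.left = _rot_left(n.left)
        return _rot_right(n)
    if bal < -1:
        if _h(n.right.right) < _h(n.right.left):
            n.right = _rot_right(n.right)
        return _rot_left(n)
    return n


def _insert_at(root: Optional[_Node], i: int, block: Block) -> _Node:
    if root is None:
        return _Node(block)
    if i <= _c(root.left):
        root.left = _insert_at(root.left, i, block)
    else:
        root.right = _insert_at(root.right, i - _c(root.left) - 1, block)
    return _rebalance(root)


def _delete_at(root: _Node, i: int) -> Optional[_Node]:
    lc = _c(root.left)
    if i < lc:
        root.left = _delete_at(root.left, i)
    elif i > lc:
        root.right = _delete_at(root.right, i - lc - 1)
    else:
        if root.left is None:
            return root.right
        if root.right is None:
            return root.left
        succ = root.right
        while succ.left is not None:
            succ = succ.left
        root.block = succ.block
        root.right = _delete_at(root.right, 0)
    return _rebalance(root)


def _get_at(root: _Node, i: int) -> Block:
    while True:
        lc = _c(root.left)
        if i < lc:
            root = root.left
        elif i > lc:
            i -= lc + 1
            root = root.right
        else:
            return root.block


def _set_at(root: _Node, i: int, block: Block) -> None:
    lc = _c(root.left)
    if i < lc:
        _set_at(root.left, i, block)
    elif i > lc:
        _set_at(root.right, i - lc - 1, block)
    else:
        root.block = block
    _update(root)


class AvlBlockTree:
    """One branch's block store, AVL-backed.

    ``locate_visits`` accumulates the number of nodes touched by each
    locate call — the instrumentation behind the O(log b) claim.
    """

    def __init__(self, n0: int | None = None) -> None:
        self.root: Optional[_Node] = None
        self.locate_visits: list[int] = []
        if n0 is not None:
            if n0 < 0:
                raise ValueError("sequence length must be nonnegative")
            self.root = _Node(Block(0, n0 + 1, 0))

    # -- queries -----------------------------------------------------------
    @property
    def block_count(self) -> int:
        return _c(self.root)

    @property
    def height(self) -> int:
        return _h(self.root)

    def current_length(self) -> int:
        return _t(self.root) - 1

    def flatten(self) -> list[Block]:
        out: list[Block] = []

        def walk(n: Optional[_Node]) -> None:
            if n is None:
                return
            walk(n.left)
            out.append(n.block)
            walk(n.right)

        walk(self.root)
        return out

    def locate(self, q: int) -> tuple[int, int]:
        """Block index and residual offset of anchored element ``q``.

        Same answer as ``locate_block`` on the flattened sequence, found
        by descending with subtree-total comparisons.
        """
        if q < 0:
            raise CoordinateError(f"negative coordinate {q}")
        node = self.root
        idx = 0
        visits = 0
        while node is not None:
            visits += 1
            lt = _t(node.left)
            if q < lt:
                node = node.left
            elif q < lt + node.block.total:
                self.locate_visits.append(visits)
                return idx + _c(node.left), q - lt
            else:
                q -= lt + node.block.total
                idx += _c(node.left) + 1
                node = node.right
        raise CoordinateError("coordinate beyond sequence end")

    # -- updates -----------------------------------------------------------
    def apply_event(self, event: IndelEvent) -> None:
        """Same block-level semantics as the sequential list engine."""
        if event.kind == INSERTION:
            self._apply_insertion(event.position, event.length)
        else:
            self._apply_deletion(event.position, event.length)

    def _apply_insertion(self, q: int, S: int) -> None:
        if S < 1:
            raise ValueError("insertion length must be >= 1")
        j, o = self.locate(q)
        b = _get_at(self.root, j)
        if o < b.length - 1:
            prefix, suffix = split_block(b, o + 1, S)
            _set_at(self.root, j, prefix)
            self.root = _insert_at(self.root, j + 1, suffix)
        else:
            _set_at(self.root, j, Block(b.start, b.length, b.insertion + S))

    def _apply_deletion(self, start: int, S: int) -> None:
        if S < 1:
            raise ValueError("deletion length must be >= 1")
        if start < 1:
            raise CoordinateError("the anchor cannot be deleted")
        if start + S - 1 > self.current_length():
            raise CoordinateError("deletion extends beyond sequence end")
        j, a = self.locate(start)
        remaining = S
        while remaining > 0:
            b = _get_at(self.root, j)
            take = min(remaining, b.total - a)
            op_left = min(a, b.length)
            op_right = max(0, b.length - (a + take))
            ap_deleted = max(0, (a + take) - max(a, b.length))
            ap_left = b.insertion - ap_deleted
            if op_right > 0:
                right = Block(b.start + op_left + take, op_right, ap_left)
                if op_left > 0:
                    _set_at(self.root, j, Block(b.start, op_left, 0))
                    self.root = _insert_at(self.root, j + 1, right)
                else:
                    _set_at(self.root, j, right)
            elif op_left > 0:
                _set_at(self.root, j, Block(b.start, op_left, ap_left))
                j += 1
            else:
                self.root = _delete_at(self.root, j)
                if ap_left > 0:
                    prev = _get_at(self.root, j - 1)
                    _set_at(
                        self.root, j - 1, Block(prev.start, prev.length, prev.insertion + ap_left)
                    )
            remaining -= take
            a = 0


def avl_from_blocks(blocks: list[Block]) -> AvlBlockTree:
    """Balanced build; in-order traversal returns exactly ``blocks``."""

    def build(lo: int, hi: int) -> Optional[_Node]:
        if lo >= hi:
            return None
        mid = (lo + hi) // 2
        node = _Node(blocks[mid])
        node.left = build(lo, mid)
        node.right = build(mid + 1, hi)
        _update(node)
        return node

    tree = AvlBlockTree()
    tree.root = build(0, len(blocks))
    return tree


def evolve_branch_avl(n0: int, events: Iterable[IndelEvent]) -> AvlBlockTree:
    """Fold the branch's event stream into an AVL block tree."""
    tree = AvlBlockTree(n0)
    for ev in events:
        tree.apply_event(ev)
    return tree
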