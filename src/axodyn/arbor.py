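"""Arbor morphometry: branch orders, counts, lengths, and the axon
complexity index (ACI).

An arbor trace is a rooted tree of polyline branches hanging off a marked
axon shaft. Branches emanating directly from the shaft are primary
(order 1); a branch off an order-``k`` branch has order ``k + 1``. The ACI
is the mean branch order — 1 for a purely primary arbor, larger as the
arbor elaborates higher-order branches — and arbors are classed simple
(ACI < 1.4) or complex (ACI >= 1.4).

Traces are read and written as SWC-like text (id, type, x, y, z, radius,
parent): shaft nodes carry structure type 2 and branch nodes type 3. On
reading, a branch starts at a node whose parent is a shaft node; within
non-shaft nodes, the first child (in file order) continues its parent's
branch and later children start child branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

__all__ = [
    "Branch",
    "ArborTrace",
    "assign_orders",
    "branch_stats",
    "aci",
    "classify_arbor",
    "synthetic_arbor",
]

ACI_COMPLEX_THRESHOLD = 1.4


class ArborStructureError(ValueError):
    """Raised for cyclic, rootless or otherwise malformed traces."""


@dataclass
class Branch:
    branch_id: int
    parent_id: Optional[int]  # None: emanates from the shaft
    points_um: np.ndarray  # (k, 3) polyline, starting at the attachment point

    def __post_init__(self) -> None:
        pts = np.asarray(self.points_um, dtype=float)
        if pts.ndim == 2 and pts.shape[1] == 2:
            pts = np.column_stack([pts, np.zeros(len(pts))])
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("branch polyline needs >= 2 points of dim 2 or 3")
        self.points_um = pts

    @property
    def length_um(self) -> float:
        seg = np.diff(self.points_um, axis=0)
        return float(np.sqrt((seg**2).sum(axis=1)).sum())


@dataclass
class ArborTrace:
    """Rooted tree of polyline branches with a marked shaft path."""

    shaft_um: np.ndarray  # (k, 3) shaft polyline
    branches: List[Branch] = field(default_factory=list)

    def __post_init__(self) -> None:
        pts = np.asarray(self.shaft_um, dtype=float)
        if pts.ndim == 2 and pts.shape[1] == 2:
            pts = np.column_stack([pts, np.zeros(len(pts))])
        self.shaft_um = pts
        ids = [b.branch_id for b in self.branches]
        if len(set(ids)) != len(ids):
            raise ArborStructureError("duplicate branch ids")

    def branch_map(self) -> Dict[int, Branch]:
        return {b.branch_id: b for b in self.branches}

    # -- SWC-like text ------------------------------------------------------

    SHAFT_TYPE, BRANCH_TYPE = 2, 3

    @classmethod
    def from_swc(cls, source) -> "ArborTrace":
        if hasattr(source, "read"):
            text = source.read()
        else:
            try:
                with open(source) as fh:
                    text = fh.read()
            except (OSError, ValueError):
                text = source
        nodes = {}
        order_seen = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            nid, ntype, x, y, z, radius, parent = line.split()[:7]
            nodes[int(nid)] = {
                "type": int(ntype),
                "xyz": (float(x), float(y), float(z)),
                "parent": int(parent),
            }
            order_seen.append(int(nid))

        shaft_ids = [i for i in order_seen if nodes[i]["type"] == cls.SHAFT_TYPE]
        if not shaft_ids:
            raise ArborStructureError("no shaft nodes (structure type 2) in trace")
        shaft = np.array([nodes[i]["xyz"] for i in shaft_ids])

        children: Dict[int, list] = {}
        for nid in order_seen:
            p = nodes[nid]["parent"]
            if p != -1:
                children.setdefault(p, []).append(nid)

        # group branch nodes into branches: new branch when parent is shaft
        # or when the node is not its parent's first child
        node_branch: Dict[int, int] = {}
        branches = []
        next_id = 0
        for nid in order_seen:
            if nodes[nid]["type"] == cls.SHAFT_TYPE:
                continue
            p = nodes[nid]["parent"]
            if p == -1:
                raise ArborStructureError(f"branch node {nid} has no parent")
            if p not in nodes:
                raise ArborStructureError(f"node {nid} references missing parent {p}")
            parent_is_shaft = nodes[p]["type"] == cls.SHAFT_TYPE
            first_child = children[p][0] == nid
            if parent_is_shaft or not first_child:
                bid = next_id
                next_id += 1
                parent_branch = None if parent_is_shaft else node_branch[p]
                branches.append(
                    {"branch_id": bid, "parent_id": parent_branch,
                     "pts": [nodes[p]["xyz"], nodes[nid]["xyz"]]}
                )
            else:
                bid = node_branch[p]
                next(b for b in branches if b["branch_id"] == bid)["pts"].append(
                    nodes[nid]["xyz"]
                )
            node_branch[nid] = bid
        trace = cls(
            shaft_um=shaft,
            branches=[
                Branch(b["branch_id"], b["parent_id"], np.array(b["pts"]))
                for b in branches
            ],
        )
        assign_orders(trace)  # validates acyclicity
        return trace

    def to_swc(self, path=None) -> str:
        lines = ["# axodyn arbor trace", "# id type x y z radius parent"]
        nid = 1
        shaft_node_at = {}
        prev = -1
        for k, p in enumerate(self.shaft_um):
            lines.append(f"{nid} {self.SHAFT_TYPE} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f} 0.5 {prev}")
            shaft_node_at[k] = nid
            prev = nid
            nid += 1

        def _nearest_shaft_node(pt):
            d = np.linalg.norm(self.shaft_um - pt, axis=1)
            return shaft_node_at[int(np.argmin(d))]

        last_node_of: Dict[int, int] = {}
        emitted = set()

        def _emit(branch: Branch):
            nonlocal nid
            if branch.branch_id in emitted:
                return
            if branch.parent_id is not None:
                parent_branch = self.branch_map()[branch.parent_id]
                _emit(parent_branch)
                # attach to the parent branch's node nearest the first point
                # (children must be written after the continuation chain so
                # first-child-continues grouping survives a round trip)
                pn_pts, pn_ids = parent_nodes[branch.parent_id]
                # never attach at the parent's terminal node: a child hanging
                # off a chain end would read back as its continuation
                if len(pn_ids) > 1:
                    pn_pts, pn_ids = pn_pts[:-1], pn_ids[:-1]
                d = [np.linalg.norm(p - branch.points_um[0]) for p in pn_pts]
                parent = pn_ids[int(np.argmin(d))]
            else:
                parent = _nearest_shaft_node(branch.points_um[0])
            for p in branch.points_um[1:]:
                lines.append(
                    f"{nid} {self.BRANCH_TYPE} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f} 0.3 {parent}"
                )
                parent = nid
                nid += 1
            parent_nodes[branch.branch_id] = (
                [p for p in branch.points_um[1:]],
                list(range(nid - (len(branch.points_um) - 1), nid)),
            )
            emitted.add(branch.branch_id)

        parent_nodes: Dict[int, tuple] = {}
        for b in self.branches:
            _emit(b)
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# morphometry
# ---------------------------------------------------------------------------


def assign_orders(trace: ArborTrace) -> Dict[int, int]:
    """Branch order per branch id: 1 off the shaft, parent order + 1 below.

    Raises :class:`ArborStructureError` on cycles or missing parents.
    """
    bmap = trace.branch_map()
    orders: Dict[int, int] = {}

    def order_of(bid, stack=()):
        if bid in orders:
            return orders[bid]
        if bid in stack:
            raise ArborStructureError(f"cycle detected at branch {bid}")
        b = bmap.get(bid)
        if b is None:
            raise ArborStructureError(f"branch {bid} referenced but not present")
        o = 1 if b.parent_id is None else order_of(b.parent_id, stack + (bid,)) + 1
        orders[bid] = o
        return o

    for b in trace.branches:
        order_of(b.branch_id)
    return orders


def branch_stats(trace: ArborTrace) -> dict:
    """Counts per order, total branch count and total branch length (um).

    Branch length covers each branch's own polyline only, not descendants.
    """
    orders = assign_orders(trace)
    per_order: Dict[int, int] = {}
    for o in orders.values():
        per_order[o] = per_order.get(o, 0) + 1
    total_len = float(sum(b.length_um for b in trace.branches))
    return {
        "counts_per_order": dict(sorted(per_order.items())),
        "n_branches": len(trace.branches),
        "total_length_um": total_len,
    }


def aci(trace: ArborTrace) -> float:
    """Axon complexity index: mean branch order over all branches.

    ``(sum of branch orders) / (number of branches)``; 1 exactly when every
    branch is primary. Returns NaN for an arbor with no branches.
    """
    if not trace.branches:
        return float("nan")
    orders = assign_orders(trace)
    return float(np.mean(list(orders.values())))


def classify_arbor(aci_value: float, threshold: float = ACI_COMPLEX_THRESHOLD) -> str:
    """``simple`` below the 1.4 ACI threshold, ``complex`` at or above."""
    if not np.isfinite(aci_value):
        return "undefined"
    return "simple" if aci_value < threshold else "complex"


def synthetic_arbor(
    seed: int = 0,
    n_primary: tuple = (2, 6),
    child_prob: float = 0.45,
    max_order: int = 4,
    shaft_length_um: float = 100.0,
) -> ArborTrace:
    """Random test arbor: primary branches off a straight shaft, each
    spawning children with probability ``child_prob`` per order level."""
    rng = np.random.default_rng(seed)
    shaft = np.array([[0.0, 0.0, 0.0], [shaft_length_um, 0.0, 0.0]])
    branches: List[Branch] = []
    next_id = 0

    def grow(parent_id, start, order):
        nonlocal next_id
        bid = next_id
        next_id += 1
        angle = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(4.0, 15.0)
        end = start + length * np.array([np.cos(angle), np.sin(angle), 0.0])
        mid = (start + end) / 2 + rng.normal(0, 0.5, 3)
        branches.append(Branch(bid, parent_id, np.array([start, mid, end])))
        if order < max_order:
            for _ in range(rng.binomial(2, child_prob)):
                t = rng.uniform(0.4, 1.0)
                attach = start + t * (end - start)
                grow(bid, attach, order + 1)

    for _ in range(rng.integers(n_primary[0], n_primary[1] + 1)):
        root = np.array([rng.uniform(5, shaft_length_um - 5), 0.0, 0.0])
        grow(None, root, 1)
    return ArborTrace(shaft_um=shaft, branches=branches)
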