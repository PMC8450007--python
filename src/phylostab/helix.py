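"""Dot-bracket helix annotation, bulge signatures, and small-parsimony
transition counting of discrete characters on a tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

from .errors import DataError, ValidationError
from .io import Node, SupportTree

__all__ = [
    "Loop",
    "HelixAnnotation",
    "BulgeSignature",
    "parse_dotbracket",
    "bulge_signature",
    "fitch_transitions",
]


class Loop(NamedTuple):
    """Unpaired region between two consecutive nested pairs (or a hairpin).

    ``size5``/``size3`` count unpaired residues on the lower-index (5')
    and higher-index (3') strand; ``outer`` is the enclosing pair.
    """

    kind: str  # 'bulge5' | 'bulge3' | 'internal' | 'hairpin'
    size5: int
    size3: int
    outer: tuple[int, int]
    inner: tuple[int, int] | None


@dataclass(frozen=True)
class HelixAnnotation:
    sequence: str
    structure: str
    pairs: tuple[tuple[int, int], ...]  # (i, j) with i < j, sorted by i
    loops: tuple[Loop, ...]

    @property
    def pairing(self) -> dict[int, int]:
        out = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def n_unpaired(self) -> int:
        return len(self.sequence) - 2 * len(self.pairs)


def parse_dotbracket(sequence: str, structure: str) -> HelixAnnotation:
    """Stack-match a dot-bracket string and classify its loops.

    Between consecutive nested pairs (i,j) > (i',j') with a = i'-i-1 and
    b = j-j'-1 unpaired residues: a>0,b=0 -> bulge5; a=0,b>0 -> bulge3;
    a>0,b>0 -> internal. A pair with nothing nested is a hairpin of size
    j-i-1. Pseudoknots are outside the grammar and multiloop interiors are
    left unclassified.
    """
    if len(sequence) != len(structure):
        raise ValidationError(
            f"sequence length {len(sequence)} != structure length {len(structure)}"
        )
    bad = set(structure) - set("().")
    if bad:
        raise DataError(f"structure contains unexpected symbols: {sorted(bad)}")

    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(structure):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise DataError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
    if stack:
        raise DataError(f"unbalanced '(' at position {stack[-1]}")
    pairs.sort()

    # direct-nesting children of each pair
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    enclosing: list[tuple[int, int]] = []
    for p in pairs:
        while enclosing and not (enclosing[-1][0] < p[0] and p[1] < enclosing[-1][1]):
            enclosing.pop()
        if enclosing:
            children[enclosing[-1]].append(p)
        enclosing.append(p)

    loops: list[Loop] = []
    for outer in pairs:
        kids = children[outer]
        i, j = outer
        if not kids:
            loops.append(Loop("hairpin", j - i - 1, 0, outer, None))
        elif len(kids) == 1:
            ii, jj = kids[0]
            a, b = ii - i - 1, j - jj - 1
            if a > 0 and b == 0:
                loops.append(Loop("bulge5", a, 0, outer, kids[0]))
            elif a == 0 and b > 0:
                loops.append(Loop("bulge3", 0, b, outer, kids[0]))
            elif a > 0 and b > 0:
                loops.append(Loop("internal", a, b, outer, kids[0]))
            # a == b == 0: stacked pair, no loop
        # len(kids) >= 2: multiloop; not classified here

    return HelixAnnotation(
        sequence=sequence,
        structure=structure,
        pairs=tuple(pairs),
        loops=tuple(loops),
    )


@dataclass(frozen=True)
class BulgeSignature:
    """Counts of 1-nt bulges per strand within a helix window.

    ``label`` is 'typical' for exactly one 1-nt 3'-strand bulge,
    'double-bulge' for two, 'other' otherwise.
    """

    n_bulge5_1nt: int
    n_bulge3_1nt: int
    n_other_loops: int
    label: str


def bulge_signature(
    h: HelixAnnotation, window: tuple[int, int] | None = None
) -> BulgeSignature:
    """Count 1-nt bulges by strand, optionally restricted to a 0-based
    half-open position window over the loops' enclosing pairs."""
    n5 = n3 = other = 0
    for loop in h.loops:
        if window is not None:
            lo, hi = window
            if not (lo <= loop.outer[0] and loop.outer[1] < hi):
                continue
        if loop.kind == "bulge5" and loop.size5 == 1:
            n5 += 1
        elif loop.kind == "bulge3" and loop.size3 == 1:
            n3 += 1
        else:
            other += 1
    if n3 == 1:
        label = "typical"
    elif n3 == 2:
        label = "double-bulge"
    else:
        label = "other"
    return BulgeSignature(n5, n3, other, label)


def fitch_transitions(
    tree: SupportTree, tip_states: Mapping[str, object]
) -> tuple[int, dict[frozenset, object]]:
    """Minimal number of state changes of a discrete character on a tree.

    Uses the unit-cost small-parsimony dynamic program (exact on
    multifurcating trees, equivalent to the classic union/intersection
    pass on binary ones); the count is invariant to where the tree is
    rooted. Returns the count and one optimal labeling keyed by each
    node's descendant-leaf set. States are opaque, hashable symbols.
    """
    leaves = tree.leaf_labels()
    missing = [l for l in leaves if l not in tip_states]
    if missing:
        raise DataError(f"leaves without a state: {missing}")

    alphabet = sorted({tip_states[l] for l in leaves}, key=repr)
    state_idx = {s: i for i, s in enumerate(alphabet)}
    big = len(leaves) + 1  # safe infinity for unit costs

    cost: dict[int, list[int]] = {}
    clade: dict[int, frozenset] = {}
    order = list(tree.postorder())
    for node in order:
        if node.is_leaf():
            clade[id(node)] = frozenset([node.label])
            row = [big] * len(alphabet)
            row[state_idx[tip_states[node.label]]] = 0
            cost[id(node)] = row
        else:
            clade[id(node)] = frozenset().union(
                *(clade[id(c)] for c in node.children)
            )
            row = []
            for s in range(len(alphabet)):
                total = 0
                for c in node.children:
                    crow = cost[id(c)]
                    total += min(
                        crow[t] + (0 if t == s else 1)
                        for t in range(len(alphabet))
                    )
                row.append(total)
            cost[id(node)] = row

    root_row = cost[id(tree.root)]
    best = min(root_row)

    # backtrack one optimal labeling (smallest alphabet index on ties)
    assignment: dict[frozenset, object] = {}
    chosen: dict[int, int] = {id(tree.root): root_row.index(best)}
    for node in reversed(order):  # preorder
        s = chosen[id(node)]
        assignment[clade[id(node)]] = alphabet[s]
        for c in node.children:
            crow = cost[id(c)]
            t_best = min(
                range(len(alphabet)),
                key=lambda t: (crow[t] + (0 if t == s else 1), t),
            )
            chosen[id(c)] = t_best

    return int(best), assignment
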