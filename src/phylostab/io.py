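"""Readers, writers and carrier types for the formats the pipeline touches.

Trees travel as Newick with numeric internal-node labels holding edge
supports (the convention of common ML programs); alignments as FASTA;
per-column score/category tables as TSV. All internal coordinates are
0-based half-open; external tables are 1-based by default.
"""

from __future__ import annotations

import io as _stdio
import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from dendropy.utility.error import DataParseError

from .errors import DataError, NewickError, ValidationError

__all__ = [
    "TaxonSet",
    "Node",
    "TreeMeta",
    "SupportTree",
    "TreeSet",
    "Alignment",
    "SiteScores",
    "parse_newick",
    "parse_newick_list",
    "write_newick",
    "read_tree_collection",
    "read_alignment",
    "write_alignment",
    "read_site_table",
    "write_site_table",
    "SUPPORT_SCALES",
]

#: Declared support scales and their admissible ranges.
SUPPORT_SCALES = {"percent": (0.0, 100.0), "probability": (0.0, 1.0)}


class TaxonSet:
    """Ordered universe of unique taxon names.

    The order given at construction is the canonical order for the whole
    run; bipartition bitsets index into it.
    """

    __slots__ = ("labels", "index")

    def __init__(self, labels: Iterable[str]):
        labels = tuple(labels)
        if not labels:
            raise ValidationError("TaxonSet must be non-empty")
        seen = set()
        for lab in labels:
            if lab in seen:
                raise ValidationError(f"duplicate taxon label: {lab!r}")
            seen.add(lab)
        self.labels = labels
        self.index = {lab: i for i, lab in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label) -> bool:
        return label in self.index

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonSet) and self.labels == other.labels

    def __hash__(self):
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxonSet({len(self.labels)} taxa)"

    def position(self, label: str) -> int:
        try:
            return self.index[label]
        except KeyError:
            raise DataError(f"taxon {label!r} not in taxon set") from None


class Node:
    """Node of a (rooted rendering of an) unrooted tree.

    ``support`` and ``length`` describe the edge between the node and its
    parent; both are ``None`` on the root.
    """

    __slots__ = ("label", "children", "length", "support")

    def __init__(self, label=None, children=None, length=None, support=None):
        self.label = label
        self.children: list[Node] = list(children) if children else []
        self.length = length
        self.support = support

    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(
            self.label,
            [c.copy() for c in self.children],
            self.length,
            self.support,
        )

    def __repr__(self) -> str:
        if self.is_leaf():
            return f"Node({self.label!r})"
        return f"Node(<{len(self.children)} children>)"


@dataclass
class TreeMeta:
    strategy: str | None = None
    source: str | None = None
    tree_id: str | None = None
    alignment_length: int | None = None
    log_likelihood: float | None = None


class SupportTree:
    """Unrooted tree with per-internal-edge numeric supports.

    Stored as an arbitrarily rooted node structure; after normalization the
    root has >=3 children (or is a 2/3-leaf degenerate) and no internal
    node has degree 2.
    """

    def __init__(self, root: Node, scale: str = "percent", meta: TreeMeta | None = None):
        if scale not in SUPPORT_SCALES:
            raise ValidationError(f"unknown support scale {scale!r}")
        self.root = root
        self.scale = scale
        self.meta = meta if meta is not None else TreeMeta()

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterable[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(n.label for n in self.postorder() if n.is_leaf())

    def internal_edge_nodes(self) -> list[Node]:
        """Non-root internal nodes; each one carries one internal edge."""
        return [
            n for n in self.postorder() if not n.is_leaf() and n is not self.root
        ]

    def copy(self) -> "SupportTree":
        return SupportTree(self.root.copy(), self.scale, replace(self.meta))

    # -- normalization -----------------------------------------------------

    def normalize(self, merge_conflict: str = "error") -> "SupportTree":
        """Suppress degree-2 nodes in place and validate supports.

        A root with exactly two children is unrooted by merging the two
        child edges; conflicting supports on the merged edge raise unless
        ``merge_conflict='max'``.
        """
        self._suppress_unary(merge_conflict)
        while len(self.root.children) == 2:
            a, b = self.root.children
            keep = a if not a.is_leaf() else b
            if keep.is_leaf():
                break  # 2-leaf degenerate tree; nothing to suppress
            other = b if keep is a else a
            other.length = _merge_lengths(keep.length, other.length)
            other.support = _merge_supports(
                keep.support, other.support, merge_conflict
            )
            keep.length = keep.support = None
            keep.children.append(other)
            self.root = keep
            self._suppress_unary(merge_conflict)
        self._validate_leaves()
        self._validate_supports()
        return self

    def _suppress_unary(self, merge_conflict: str) -> None:
        def rebuild(node: Node) -> Node:
            node.children = [rebuild(c) for c in node.children]
            if len(node.children) == 1:
                child = node.children[0]
                child.length = _merge_lengths(node.length, child.length)
                child.support = _merge_supports(
                    node.support, child.support, merge_conflict
                )
                return child
            return node

        self.root = rebuild(self.root)

    def _validate_leaves(self) -> None:
        labels = [n.label for n in self.postorder() if n.is_leaf()]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate leaf labels: {dupes}")
        if any(l is None or l == "" for l in labels):
            raise NewickError("unlabeled leaf encountered")

    def _validate_supports(self) -> None:
        lo, hi = SUPPORT_SCALES[self.scale]
        for node in self.internal_edge_nodes():
            s = node.support
            if s is not None and not (lo <= s <= hi):
                raise DataError(
                    f"support {s} outside declared scale {self.scale!r} [{lo}, {hi}]"
                )

    # -- editing -----------------------------------------------------------

    def pruned_to(self, keep: Iterable[str]) -> "SupportTree":
        """Copy of the tree restricted to ``keep`` leaf labels."""
        keep = set(keep)
        if len(keep) < 4:
            raise DataError(
                f"cannot prune to fewer than 4 taxa (got {len(keep)})"
            )

        def rebuild(node: Node) -> Node | None:
            if node.is_leaf():
                return node.copy() if node.label in keep else None
            kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
            if not kids:
                return None
            new = Node(node.label, kids, node.length, node.support)
            return new

        root = rebuild(self.root)
        if root is None:
            raise DataError("pruning removed every leaf")
        out = SupportTree(root, self.scale, replace(self.meta))
        # supports merged with max: pruning legitimately collapses edges
        out.normalize(merge_conflict="max")
        return out


def _merge_lengths(a, b):
    if a is None:
        return b
    if b is None:
        return a
    return a + b


def _merge_supports(a, b, policy: str):
    if a is None:
        return b
    if b is None:
        return a
    if a == b:
        return a
    if policy == "max":
        return max(a, b)
    raise NewickError(
        f"conflicting supports {a} and {b} on a merged edge "
        "(pass merge_conflict='max' to take the maximum)"
    )


@dataclass
class TreeSet:
    """Trees over one shared taxon universe, tagged by strategy."""

    taxa: TaxonSet
    trees: list[SupportTree]
    strategies: list[str]
    pruned_taxa: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.trees) != len(self.strategies):
            raise ValidationError("trees and strategies must align")
        expected = set(self.taxa.labels)
        for tree in self.trees:
            got = set(tree.leaf_labels())
            if got != expected:
                missing = sorted(expected - got)
                extra = sorted(got - expected)
                raise DataError(
                    "tree leaf set differs from taxon universe "
                    f"(source={tree.meta.source!r}, missing={missing}, extra={extra})"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def tree_ids(self) -> list[str]:
        out = []
        for i, tree in enumerate(self.trees):
            out.append(tree.meta.tree_id or f"tree{i:03d}")
        return out


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: "dendropy.Tree", scale: str, merge_conflict: str,
                   source: str | None = None) -> SupportTree:
    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            return Node(label=label, length=dnode.edge.length)
        support = None
        if dnode.label is not None:
            try:
                support = float(dnode.label)
            except ValueError:
                warnings.warn(
                    f"ignoring non-numeric internal label {dnode.label!r}",
                    stacklevel=4,
                )
        return Node(
            children=[convert(c) for c in dnode.child_nodes()],
            length=dnode.edge.length,
            support=support,
        )

    root = convert(dtree.seed_node)
    root.support = root.length = None  # a root carries no edge
    tree = SupportTree(root, scale=scale, meta=TreeMeta(source=source))
    return tree.normalize(merge_conflict=merge_conflict)


def parse_newick(text: str, scale: str = "percent",
                 merge_conflict: str = "error") -> SupportTree:
    """Parse a single Newick statement into an unrooted :class:`SupportTree`.

    Numeric internal-node labels become edge supports; non-numeric ones are
    dropped with a warning. A degree-2 root is suppressed; unequal supports
    on the two merged edges raise unless ``merge_conflict='max'``.
    """
    if scale not in SUPPORT_SCALES:
        raise ValidationError(f"unknown support scale {scale!r}")
    text = text.strip()
    if not text.endswith(";"):
        raise NewickError("Newick statement must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=False,
            preserve_underscores=True,
        )
    except DataParseError as exc:
        raise NewickError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree, scale, merge_conflict)


def parse_newick_list(text: str, scale: str = "percent",
                      merge_conflict: str = "error",
                      source: str | None = None) -> list[SupportTree]:
    """Parse one or more ';'-terminated Newick statements."""
    try:
        dtrees = dendropy.TreeList.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except DataParseError as exc:
        raise NewickError(f"malformed Newick ({source or 'input'}): {exc}") from exc
    if len(dtrees) == 0:
        raise DataError(f"no trees found in {source or 'input'}")
    return [_from_dendropy(t, scale, merge_conflict, source) for t in dtrees]


def _fmt_support(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return format(x, ".12g")


def _fmt_length(x: float) -> str:
    return format(x, ".12g")


def write_newick(tree: SupportTree, taxa: TaxonSet | None = None) -> str:
    """Deterministic Newick: children sorted by their smallest contained taxon.

    The sort key is the taxon's position in ``taxa`` when given, otherwise
    the lexicographically smallest leaf label. Supports are written as
    internal-node labels; branch lengths only when present.
    """

    def sort_key(node: Node):
        leaves = (n.label for n in _subtree_postorder(node) if n.is_leaf())
        if taxa is not None:
            return min(taxa.position(l) for l in leaves)
        return min(leaves)

    def render(node: Node, is_root: bool) -> str:
        if node.is_leaf():
            out = _escape_label(node.label)
        else:
            kids = sorted(node.children, key=sort_key)
            out = "(" + ",".join(render(k, False) for k in kids) + ")"
            if not is_root and node.support is not None:
                out += _fmt_support(node.support)
        if not is_root and node.length is not None:
            out += ":" + _fmt_length(node.length)
        return out

    return render(tree.root, True) + ";"


def _subtree_postorder(node: Node):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


_NEWICK_UNSAFE = set("(),:;'[] \t\n")


def _escape_label(label: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Tree collections
# ---------------------------------------------------------------------------


def read_manifest(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a TSV manifest of (tree file path, strategy label)."""
    entries: list[tuple[str, str]] = []
    base = os.path.dirname(os.fspath(path))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and [p.lower() for p in parts[:2]] == ["path", "strategy"]:
                continue
            if len(parts) < 2:
                raise DataError(f"manifest line {lineno}: need path<TAB>strategy")
            p = parts[0]
            if base and not os.path.isabs(p):
                p = os.path.join(base, p)
            entries.append((p, parts[1]))
    if not entries:
        raise DataError("empty manifest")
    return entries


def read_tree_collection(entries, scale: str = "percent",
                         prune_to_common: bool = False,
                         merge_conflict: str = "error") -> TreeSet:
    """Load trees from ``(path, strategy)`` entries into a :class:`TreeSet`.

    By default all trees must share one leaf set; with ``prune_to_common``
    every tree is pruned to the intersection and the dropped taxa are
    recorded on the returned set.
    """
    if isinstance(entries, (str, os.PathLike)):
        entries = read_manifest(entries)
    entries = list(entries)
    if not entries:
        raise DataError("empty manifest")

    trees: list[SupportTree] = []
    strategies: list[str] = []
    for path, strategy in entries:
        with open(path) as fh:
            text = fh.read()
        parsed = parse_newick_list(
            text, scale=scale, merge_conflict=merge_conflict,
            source=os.path.basename(os.fspath(path)),
        )
        for k, tree in enumerate(parsed):
            tree.meta.strategy = strategy
            stem = os.path.splitext(os.path.basename(os.fspath(path)))[0]
            tree.meta.tree_id = stem if len(parsed) == 1 else f"{stem}.{k}"
            trees.append(tree)
            strategies.append(strategy)

    leaf_sets = [set(t.leaf_labels()) for t in trees]
    union_order: list[str] = []
    seen: set[str] = set()
    for t in trees:
        for lab in t.leaf_labels():
            if lab not in seen:
                seen.add(lab)
                union_order.append(lab)

    common = set.intersection(*leaf_sets)
    if not prune_to_common:
        for t, ls in zip(trees, leaf_sets):
            if ls != leaf_sets[0]:
                raise DataError(
                    f"leaf set of {t.meta.source!r} differs from "
                    f"{trees[0].meta.source!r}; rerun with prune_to_common"
                )
        taxa = TaxonSet(sorted(leaf_sets[0]))
        return TreeSet(taxa, trees, strategies)

    if len(common) < 4:
        raise DataError(
            f"common taxon intersection has only {len(common)} taxa (<4)"
        )
    dropped = tuple(sorted(set(union_order) - common))
    pruned = [
        t if set(t.leaf_labels()) == common else t.pruned_to(common)
        for t in trees
    ]
    taxa = TaxonSet(sorted(common))
    return TreeSet(taxa, pruned, strategies, pruned_taxa=dropped)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """Equal-length sequence records; gap character '-'."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValidationError("ids and seqs must align")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise DataError(f"duplicate sequence ids: {dupes}")
        if self.seqs:
            n = len(self.seqs[0])
            for sid, s in zip(self.ids, self.seqs):
                if len(s) != n:
                    raise DataError(
                        f"record {sid!r} has length {len(s)}, expected {n}"
                    )

    @property
    def n_seq(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def column(self, j: int) -> str:
        return "".join(s[j] for s in self.seqs)

    def take_columns(self, cols: Sequence[int]) -> "Alignment":
        cols = list(cols)
        return Alignment(
            self.ids, tuple("".join(s[j] for j in cols) for s in self.seqs)
        )

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{s}\n" for i, s in zip(self.ids, self.seqs))


def read_alignment(source) -> Alignment:
    """Read an aligned FASTA (path, handle, or raw text starting with '>')."""
    if isinstance(source, str) and source.lstrip().startswith(">"):
        handle = _stdio.StringIO(source)
    elif hasattr(source, "read"):
        handle = source
    else:
        handle = open(source)
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if handle is not source and not isinstance(source, str):
            handle.close()
        elif isinstance(source, str) and not source.lstrip().startswith(">"):
            handle.close()
    if len(records) < 2:
        raise DataError(f"alignment needs >=2 records, found {len(records)}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).replace(".", "-") for r in records)
    return Alignment(ids, seqs)


def write_alignment(alignment: Alignment, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(alignment.to_fasta())


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteScores:
    """Per-column numeric scores plus optional rate categories (1 = slowest)."""

    values: np.ndarray
    categories: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.categories is not None:
            cats = np.asarray(self.categories, dtype=int)
            object.__setattr__(self, "categories", cats)
            if len(cats) != len(self.values):
                raise ValidationError("categories length must match values")
            present = sorted(set(cats.tolist()))
            if present and present != list(range(1, max(present) + 1)):
                raise DataError(
                    f"categories must form a contiguous range from 1, got {present}"
                )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_categories(self) -> int:
        if self.categories is None:
            return 0
        return int(self.categories.max())


def read_site_table(source, n_sites: int, one_based: bool = True) -> SiteScores:
    """Read a TSV of ``site<TAB>value[<TAB>category]`` into dense SiteScores."""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and ("\n" in source or "\t" in source):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()

    values = np.full(n_sites, np.nan)
    categories = np.zeros(n_sites, dtype=int)
    has_cat = None
    seen: set[int] = set()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        try:
            site = int(parts[0])
        except ValueError:
            if lineno == 1:
                continue  # header row
            raise DataError(f"site table line {lineno}: bad site {parts[0]!r}")
        idx = site - 1 if one_based else site
        if not 0 <= idx < n_sites:
            raise DataError(
                f"site {site} out of range for n_sites={n_sites} "
                f"({'1-based' if one_based else '0-based'})"
            )
        if idx in seen:
            raise DataError(f"duplicate site {site}")
        seen.add(idx)
        if len(parts) < 2:
            raise DataError(f"site table line {lineno}: missing value")
        values[idx] = float(parts[1])
        row_has_cat = len(parts) >= 3
        if has_cat is None:
            has_cat = row_has_cat
        elif has_cat != row_has_cat:
            raise DataError("inconsistent category column across rows")
        if row_has_cat:
            categories[idx] = int(parts[2])

    if len(seen) != n_sites:
        missing = sorted(set(range(n_sites)) - seen)
        shown = [m + 1 if one_based else m for m in missing[:5]]
        raise DataError(f"missing sites (first few): {shown}")
    return SiteScores(values, categories if has_cat else None)


def write_site_table(scores: SiteScores, one_based: bool = True) -> str:
    lines = []
    for i, v in enumerate(scores.values):
        site = i + 1 if one_based else i
        row = f"{site}\t{format(float(v), '.12g')}"
        if scores.categories is not None:
            row += f"\t{int(scores.categories[i])}"
        lines.append(row)
    return "\n".join(lines) + "\n"
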