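"""Canonical bipartitions, RF distance, and the trees x splits support matrix.

A bipartition is the pair of leaf sets induced by deleting an internal
edge. It is stored as an integer bitset over the taxon universe, oriented
so that the side NOT containing taxon 0 is kept; trivial splits (a side
with fewer than 2 taxa) are excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .io import Node, SupportTree, TaxonSet, TreeSet

__all__ = [
    "Bipartition",
    "BipartitionSupportMatrix",
    "extract_bipartitions",
    "rf_distance",
    "build_support_matrix",
]


@dataclass(frozen=True, order=True)
class Bipartition:
    """Non-trivial split in canonical orientation (bit 0 never set).

    Ordering is by (size, mask), the byte-stable column order used by
    :class:`BipartitionSupportMatrix`.
    """

    size: int
    mask: int
    n_taxa: int = field(compare=False)

    @staticmethod
    def from_mask(mask: int, n_taxa: int) -> "Bipartition":
        full = (1 << n_taxa) - 1
        if mask & 1:
            mask = full & ~mask
        size = mask.bit_count()
        if not 2 <= size <= n_taxa - 2:
            raise ValidationError(
                f"trivial split: canonical side has {size} of {n_taxa} taxa"
            )
        return Bipartition(size=size, mask=mask, n_taxa=n_taxa)

    @staticmethod
    def from_side(side: Iterable[str], taxa: TaxonSet) -> "Bipartition":
        mask = 0
        for label in side:
            mask |= 1 << taxa.position(label)
        return Bipartition.from_mask(mask, len(taxa))

    def indices(self) -> tuple[int, ...]:
        """0-based taxon positions on the canonical side."""
        return tuple(i for i in range(self.n_taxa) if self.mask >> i & 1)

    def side_labels(self, taxa: TaxonSet) -> tuple[str, ...]:
        return tuple(taxa.labels[i] for i in self.indices())

    def complement_indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.n_taxa) if not self.mask >> i & 1)

    def encode(self, taxa: TaxonSet) -> str:
        """Canonical-side taxon names, sorted, joined by '|'."""
        return "|".join(sorted(self.side_labels(taxa)))

    @staticmethod
    def decode(encoded: str, taxa: TaxonSet) -> "Bipartition":
        return Bipartition.from_side(encoded.split("|"), taxa)


def extract_bipartitions(
    tree: SupportTree, taxa: TaxonSet
) -> list[tuple[Bipartition, float | None]]:
    """One (split, support) pair per internal edge of ``tree``.

    The tree's leaf set must equal the taxon universe (prune first if not).
    Edges lacking a support yield ``None`` in the support slot.
    """
    leaves = set(tree.leaf_labels())
    universe = set(taxa.labels)
    if leaves - universe:
        raise DataError(
            f"taxa in tree but not in taxon set: {sorted(leaves - universe)}"
        )
    if universe - leaves:
        raise DataError(
            f"taxa missing from tree: {sorted(universe - leaves)}; "
            "prune the collection to a common universe first"
        )

    masks: dict[int, int] = {}  # id(node) -> leaf bitmask
    out: list[tuple[Bipartition, float | None]] = []
    for node in tree.postorder():
        if node.is_leaf():
            masks[id(node)] = 1 << taxa.position(node.label)
        else:
            m = 0
            for c in node.children:
                m |= masks[id(c)]
            masks[id(node)] = m
            if node is not tree.root:
                size = m.bit_count()
                if 2 <= size <= len(taxa) - 2:
                    out.append((Bipartition.from_mask(m, len(taxa)), node.support))
    return out


def rf_distance(t1: SupportTree, t2: SupportTree) -> int:
    """Robinson-Foulds distance: |symmetric difference of split sets|."""
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise DataError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}"
        )
    taxa = TaxonSet(sorted(l1))
    s1 = {b for b, _ in extract_bipartitions(t1, taxa)}
    s2 = {b for b, _ in extract_bipartitions(t2, taxa)}
    return len(s1 ^ s2)


# ---------------------------------------------------------------------------
# Support matrix
# ---------------------------------------------------------------------------


@dataclass
class BipartitionSupportMatrix:
    """Trees x bipartitions table of support values (the PCA input).

    ``values[i, j]`` is the support of split ``splits[j]`` in tree ``i``,
    the ``fill`` value when the split is absent from that tree, and NaN
    when the edge is present but carries no support (a sentinel rejected
    by downstream PCA). ``fill=None`` switches to missing-marker mode in
    which absent cells are NaN too.
    """

    taxa: TaxonSet
    splits: list[Bipartition]
    values: np.ndarray
    tree_ids: list[str]
    strategies: list[str]
    scale: str = "percent"
    fill: float | None = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.tree_ids), len(self.splits)):
            raise ValidationError(
                f"values shape {self.values.shape} != "
                f"({len(self.tree_ids)}, {len(self.splits)})"
            )
        if len(self.tree_ids) != len(self.strategies):
            raise ValidationError("tree_ids and strategies must align")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column_encodings(self) -> list[str]:
        return [b.encode(self.taxa) for b in self.splits]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    # -- serialization -----------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.tree_ids, columns=self.column_encodings()
        )
        df.insert(0, "strategy", self.strategies)
        df.index.name = "tree"
        return df

    def to_csv(self) -> str:
        return self.to_dataframe().to_csv(lineterminator="\n")

    @classmethod
    def from_csv(cls, text: str, taxa: TaxonSet, scale: str = "percent",
                 fill: float | None = 0.0) -> "BipartitionSupportMatrix":
        import io as _stdio

        df = pd.read_csv(_stdio.StringIO(text), index_col=0)
        strategies = df.pop("strategy").astype(str).tolist()
        splits = [Bipartition.decode(c, taxa) for c in df.columns]
        return cls(
            taxa=taxa,
            splits=splits,
            values=df.to_numpy(dtype=float),
            tree_ids=[str(i) for i in df.index],
            strategies=strategies,
            scale=scale,
            fill=fill,
        )

    def to_json(self) -> str:
        payload = {
            "taxa": list(self.taxa.labels),
            "splits": self.column_encodings(),
            "values": [
                [None if np.isnan(v) else float(v) for v in row]
                for row in self.values
            ],
            "tree_ids": list(self.tree_ids),
            "strategies": list(self.strategies),
            "scale": self.scale,
            "fill": self.fill,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "BipartitionSupportMatrix":
        payload = json.loads(text)
        taxa = TaxonSet(payload["taxa"])
        values = np.array(
            [[np.nan if v is None else v for v in row] for row in payload["values"]],
            dtype=float,
        ).reshape(len(payload["tree_ids"]), len(payload["splits"]))
        return cls(
            taxa=taxa,
            splits=[Bipartition.decode(e, taxa) for e in payload["splits"]],
            values=values,
            tree_ids=payload["tree_ids"],
            strategies=payload["strategies"],
            scale=payload["scale"],
            fill=payload["fill"],
        )


def build_support_matrix(
    treeset: TreeSet, fill: float | None = 0.0
) -> BipartitionSupportMatrix:
    """Assemble the trees x union-of-splits support matrix.

    Columns are ordered by (split size, mask) so output is byte-stable.
    """
    if len(treeset) == 0:
        raise DataError("empty tree set")
    per_tree = [extract_bipartitions(t, treeset.taxa) for t in treeset.trees]
    union = sorted({b for entries in per_tree for b, _ in entries})
    col_index = {b: j for j, b in enumerate(union)}

    n, p = len(treeset), len(union)
    base = np.nan if fill is None else float(fill)
    values = np.full((n, p), base)
    for i, entries in enumerate(per_tree):
        for b, support in entries:
            values[i, col_index[b]] = np.nan if support is None else support

    scale = treeset.trees[0].scale if treeset.trees else "percent"
    return BipartitionSupportMatrix(
        taxa=treeset.taxa,
        splits=union,
        values=values,
        tree_ids=treeset.tree_ids(),
        strategies=list(treeset.strategies),
        scale=scale,
        fill=fill,
    )
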