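"""Reduction of a support matrix to backbone splits.

A backbone split respects a user-supplied partition of the taxa into
groups: every group falls wholly on one side, and projecting onto group
labels still separates at least one group from another. Columns failing
that, or lacking the required support presence across trees, are dropped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bipartitions import Bipartition, BipartitionSupportMatrix
from .errors import DataError, ValidationError
from .io import TaxonSet

__all__ = ["GroupScheme", "is_group_respecting", "reduce_matrix"]


@dataclass(frozen=True)
class GroupScheme:
    """Taxon -> group assignment with a stable group order."""

    assignment: dict
    groups: tuple[str, ...]

    @classmethod
    def from_pairs(cls, pairs) -> "GroupScheme":
        assignment: dict[str, str] = {}
        groups: list[str] = []
        for taxon, group in pairs:
            if taxon in assignment:
                raise DataError(f"taxon {taxon!r} assigned twice")
            assignment[taxon] = group
            if group not in groups:
                groups.append(group)
        if not assignment:
            raise DataError("empty group scheme")
        return cls(assignment=assignment, groups=tuple(groups))

    @classmethod
    def from_tsv(cls, source) -> "GroupScheme":
        if hasattr(source, "read"):
            text = source.read()
        elif isinstance(source, str) and "\n" in source:
            text = source
        else:
            with open(source) as fh:
                text = fh.read()
        pairs = []
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and [p.lower() for p in parts[:2]] == ["taxon", "group"]:
                continue
            if len(parts) < 2:
                raise DataError(f"group scheme line {lineno}: need taxon<TAB>group")
            pairs.append((parts[0], parts[1]))
        return cls.from_pairs(pairs)

    def to_tsv(self) -> str:
        lines = ["taxon\tgroup"]
        lines += [f"{t}\t{g}" for t, g in self.assignment.items()]
        return "\n".join(lines) + "\n"

    def members(self, group: str) -> tuple[str, ...]:
        return tuple(t for t, g in self.assignment.items() if g == group)

    def validate_against(self, taxa: TaxonSet, unassigned: str = "error") -> None:
        if unassigned not in ("error", "wildcard"):
            raise ValidationError(f"unknown unassigned policy {unassigned!r}")
        foreign = sorted(set(self.assignment) - set(taxa.labels))
        if foreign:
            raise DataError(f"group scheme names unknown taxa: {foreign}")
        if unassigned == "error":
            missing = sorted(set(taxa.labels) - set(self.assignment))
            if missing:
                raise DataError(
                    f"taxa without a group assignment: {missing} "
                    "(pass unassigned='wildcard' to ignore them)"
                )


def is_group_respecting(
    b: Bipartition,
    scheme: GroupScheme,
    taxa: TaxonSet,
    unassigned: str = "error",
) -> tuple[bool, tuple[frozenset, frozenset] | None]:
    """Does ``b`` keep every group intact, with a non-trivial group projection?

    Returns ``(flag, (groups_on_canonical_side, groups_on_other_side))``;
    the projection is ``None`` when the flag is false. Unassigned taxa
    raise by default, or never violate under ``unassigned='wildcard'``.
    """
    scheme.validate_against(taxa, unassigned)
    side0 = set(b.side_labels(taxa))
    groups0: set[str] = set()
    groups1: set[str] = set()
    for group in scheme.groups:
        members = scheme.members(group)
        inside = sum(1 for t in members if t in side0)
        if inside == 0:
            groups1.add(group)
        elif inside == len(members):
            groups0.add(group)
        else:
            return False, None
    if not groups0 or not groups1:
        return False, None
    return True, (frozenset(groups0), frozenset(groups1))


def reduce_matrix(
    m: BipartitionSupportMatrix,
    scheme: GroupScheme,
    min_support: float = 50.0,
    min_presence: float = 0.5,
    unassigned: str = "error",
) -> tuple[BipartitionSupportMatrix, pd.DataFrame]:
    """Keep only backbone columns passing a support-presence filter.

    A column survives iff it is group-respecting and has support
    ``>= min_support`` in at least a ``min_presence`` fraction of trees.
    Returns the reduced matrix and a per-column report (split, kept,
    reason). Raises if nothing survives.
    """
    if not 0.0 <= min_presence <= 1.0:
        raise ValidationError(f"min_presence must be in [0, 1], got {min_presence}")
    scheme.validate_against(m.taxa, unassigned)

    n_rows = len(m.tree_ids)
    kept_idx: list[int] = []
    rows = []
    for j, b in enumerate(m.splits):
        ok, projection = is_group_respecting(b, scheme, m.taxa, unassigned)
        if not ok:
            reason = "not-group-respecting"
            kept = False
        else:
            col = m.values[:, j]
            with np.errstate(invalid="ignore"):
                presence = np.count_nonzero(col >= min_support) / n_rows
            if presence >= min_presence:
                kept = True
                reason = "kept"
                kept_idx.append(j)
            else:
                kept = False
                reason = (
                    f"presence {presence:.3f} < {min_presence:.3f} "
                    f"at min_support {min_support:g}"
                )
        rows.append(
            {
                "split": b.encode(m.taxa),
                "kept": kept,
                "reason": reason,
                "group_projection": (
                    "|".join(sorted(projection[0])) + " vs "
                    + "|".join(sorted(projection[1]))
                    if projection
                    else ""
                ),
            }
        )
    report = pd.DataFrame(rows, columns=["split", "kept", "reason", "group_projection"])

    if not kept_idx:
        raise DataError(
            "backbone reduction removed every column "
            f"({sum(r['reason'] == 'not-group-respecting' for r in rows)} "
            f"not group-respecting, rest below presence threshold out of {len(rows)})"
        )

    reduced = BipartitionSupportMatrix(
        taxa=m.taxa,
        splits=[m.splits[j] for j in kept_idx],
        values=m.values[:, kept_idx].copy(),
        tree_ids=list(m.tree_ids),
        strategies=list(m.strategies),
        scale=m.scale,
        fill=m.fill,
    )
    return reduced, report


def write_reduction_report(report: pd.DataFrame, path: str | os.PathLike) -> None:
    report.to_csv(path, sep="\t", index=False, lineterminator="\n")
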