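"""Alignment-thinning generators: gap/block masking, score-threshold series,
and stepwise removal of the fastest rate categories.

All generators preserve row order and sequence ids, and report the kept
original column indices so masked positions can be traced back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .io import Alignment, SiteScores

__all__ = [
    "MaskPolicy",
    "MaskedAlignment",
    "gap_block_mask",
    "score_threshold_series",
    "rate_strip_series",
    "column_map_table",
]

GAP = "-"


@dataclass(frozen=True)
class MaskPolicy:
    """Parameters of the thinning generators.

    ``gap_threshold`` is the minimum NON-gap fraction for a column to be
    kept (a column with exactly half gaps survives at the 0.5 default);
    ``min_block`` is the minimum run length of consecutive kept columns.
    """

    gap_threshold: float = 0.5
    min_block: int = 3
    score_thresholds: tuple[float, ...] = ()
    strip_steps: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gap_threshold <= 1.0:
            raise ValidationError(
                f"gap_threshold must be in [0, 1], got {self.gap_threshold}"
            )
        if self.min_block < 1:
            raise ValidationError(f"min_block must be >= 1, got {self.min_block}")
        ts = tuple(self.score_thresholds)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValidationError(
                f"score_thresholds must be strictly ascending, got {ts}"
            )


@dataclass(frozen=True)
class MaskedAlignment:
    """An alignment together with the original columns it retains."""

    alignment: Alignment
    kept_columns: tuple[int, ...]
    provenance: str = ""

    def __post_init__(self):
        ks = self.kept_columns
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValidationError("kept_columns must be strictly ascending")
        if len(ks) != self.alignment.length:
            raise ValidationError(
                f"kept_columns has {len(ks)} entries for an alignment of "
                f"length {self.alignment.length}"
            )

    @property
    def length(self) -> int:
        return self.alignment.length


def _non_gap_fraction(a: Alignment) -> np.ndarray:
    counts = np.zeros(a.length, dtype=int)
    for seq in a.seqs:
        for j, ch in enumerate(seq):
            if ch != GAP:
                counts[j] += 1
    return counts / a.n_seq


def gap_block_mask(
    a: Alignment, gap_threshold: float = 0.5, min_block: int = 3
) -> MaskedAlignment:
    """Two-step column mask: non-gap fraction threshold, then short-run removal.

    Step 1 keeps column ``c`` iff its non-gap fraction is ``>= gap_threshold``;
    step 2 deletes maximal runs of kept columns shorter than ``min_block``.
    Runs are evaluated once, on the step-1 pattern only.
    """
    policy = MaskPolicy(gap_threshold=gap_threshold, min_block=min_block)
    frac = _non_gap_fraction(a)
    step1 = frac >= gap_threshold

    kept: list[int] = []
    run: list[int] = []
    for j in range(a.length + 1):
        if j < a.length and step1[j]:
            run.append(j)
        else:
            if len(run) >= min_block:
                kept.extend(run)
            run = []

    if not kept:
        warnings.warn("gap/block masking removed every column", stacklevel=2)
    return MaskedAlignment(
        alignment=a.take_columns(kept),
        kept_columns=tuple(kept),
        provenance=f"gap_block(gt={policy.gap_threshold:g},block={policy.min_block})",
    )


def score_threshold_series(
    a: Alignment, s: SiteScores, thresholds: Sequence[float]
) -> list[MaskedAlignment]:
    """For each ascending threshold t, drop columns whose score is < t.

    Outputs are ordered by t and nested: each kept set contains the next.
    """
    if len(s) != a.length:
        raise ValidationError(
            f"scores length {len(s)} != alignment length {a.length}"
        )
    thresholds = tuple(float(t) for t in thresholds)
    MaskPolicy(score_thresholds=thresholds)  # validates ascending order
    out = []
    for t in thresholds:
        kept = tuple(int(j) for j in np.flatnonzero(s.values >= t))
        out.append(
            MaskedAlignment(
                alignment=a.take_columns(kept),
                kept_columns=kept,
                provenance=f"score_threshold(t={t:g})",
            )
        )
    return out


def rate_strip_series(a: Alignment, s: SiteScores) -> list[MaskedAlignment]:
    """Stepwise removal of rate categories, fastest (highest index) first.

    Step 0 is the identity; step k (1..C-1) removes every column whose
    category is among the k largest. The series is nested with
    non-increasing lengths.
    """
    if s.categories is None:
        raise DataError("rate stripping needs per-column categories")
    if len(s) != a.length:
        raise ValidationError(
            f"scores length {len(s)} != alignment length {a.length}"
        )
    n_cat = s.n_categories
    if n_cat < 2:
        raise DataError(f"need >=2 rate categories, got {n_cat}")
    out = [
        MaskedAlignment(
            alignment=a,
            kept_columns=tuple(range(a.length)),
            provenance="rate_strip(step=0)",
        )
    ]
    for k in range(1, n_cat):
        cutoff = n_cat - k  # keep categories 1..cutoff
        kept = tuple(int(j) for j in np.flatnonzero(s.categories <= cutoff))
        out.append(
            MaskedAlignment(
                alignment=a.take_columns(kept),
                kept_columns=kept,
                provenance=f"rate_strip(step={k},kept_cats=1..{cutoff})",
            )
        )
    return out


def column_map_table(series: Sequence[MaskedAlignment], n_sites: int) -> pd.DataFrame:
    """Long-format (step, original_column, kept) table for a masking series."""
    rows = []
    for step, ma in enumerate(series):
        kept = set(ma.kept_columns)
        for j in range(n_sites):
            rows.append(
                {"step": step, "original_column": j, "kept": j in kept}
            )
    return pd.DataFrame(rows, columns=["step", "original_column", "kept"])
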