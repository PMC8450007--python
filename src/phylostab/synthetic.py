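"""Reproducible synthetic fixtures: strategy-labeled tree sets built around
planted backbone rearrangements with beta-noise supports, and alignments
with gap patterns, column scores and rate categories.

A single integer seed drives everything through named substreams, so e.g.
adding trees to one strategy never perturbs the alignment fixture.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .backbone import GroupScheme, is_group_respecting
from .bipartitions import Bipartition, extract_bipartitions
from .errors import ValidationError
from .io import (
    Alignment,
    Node,
    SiteScores,
    SupportTree,
    TaxonSet,
    TreeMeta,
    TreeSet,
    write_newick,
)

__all__ = [
    "StrategySpec",
    "SyntheticTreeSetConfig",
    "TruthRecord",
    "generate_treeset",
    "simulate_supports",
    "generate_alignment_fixture",
    "random_unrooted_tree",
    "substream",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG stream derived from (seed, stage name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# Random trees and rearrangements
# ---------------------------------------------------------------------------


def _rooted_random_tree(labels: Sequence[str], rng: np.random.Generator) -> Node:
    """Random rooted binary tree (root degree 2) used for within-group clades."""
    labels = list(labels)
    if len(labels) == 1:
        return Node(label=labels[0])
    root = Node(children=[Node(label=labels[0]), Node(label=labels[1])])
    attachable = list(root.children)
    parent = {id(c): root for c in root.children}
    for lab in labels[2:]:
        target = attachable[int(rng.integers(len(attachable)))]
        p = parent[id(target)]
        leaf = Node(label=lab)
        joint = Node(children=[target, leaf])
        p.children[p.children.index(target)] = joint
        parent[id(joint)] = p
        parent[id(target)] = joint
        parent[id(leaf)] = joint
        attachable.extend([joint, leaf])
    return root


def random_unrooted_tree(labels: Sequence[str], rng: np.random.Generator) -> SupportTree:
    """Random unrooted binary topology (root rendered with 3 children)."""
    labels = list(labels)
    if len(labels) < 4:
        raise ValidationError("need >=4 taxa for an unrooted binary tree")
    order = list(labels)
    rng.shuffle(order)
    root = Node(children=[Node(label=l) for l in order[:3]])
    attachable = list(root.children)
    parent = {id(c): root for c in root.children}
    for lab in order[3:]:
        target = attachable[int(rng.integers(len(attachable)))]
        p = parent[id(target)]
        leaf = Node(label=lab)
        joint = Node(children=[target, leaf])
        p.children[p.children.index(target)] = joint
        parent[id(joint)] = p
        parent[id(target)] = joint
        parent[id(leaf)] = joint
        attachable.extend([joint, leaf])
    return SupportTree(root)


def _grouped_random_tree(
    group_members: dict[str, list[str]], rng: np.random.Generator
) -> SupportTree:
    """Random unrooted tree in which every group is a clade."""
    groups = list(group_members)
    if len(groups) == 3:
        skeleton = SupportTree(Node(children=[Node(label=g) for g in groups]))
    else:
        skeleton = random_unrooted_tree(groups, rng)
    for node in list(skeleton.postorder()):
        if node.is_leaf():
            members = group_members[node.label]
            if len(members) == 1:
                node.label = members[0]
            else:
                sub = _rooted_random_tree(members, rng)
                node.label = None
                node.children = sub.children
    return skeleton


def _parent_map(tree: SupportTree) -> dict[int, Node]:
    parents: dict[int, Node] = {}
    for node in tree.postorder():
        for c in node.children:
            parents[id(c)] = node
    return parents


def apply_nni(tree: SupportTree, v: Node, which: int) -> None:
    """NNI on the edge above internal node ``v``: swap one of its children
    with its first sibling. ``which`` selects the child (mod arity)."""
    parents = _parent_map(tree)
    u = parents.get(id(v))
    if u is None or v.is_leaf():
        raise ValidationError("NNI target must be an internal non-root node")
    siblings = [c for c in u.children if c is not v]
    if not siblings:
        raise ValidationError("NNI target has no sibling")
    child = v.children[which % len(v.children)]
    sib = siblings[0]
    v.children[v.children.index(child)] = sib
    u.children[u.children.index(sib)] = child


def _focal_edge(tree: SupportTree, taxa: TaxonSet, scheme: GroupScheme) -> Node:
    """Deterministic focal edge: the group-respecting internal edge with the
    lowest canonical split (falling back to the lowest overall)."""
    masks: dict[int, int] = {}
    candidates: list[tuple[Bipartition, bool, Node]] = []
    for node in tree.postorder():
        if node.is_leaf():
            masks[id(node)] = 1 << taxa.position(node.label)
            continue
        m = 0
        for c in node.children:
            m |= masks[id(c)]
        masks[id(node)] = m
        if node is tree.root:
            continue
        size = m.bit_count()
        if 2 <= size <= len(taxa) - 2:
            b = Bipartition.from_mask(m, len(taxa))
            respecting, _ = is_group_respecting(b, scheme, taxa)
            candidates.append((b, respecting, node))
    if not candidates:
        raise ValidationError("tree has no internal edge for an NNI")
    respecting = [c for c in candidates if c[1]]
    pool = respecting or candidates
    return min(pool, key=lambda c: c[0])[2]


# ---------------------------------------------------------------------------
# Support simulation
# ---------------------------------------------------------------------------


def simulate_supports(
    tree: SupportTree,
    taxa: TaxonSet,
    mu_stable: float,
    mu_var: float,
    kappa: float,
    rng: np.random.Generator | int,
    stable_splits: set | None = None,
) -> SupportTree:
    """Copy of ``tree`` with beta-noise supports on every internal edge.

    An edge whose split is in ``stable_splits`` (all edges when ``None``)
    draws from a beta with mean ``mu_stable``, others from ``mu_var``;
    ``kappa`` is the concentration (alpha+beta). Supports are
    ``round(100 * draw)`` clipped to [0, 100].
    """
    if kappa <= 0:
        raise ValidationError(f"kappa must be > 0, got {kappa}")
    for mu in (mu_stable, mu_var):
        if not 0.0 <= mu <= 1.0:
            raise ValidationError(f"beta mean must be in [0, 1], got {mu}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    out = tree.copy()
    masks: dict[int, int] = {}
    for node in out.postorder():
        if node.is_leaf():
            masks[id(node)] = 1 << taxa.position(node.label)
            continue
        m = 0
        for c in node.children:
            m |= masks[id(c)]
        masks[id(node)] = m
        if node is out.root:
            continue
        size = m.bit_count()
        if not 2 <= size <= len(taxa) - 2:
            continue
        split = Bipartition.from_mask(m, len(taxa))
        mu = mu_stable if (stable_splits is None or split in stable_splits) else mu_var
        if mu <= 0.0:
            draw = 0.0
        elif mu >= 1.0:
            draw = 1.0
        else:
            draw = float(rng.beta(mu * kappa, (1.0 - mu) * kappa))
        node.support = float(np.clip(round(100.0 * draw), 0.0, 100.0))
    return out


# ---------------------------------------------------------------------------
# Tree-set generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrategySpec:
    label: str
    n_trees: int
    nni_moves: int = 0          # backbone rearrangement relative to the base
    jitter_prob: float = 0.0    # per-internal-edge probability of a random NNI
    kappa: float = 100.0        # support-noise concentration
    mu_stable: float = 0.9      # beta mean on backbone-stable edges
    mu_var: float = 0.5         # beta mean on other edges

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.nni_moves < 0:
            raise ValidationError("nni_moves must be >= 0")
        if not 0.0 <= self.jitter_prob <= 1.0:
            raise ValidationError("jitter_prob must be in [0, 1]")
        if self.kappa <= 0:
            raise ValidationError("kappa must be > 0")
        for mu in (self.mu_stable, self.mu_var):
            if not 0.0 <= mu <= 1.0:
                raise ValidationError("beta means must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticTreeSetConfig:
    n_taxa: int
    group_sizes: tuple[int, ...]
    strategies: tuple[StrategySpec, ...]
    seed: int
    branch_length_mean: float = 0.1

    def __post_init__(self):
        if self.n_taxa < 6:
            raise ValidationError("n_taxa must be >= 6")
        sizes = tuple(self.group_sizes)
        if len(sizes) < 3 or any(s < 1 for s in sizes) or sum(sizes) != self.n_taxa:
            raise ValidationError(
                f"group sizes {sizes} invalid: need >=3 positive sizes summing "
                f"to n_taxa={self.n_taxa}"
            )
        if not self.strategies:
            raise ValidationError("at least one strategy required")
        if self.seed is None:
            raise ValidationError("seed is mandatory")


@dataclass
class TruthRecord:
    """Generative ground truth for a synthetic tree set."""

    base_newick: str
    backbone_newicks: dict
    stable_splits: set
    scheme: GroupScheme


def generate_treeset(cfg: SyntheticTreeSetConfig) -> tuple[TreeSet, TruthRecord]:
    """Strategy-labeled tree clouds around (possibly rearranged) backbones."""
    taxa_labels = [f"t{i + 1:03d}" for i in range(cfg.n_taxa)]
    taxa = TaxonSet(taxa_labels)
    group_members: dict[str, list[str]] = {}
    pos = 0
    for g, size in enumerate(cfg.group_sizes):
        group_members[f"G{g + 1}"] = taxa_labels[pos: pos + size]
        pos += size
    scheme = GroupScheme.from_pairs(
        (t, g) for g, members in group_members.items() for t in members
    )

    rng_topology = substream(cfg.seed, "topology")
    base = _grouped_random_tree(group_members, rng_topology)
    base_splits = {b for b, _ in extract_bipartitions(base, taxa)}

    trees: list[SupportTree] = []
    strategies: list[str] = []
    backbones: dict[str, str] = {}
    for spec in cfg.strategies:
        backbone = base.copy()
        if spec.nni_moves:
            focal = _focal_edge(backbone, taxa, scheme)
            for j in range(spec.nni_moves):
                apply_nni(backbone, focal, which=j)
        backbones[spec.label] = write_newick(backbone, taxa)

        rng = substream(cfg.seed, f"trees:{spec.label}")
        for i in range(spec.n_trees):
            t = backbone.copy()
            if spec.jitter_prob > 0:
                for node in list(t.internal_edge_nodes()):
                    if rng.random() < spec.jitter_prob:
                        apply_nni(t, node, which=int(rng.integers(len(node.children))))
            for node in t.postorder():
                if node is not t.root:
                    node.length = float(rng.exponential(cfg.branch_length_mean))
            t = simulate_supports(
                t, taxa, spec.mu_stable, spec.mu_var, spec.kappa, rng,
                stable_splits=base_splits,
            )
            t.meta = TreeMeta(
                strategy=spec.label,
                source="synthetic",
                tree_id=f"{spec.label}_{i:02d}",
            )
            trees.append(t)
            strategies.append(spec.label)

    treeset = TreeSet(taxa, trees, strategies)
    truth = TruthRecord(
        base_newick=write_newick(base, taxa),
        backbone_newicks=backbones,
        stable_splits=base_splits,
        scheme=scheme,
    )
    return treeset, truth


# ---------------------------------------------------------------------------
# Alignment fixture
# ---------------------------------------------------------------------------


def generate_alignment_fixture(
    n_seq: int,
    n_sites: int,
    gap_profile=0.0,
    score_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    n_categories: int = 8,
    seed: int = 0,
    gamma_shape: float = 0.5,
) -> tuple[Alignment, SiteScores]:
    """Random alignment plus per-column scores and rate categories.

    Residues are uniform over ACGT; gaps are independent per cell with the
    column's gap probability; scores default to uniform on [0, 1];
    categories come from equal-frequency binning of per-column gamma rates
    (category 1 = slowest), emulating a discretized-gamma rate model.
    """
    if n_seq < 2:
        raise ValidationError("n_seq must be >= 2")
    if n_categories < 2:
        raise ValidationError("n_categories must be >= 2")
    if n_sites < n_categories:
        raise ValidationError("n_sites must be >= n_categories")

    gap_p = np.broadcast_to(np.asarray(gap_profile, dtype=float), (n_sites,))
    if ((gap_p < 0) | (gap_p > 1)).any():
        raise ValidationError("gap probabilities must be in [0, 1]")

    rng_seq = substream(seed, "alignment:residues")
    rng_gap = substream(seed, "alignment:gaps")
    rng_score = substream(seed, "alignment:scores")
    rng_rate = substream(seed, "alignment:rates")

    residues = np.array(list("ACGT"))
    mat = residues[rng_seq.integers(0, 4, size=(n_seq, n_sites))]
    gaps = rng_gap.random((n_seq, n_sites)) < gap_p[None, :]
    mat[gaps] = "-"
    seqs = tuple("".join(row) for row in mat)
    ids = tuple(f"s{i + 1:02d}" for i in range(n_seq))
    alignment = Alignment(ids, seqs)

    if score_sampler is None:
        scores = rng_score.random(n_sites)
    else:
        scores = np.asarray(score_sampler(rng_score, n_sites), dtype=float)
        if scores.shape != (n_sites,):
            raise ValidationError("score_sampler must return one value per site")

    rates = rng_rate.gamma(shape=gamma_shape, scale=1.0 / gamma_shape, size=n_sites)
    ranks = np.argsort(np.argsort(rates, kind="stable"), kind="stable")
    categories = (ranks * n_categories) // n_sites + 1

    return alignment, SiteScores(values=scores, categories=categories)
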