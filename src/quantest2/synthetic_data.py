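"""Seeded generators for benchmark test fixtures.

Real benchmark families pair a structure-based reference alignment with a
large pool of homologs.  These generators produce the same shapes of data
with known ground truth: a family evolved down a random binary tree (the
indel history *is* the true alignment), 3-state secondary-structure strings
with controllable prediction corruption, and 2-D Euclidean distance
geometries with planted reference spreads and candidate categories.

Simulation here only builds test fixtures for the toolkit's own machinery;
simulated alignments are never presented as benchmark references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .guidetree import GuideTree, TreeNode
from .io_formats import Alignment, DistanceMatrix, SequenceRecord
from .selection import (
    CATEGORY_BETWEEN,
    CATEGORY_NEAR_FAR,
    CATEGORY_NEIGHBOURHOOD,
)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_SS = "HEC"


class SimulationError(ValueError):
    """Invalid generator specification."""


def random_binary_tree(
    n_leaves: int,
    seed: int,
    labels: Optional[Sequence[str]] = None,
) -> GuideTree:
    """Uniform coalescent-style random rooted binary tree.

    Lineages are merged two at a time, each pair chosen uniformly, until one
    remains — the standard neutral-topology null for guide-trees.
    """
    if n_leaves < 2:
        raise SimulationError("need at least two leaves")
    if labels is None:
        width = len(str(n_leaves))
        labels = [f"seq{i + 1:0{width}d}" for i in range(n_leaves)]
    elif len(labels) != n_leaves:
        raise SimulationError("label count does not match n_leaves")
    rng = np.random.default_rng(seed)
    lineages: list[TreeNode] = [TreeNode(lab) for lab in labels]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        joint = TreeNode()
        joint.add(lineages[i])
        joint.add(lineages[j])
        lineages[i] = joint
        lineages.pop(j)
    return GuideTree(lineages[0], rooted=True)


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Parameters of one simulated family.

    Rates are per residue site per branch: ``substitution_rate`` is the
    probability a site mutates on a branch, ``indel_rate`` the expected
    number of indel events per site per branch (geometric lengths, mean 2).
    ``prediction_corruption`` redraws each predicted structure state
    uniformly with the given probability, so corruption 1 leaves the
    expected agreement at the 3-state chance level of 1/3.
    """

    n_sequences: int = 100
    mean_length: int = 150
    substitution_rate: float = 0.05
    indel_rate: float = 0.02
    n_structure_annotated: int = 3
    prediction_corruption: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise SimulationError("n_sequences must be at least 2")
        if self.mean_length < 1:
            raise SimulationError("mean_length must be positive")
        if self.substitution_rate < 0 or self.indel_rate < 0:
            raise SimulationError("rates must be nonnegative")
        if not 0 <= self.prediction_corruption <= 1:
            raise SimulationError("prediction_corruption must be in [0, 1]")
        if self.n_structure_annotated > self.n_sequences:
            raise SimulationError(
                "cannot annotate more sequences than the family contains"
            )
        if self.n_structure_annotated < 1:
            raise SimulationError("need at least one annotated sequence")


@dataclass(frozen=True)
class SyntheticFamily:
    """A generated family with its ground truth."""

    spec: SyntheticFamilySpec
    alignment: Alignment              # the true alignment (indel history)
    records: list[SequenceRecord]     # unaligned, in alignment row order
    tree: GuideTree
    annotated_ids: tuple[str, ...]
    ss_actual: dict[str, str]
    ss_predicted: dict[str, str]


def _evolve_branch(seq, master, rng, spec, next_token):
    """One branch: i.i.d. substitutions then Poisson indel events.

    ``seq`` is a list of (column token, residue); ``master`` the global
    column order shared by the whole family.  Inserted columns are spliced
    into ``master`` so every row stays a subsequence of it.
    """
    seq = list(seq)
    if spec.substitution_rate > 0:
        hits = rng.random(len(seq)) < spec.substitution_rate
        for pos in np.nonzero(hits)[0]:
            tok, _ = seq[pos]
            seq[pos] = (tok, _AA20[rng.integers(20)])
    n_events = rng.poisson(spec.indel_rate * len(seq))
    for _ in range(n_events):
        length = int(rng.geometric(0.5))
        if rng.random() < 0.5 and len(seq) > length:  # deletion, never to empty
            start = int(rng.integers(len(seq) - length + 1))
            del seq[start : start + length]
        else:  # insertion
            pos = int(rng.integers(len(seq) + 1))
            if pos < len(seq):
                anchor = master.index(seq[pos][0])
            else:
                anchor = master.index(seq[-1][0]) + 1
            new = []
            for off in range(length):
                tok = next_token[0]
                next_token[0] += 1
                master.insert(anchor + off, tok)
                new.append((tok, _AA20[rng.integers(20)]))
            seq[pos:pos] = new
    return seq


def _markov_ss(length: int, rng) -> str:
    """3-state chain, self-transition 0.8, others 0.1 each."""
    states = [int(rng.integers(3))]
    for _ in range(length - 1):
        if rng.random() < 0.8:
            states.append(states[-1])
        else:
            current = states[-1]
            states.append([s for s in range(3) if s != current][int(rng.integers(2))])
    return "".join(_SS[s] for s in states)


def _corrupt_ss(actual: str, rate: float, rng) -> str:
    out = list(actual)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = _SS[int(rng.integers(3))]
    return "".join(out)


def generate_family(spec: SyntheticFamilySpec) -> SyntheticFamily:
    """Simulate one family down a random binary tree.

    The root sequence is uniform over the 20 amino acids; each branch applies
    substitutions and geometric-length indels.  Because every inserted column
    is tracked in a global column order, the evolved leaves come with their
    true alignment for free, and stripping its gaps reproduces the unaligned
    sequences exactly.  Structure annotations are 3-state Markov chains over
    ungapped residues, with predicted variants corrupted at the configured
    rate.  Everything is deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    tree = random_binary_tree(spec.n_sequences, seed=int(rng.integers(2**31)))

    master: list[int] = list(range(spec.mean_length))
    next_token = [spec.mean_length]
    root_seq = [(tok, _AA20[rng.integers(20)]) for tok in master]

    leaf_seqs: dict[str, list] = {}
    stack = [(tree.root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node.is_leaf:
            leaf_seqs[node.label] = seq
            continue
        for child in node.children:
            stack.append(
                (child, _evolve_branch(seq, master, rng, spec, next_token))
            )

    order = tree.leaf_labels()
    used_tokens = set()
    for seq in leaf_seqs.values():
        used_tokens.update(tok for tok, _ in seq)
    columns = [tok for tok in master if tok in used_tokens]
    col_index = {tok: i for i, tok in enumerate(columns)}

    rows = []
    for label in order:
        row = ["-"] * len(columns)
        for tok, aa in leaf_seqs[label]:
            row[col_index[tok]] = aa
        rows.append(SequenceRecord(label, "".join(row)))
    alignment = Alignment(rows)
    records = [SequenceRecord(r.id, r.ungapped()) for r in rows]

    annotated = tuple(sorted(
        str(label)
        for label in rng.choice(order, size=spec.n_structure_annotated, replace=False)
    ))
    ss_actual: dict[str, str] = {}
    ss_predicted: dict[str, str] = {}
    for label in annotated:
        actual = _markov_ss(len(leaf_seqs[label]), rng)
        ss_actual[label] = actual
        ss_predicted[label] = _corrupt_ss(actual, spec.prediction_corruption, rng)

    return SyntheticFamily(
        spec=spec,
        alignment=alignment,
        records=records,
        tree=tree,
        annotated_ids=annotated,
        ss_actual=ss_actual,
        ss_predicted=ss_predicted,
    )


# ---------------------------------------------------------------------------
# Planted distance geometries
# ---------------------------------------------------------------------------

GEOMETRY_SPREAD = "spread-refs"
GEOMETRY_CLUMPED = "clumped-refs"


@dataclass(frozen=True)
class PlantedDistances:
    """Euclidean 2-D geometry with known reference spread and categories.

    ``planted`` names one candidate per selection category whose geometric
    role is exact by construction (the "between" candidate sits on an
    axis-aligned midpoint, so its triangle deviation is exactly 0 in
    floating point).
    """

    dm: DistanceMatrix
    reference_labels: tuple[str, ...]
    planted: dict[str, str]           # label -> category
    coordinates: np.ndarray
    geometry: str


def generate_planted_distances(
    n_points: int, geometry: str, seed: int
) -> PlantedDistances:
    """Plant k=3 references plus categorized candidates in the plane.

    ``spread-refs`` places the references on a wide triangle whose pairwise
    distances dominate any triple involving pool points (pool points live in
    a small central disc), so spread-maximizing selection must recover them.
    ``clumped-refs`` confines all references to one small disc with the pool
    spread widely around them — the failure mode the selection scheme is
    designed to avoid.
    """
    if n_points < 10:
        raise SimulationError("need at least 10 points")
    if geometry not in (GEOMETRY_SPREAD, GEOMETRY_CLUMPED):
        raise SimulationError(f"unknown geometry {geometry!r}")
    rng = np.random.default_rng(seed)

    if geometry == GEOMETRY_SPREAD:
        refs = np.array([[0.0, 0.0], [4.0, 0.0], [2.0, 7.0]])
        planted_pts = {
            "cand_neighbourhood": (np.array([0.0625, 0.0625]), CATEGORY_NEIGHBOURHOOD),
            "cand_near_far": (np.array([2.0, 6.5]), CATEGORY_NEAR_FAR),
            "cand_between": (np.array([2.0, 0.0]), CATEGORY_BETWEEN),
        }
        pool_center, pool_radius = np.array([2.0, 3.0]), 1.0
    else:
        refs = np.array([[0.0, 0.0], [0.25, 0.0], [0.125, 0.1]])
        planted_pts = {
            "cand_neighbourhood": (np.array([0.0, 0.01]), CATEGORY_NEIGHBOURHOOD),
            "cand_near_far": (np.array([0.0, 0.75]), CATEGORY_NEAR_FAR),
            "cand_between": (np.array([0.125, 0.0]), CATEGORY_BETWEEN),
        }
        pool_center, pool_radius = np.array([0.125, 0.05]), 2.0

    n_pool = n_points - len(refs) - len(planted_pts)
    theta = rng.uniform(0, 2 * math.pi, n_pool)
    radius = pool_radius * np.sqrt(rng.uniform(0.05, 1.0, n_pool))
    pool = pool_center + np.column_stack(
        (radius * np.cos(theta), radius * np.sin(theta))
    )

    labels = [f"ref{i + 1}" for i in range(len(refs))]
    points = [refs]
    planted: dict[str, str] = {}
    for name, (pt, cat) in planted_pts.items():
        labels.append(name)
        points.append(pt[None, :])
        planted[name] = cat
    width = len(str(max(n_pool, 1)))
    labels.extend(f"pool{i + 1:0{width}d}" for i in range(n_pool))
    points.append(pool)
    coords = np.vstack(points)

    diff = coords[:, None, :] - coords[None, :, :]
    values = np.sqrt((diff ** 2).sum(axis=2))
    values = np.minimum(values, values.T)  # exact symmetry
    np.fill_diagonal(values, 0.0)
    return PlantedDistances(
        dm=DistanceMatrix(labels, values),
        reference_labels=tuple(labels[: len(refs)]),
        planted=planted,
        coordinates=coords,
        geometry=geometry,
    )
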