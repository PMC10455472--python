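"""Bootstrap stability metrics: dimension alignment, item stability,
structural consistency.

Replicate solutions label their communities arbitrarily, so before counting
where items land, each replicate's dimensions are matched one-to-one to the
empirical (reference) dimensions.  The matching maximizes total Jaccard
overlap of item sets via optimal assignment, with one refinement: a
replicate dimension whose item set equals a reference dimension exactly is
pinned to it first, which guarantees that exact structural recovery always
counts toward each member's own-dimension stability.  Replicate dimensions
with no counterpart (zero overlap, or more replicate dimensions than
reference ones) are reported in overflow columns K+1, K+2, ...; overflow
item sets from different replicates share a column when they resemble each
other (Jaccard >= 0.5 with the column's first-seen prototype), mirroring
how analysts aggregate a recurring "extra" dimension across replicates.

Item stability of item i in column d is the proportion of replicates
placing i in d; an item is stable when its proportion in its own reference
dimension is >= 0.70.  Structural consistency of a reference dimension is
the proportion of replicates containing its exact item set, computed by set
equality independent of the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .communities import DimensionSolution

ITEM_STABILITY_THRESHOLD = 0.70
CONSISTENCY_THRESHOLD = 0.75


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


@dataclass(frozen=True)
class AlignedEnsemble:
    """Per-replicate mapping from replicate dimensions to report columns.

    ``mappings[b]`` maps replicate b's dimension index (1-based) to a
    column: 1..K for the reference dimensions, K+1.. for overflow columns.
    """

    reference: DimensionSolution
    solutions: tuple[DimensionSolution, ...]
    mappings: tuple[dict[int, int], ...]
    n_overflow: int

    @property
    def n_columns(self) -> int:
        return self.reference.n_dims + self.n_overflow


def align_dimensions(
    solutions,
    reference: DimensionSolution,
) -> AlignedEnsemble:
    """Match every replicate's dimensions to the reference dimensions.

    Exact set matches are pinned first; the remaining replicate dimensions
    are assigned one-to-one to remaining reference dimensions by maximum
    total Jaccard overlap; zero-overlap or surplus replicate dimensions go
    to overflow columns (created in decreasing-size order within each
    replicate, consolidated across replicates at Jaccard >= 0.5).
    """
    solutions = tuple(solutions)
    ref_sets = reference.item_sets()
    k = len(ref_sets)
    overflow_prototypes: list[frozenset] = []
    mappings: list[dict[int, int]] = []
    for sol in solutions:
        if set(sol.labels) != set(reference.labels):
            raise ValueError("replicate and reference label sets differ")
        rep_sets = sol.item_sets()
        mapping: dict[int, int] = {}
        free_ref = set(range(k))
        free_rep = set(range(len(rep_sets)))
        # pin exact recoveries
        for ri in list(free_rep):
            for di in sorted(free_ref):
                if rep_sets[ri] == ref_sets[di]:
                    mapping[ri + 1] = di + 1
                    free_ref.discard(di)
                    free_rep.discard(ri)
                    break
        # optimal assignment on the remainder
        if free_rep and free_ref:
            rows = sorted(free_rep)
            cols = sorted(free_ref)
            cost = np.zeros((len(rows), len(cols)))
            for a, ri in enumerate(rows):
                for b, di in enumerate(cols):
                    cost[a, b] = -_jaccard(rep_sets[ri], ref_sets[di])
            ri_idx, di_idx = linear_sum_assignment(cost)
            for a, b in zip(ri_idx, di_idx):
                if cost[a, b] < 0:  # zero-overlap pairs stay unmatched
                    mapping[rows[a] + 1] = cols[b] + 1
                    free_rep.discard(rows[a])
        # overflow: unmatched replicate dimensions, largest first
        for ri in sorted(free_rep, key=lambda r: (-len(rep_sets[r]), r)):
            s = rep_sets[ri]
            col = None
            best = 0.0
            for oi, proto in enumerate(overflow_prototypes):
                j = _jaccard(s, proto)
                if j >= 0.5 and j > best:
                    best, col = j, oi
            if col is None:
                overflow_prototypes.append(s)
                col = len(overflow_prototypes) - 1
            mapping[ri + 1] = k + col + 1
        mappings.append(mapping)
    return AlignedEnsemble(reference, solutions, tuple(mappings), len(overflow_prototypes))


def item_stability_matrix(aligned: AlignedEnsemble) -> pd.DataFrame:
    """Items x columns matrix of placement proportions (rows sum to 1)."""
    ref = aligned.reference
    labels = list(ref.labels)
    ncol = aligned.n_columns
    counts = np.zeros((len(labels), ncol))
    pos = {lab: i for i, lab in enumerate(labels)}
    for sol, mapping in zip(aligned.solutions, aligned.mappings):
        for lab, m in zip(sol.labels, sol.membership):
            counts[pos[lab], mapping[m] - 1] += 1.0
    props = counts / len(aligned.solutions)
    cols = [f"dim{d}" for d in range(1, ref.n_dims + 1)] + [
        f"extra{d}" for d in range(1, aligned.n_overflow + 1)
    ]
    return pd.DataFrame(props, index=labels, columns=cols)


def structural_consistency(solutions, reference: DimensionSolution) -> pd.Series:
    """Proportion of replicates exactly reproducing each reference
    dimension's item set (set equality; alignment-free)."""
    solutions = tuple(solutions)
    ref_sets = reference.item_sets()
    hits = np.zeros(len(ref_sets))
    for sol in solutions:
        rep = set(sol.item_sets())
        for d, s in enumerate(ref_sets):
            if s in rep:
                hits[d] += 1.0
    return pd.Series(
        hits / max(len(solutions), 1),
        index=[f"dim{d}" for d in range(1, len(ref_sets) + 1)],
        name="structural_consistency",
    )


@dataclass(frozen=True)
class StabilityReport:
    """Item-stability matrix, structural consistency, and flagged items."""

    item_stability: pd.DataFrame = field(repr=False)
    consistency: pd.Series = field(repr=False)
    reference: DimensionSolution
    item_threshold: float = ITEM_STABILITY_THRESHOLD
    consistency_threshold: float = CONSISTENCY_THRESHOLD

    def __post_init__(self) -> None:
        rows = self.item_stability.to_numpy().sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > 1e-12:
            raise AssertionError("item-stability rows must sum to 1 (overflow included)")
        for d, s in enumerate(self.reference.item_sets(), start=1):
            col = f"dim{d}"
            member_min = self.item_stability.loc[list(s), col].min() if s else 1.0
            if self.consistency[col] > member_min + 1e-12:
                raise AssertionError(
                    f"structural consistency of {col} exceeds a member's item stability"
                )

    @property
    def own_stability(self) -> pd.Series:
        """Each item's stability in its own reference dimension."""
        vals = {}
        for lab, d in self.reference.assignment.items():
            vals[lab] = float(self.item_stability.loc[lab, f"dim{d}"])
        return pd.Series(vals, name="own_stability")

    @property
    def unstable_items(self) -> tuple[str, ...]:
        own = self.own_stability
        return tuple(lab for lab in self.reference.labels if own[lab] < self.item_threshold)

    @property
    def unstable_dimensions(self) -> tuple[str, ...]:
        return tuple(self.consistency.index[self.consistency < self.consistency_threshold])

    def to_dict(self) -> dict:
        return {
            "item_stability": {
                lab: {c: float(v) for c, v in row.items()}
                for lab, row in self.item_stability.iterrows()
            },
            "structural_consistency": {c: float(v) for c, v in self.consistency.items()},
            "own_stability": {k: float(v) for k, v in self.own_stability.items()},
            "unstable_items": list(self.unstable_items),
            "item_threshold": self.item_threshold,
            "consistency_threshold": self.consistency_threshold,
        }


def stability_report(
    solutions,
    reference: DimensionSolution,
    item_threshold: float = ITEM_STABILITY_THRESHOLD,
    consistency_threshold: float = CONSISTENCY_THRESHOLD,
) -> StabilityReport:
    """Align replicates to the reference and assemble the full report."""
    aligned = align_dimensions(solutions, reference)
    return StabilityReport(
        item_stability=item_stability_matrix(aligned),
        consistency=structural_consistency(solutions, reference),
        reference=reference,
        item_threshold=item_threshold,
        consistency_threshold=consistency_threshold,
    )
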