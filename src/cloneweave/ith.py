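"""Trunk/branch classification, heterogeneity statistics and phylogeny.

A mutation detected in every retained region of a patient is an early
"trunk" mutation; anything else is a late "branch" mutation, subdivided
into private (exactly one region) and shared branch (more than one but not
all). The heterogeneity frequency H is the branch fraction: branch
mutations divided by all patient-specific (trunk + branch) non-silent
mutations.

The per-patient phylogeny treats regions as leaves and presence patterns as
binary characters. When patterns are pairwise compatible (laminar: any two
are nested or disjoint) the unique perfect phylogeny is returned; otherwise
a greedy maximum-parsimony tree is built by accepting patterns in order of
mutation support and attaching the incompatible remainder as homoplasies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .variants import PresenceMatrix

logger = logging.getLogger(__name__)

TRUNK = "trunk"
SHARED_BRANCH = "shared_branch"
PRIVATE_BRANCH = "private_branch"


@dataclass
class MutationEvolutionLabel:
    mutation_key: str
    label: str


@dataclass
class IthSummary:
    patient_id: str
    n_trunk: int
    n_branch: int
    heterogeneity_frequency: float
    subclonal_driver_fraction: float | None = None
    subclonal_driver_counts: tuple[int, int] | None = None  # (numerator, denominator)
    ith_high: bool | None = None


def classify_trunk_branch(matrix: PresenceMatrix) -> list[MutationEvolutionLabel]:
    """Label each mutation trunk / shared_branch / private_branch.

    Trunk = present in all retained regions; private = exactly one region;
    shared branch = several but not all. A single-region patient yields
    all-trunk labels (logged caveat: one region cannot reveal branching).
    """
    n_regions = len(matrix.regions)
    if n_regions < 1:
        raise ValueError("presence matrix has no regions")
    if matrix.present.shape[0] and not matrix.present.any(axis=1).all():
        raise ValueError("presence matrix contains an all-false row")
    if n_regions == 1:
        logger.warning(
            "single-region patient: all mutations labelled trunk; branching "
            "is unobservable from one region"
        )
    hits = matrix.present.sum(axis=1)
    labels = []
    for key, h in zip(matrix.mutations, hits):
        if h == n_regions:
            lab = TRUNK
        elif h == 1:
            lab = PRIVATE_BRANCH
        else:
            lab = SHARED_BRANCH
        labels.append(MutationEvolutionLabel(key, lab))
    return labels


def heterogeneity_frequency(labels: Sequence[MutationEvolutionLabel]) -> float:
    """Branch mutations / all patient-specific mutations.

    The denominator is every labelled (trunk + branch) mutation.
    """
    if not labels:
        raise ValueError("no labelled mutations: heterogeneity frequency undefined")
    n_branch = sum(l.label in (SHARED_BRANCH, PRIVATE_BRANCH) for l in labels)
    return n_branch / len(labels)


def subclonal_driver_fraction(
    driver_genes: Sequence[str],
    gene_status: dict[str, Sequence[str]],
) -> tuple[float, int, int]:
    """Fraction of mutated driver genes with any subclonal mutation.

    ``gene_status`` maps gene -> per-mutation-per-region clonal statuses
    (strings 'clonal'/'subclonal'/'absent'). A driver counts as subclonal
    when any of its mutations is subclonal in any region. The denominator
    is the number of driver genes mutated in this patient.

    Returns (fraction, numerator, denominator).
    """
    if not driver_genes:
        raise ValueError("driver gene list is empty")
    mutated = [g for g in driver_genes if gene_status.get(g)]
    if not mutated:
        return 0.0, 0, 0
    n_sub = sum(
        any(s == "subclonal" for s in gene_status[g]) for g in mutated
    )
    return n_sub / len(mutated), n_sub, len(mutated)


def percent_display(fraction: float) -> int:
    """Whole-percent display value with half-up rounding (0.846 -> 85)."""
    import decimal

    return int(
        (decimal.Decimal(str(fraction)) * 100).quantize(
            decimal.Decimal("1"), rounding=decimal.ROUND_HALF_UP
        )
    )


def ith_high_flag(subclonal_fraction: float, threshold: float = 0.5) -> bool:
    """Binary high-ITH flag: subclonal driver fraction >= threshold."""
    if subclonal_fraction < 0:
        raise ValueError("fraction must be >= 0")
    return subclonal_fraction >= threshold


# ---------------------------------------------------------------------------
# Region phylogeny from presence patterns
# ---------------------------------------------------------------------------


@dataclass
class PhyloNode:
    """Internal node of the region tree, defined by a region set."""

    regions: frozenset[str]
    n_mutations: int = 0  # mutations whose pattern equals this node's set
    children: list["PhyloNode"] = field(default_factory=list)

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        comment = f"[&muts={self.n_mutations}]"
        if not self.children and len(self.regions) == 1:
            return f"{next(iter(self.regions))}{comment}"
        parts = [c._newick_inner() for c in self.children]
        name = "" if len(self.regions) > 1 else next(iter(self.regions))
        return f"({','.join(parts)}){name}{comment}"

    def clades(self) -> set[frozenset[str]]:
        out = {self.regions}
        for c in self.children:
            out |= c.clades()
        return out


@dataclass
class PhylogenyResult:
    root: PhyloNode
    homoplasy_count: int  # mutations whose pattern conflicted with the tree
    pattern_counts: dict[frozenset, int]


def _compatible(p: frozenset, q: frozenset) -> bool:
    return p <= q or q <= p or not (p & q)


def build_phylogeny(matrix: PresenceMatrix) -> PhylogenyResult:
    """Region tree from mutation presence patterns.

    Pairwise-compatible pattern sets yield the unique perfect phylogeny;
    otherwise patterns are accepted greedily by mutation support and the
    rejected patterns' mutations are counted as homoplasies (attached to
    the smallest accepted superset). Trunk mutations sit on the root edge.
    """
    if len(matrix.regions) < 2:
        raise ValueError("phylogeny needs at least 2 regions")
    all_regions = frozenset(matrix.regions)
    counts: dict[frozenset, int] = {}
    for row in matrix.present:
        pattern = frozenset(r for r, p in zip(matrix.regions, row) if p)
        if pattern:
            counts[pattern] = counts.get(pattern, 0) + 1

    accepted: list[frozenset] = [all_regions]
    homoplasy = 0
    homoplasy_extra: dict[frozenset, int] = {}
    for pattern in sorted(counts, key=lambda p: (-counts[p], sorted(p))):
        if pattern == all_regions:
            continue
        if all(_compatible(pattern, q) for q in accepted):
            accepted.append(pattern)
        else:
            homoplasy += counts[pattern]
            host = min(
                (q for q in accepted if pattern <= q),
                key=len,
                default=all_regions,
            )
            homoplasy_extra[host] = homoplasy_extra.get(host, 0) + counts[pattern]

    # ensure every region appears as a leaf
    for r in matrix.regions:
        single = frozenset([r])
        if single not in accepted:
            accepted.append(single)

    nodes = {
        p: PhyloNode(
            regions=p,
            n_mutations=counts.get(p, 0) + homoplasy_extra.get(p, 0),
        )
        for p in accepted
    }
    # laminar family -> attach each node to its smallest strict superset
    for p in sorted(accepted, key=len):
        if p == all_regions:
            continue
        supersets = [q for q in accepted if p < q]
        parent = min(supersets, key=len)
        nodes[parent].children.append(nodes[p])
    for node in nodes.values():
        node.children.sort(key=lambda n: sorted(n.regions))
    return PhylogenyResult(
        root=nodes[all_regions],
        homoplasy_count=homoplasy,
        pattern_counts=counts,
    )
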