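"""Coefficients of kinship and inbreeding from pedigrees.

The coefficient of kinship between two individuals is the probability that
one allele drawn at random from each is identical by descent (IBD).  The
coefficient of consanguinity *F* of a couple — the quantity population
surveys of consanguineous marriage report — equals the kinship between the
partners, and also equals the inbreeding coefficient of their child: the
probability that the child's two alleles at a locus are IBD.

Two independent routes to the same quantity are provided: the exact
recursion on the pedigree graph (:func:`kinship`) and a gene-dropping
Monte Carlo simulation (:func:`gene_drop_kinship`).  Canonical pedigrees
for the standard consanguineous-union classes (first cousins, double first
cousins, ...) are built by :func:`build_relationship_pedigree`; the child's
inbreeding coefficient in each reproduces the textbook values exactly
(they are dyadic rationals).

Founders are assumed non-inbred and mutually unrelated, so every
coefficient is "above population average": the background kinship of the
population is fixed at zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np

__all__ = [
    "Pedigree",
    "RelationshipClass",
    "PedigreeError",
    "UnknownIndividualError",
    "CyclicPedigreeError",
    "kinship",
    "inbreeding_coefficient",
    "build_relationship_pedigree",
    "gene_drop_kinship",
    "read_ped",
    "write_ped",
]


class PedigreeError(ValueError):
    """Structural problem with a pedigree."""


class UnknownIndividualError(KeyError):
    """Identifier not present in the pedigree."""


class CyclicPedigreeError(PedigreeError):
    """An individual is its own ancestor."""


class RelationshipClass(enum.Enum):
    """Standard classes of parental consanguinity.

    The value of each member is the coefficient of consanguinity *F* of the
    union: the proportion of the child's gene pairs identical by descent,
    above the population average.  Uncle–niece unions carry the same *F* as
    double first cousins and are exposed as an alias of that class.
    """

    DOUBLE_FIRST_COUSINS = 0.125
    FIRST_COUSINS = 0.0625
    FIRST_COUSINS_ONCE_REMOVED = 0.03125
    SECOND_COUSINS = 0.015625
    NON_CONSANGUINEOUS = 0.0

    @property
    def coefficient_F(self) -> float:
        return self.value

    @property
    def percent_identical(self) -> float:
        """Percent of genes identical by descent (100 × F)."""
        return self.value * 100.0


# Uncle–niece: F identical to double first cousins (alias, not a new class).
UNCLE_NIECE = RelationshipClass.DOUBLE_FIRST_COUSINS


@dataclass(frozen=True)
class Pedigree:
    """Minimal ancestry graph.

    ``parent_map`` maps each individual to ``(father, mother)``; founders
    map to ``(None, None)``.  Each individual has exactly zero or two
    recorded parents and the graph must be acyclic.  A topological order
    (founders first) is computed at construction, which doubles as the
    acyclicity check.
    """

    parent_map: Mapping[str, tuple[Optional[str], Optional[str]]]
    _topo_rank: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pm = dict(self.parent_map)
        for ind, (f, m) in pm.items():
            if (f is None) != (m is None):
                raise PedigreeError(
                    f"individual {ind!r} has exactly one recorded parent; "
                    "founders have zero, non-founders two"
                )
            for p in (f, m):
                if p is not None and p not in pm:
                    raise UnknownIndividualError(
                        f"parent {p!r} of {ind!r} is not in the pedigree"
                    )
        object.__setattr__(self, "parent_map", pm)
        object.__setattr__(self, "_topo_rank", self._topological_rank())

    def _topological_rank(self) -> dict[str, int]:
        # Kahn's algorithm; failure to exhaust all individuals means a cycle.
        children: dict[str, list[str]] = {i: [] for i in self.parent_map}
        indegree = {i: 0 for i in self.parent_map}
        for ind, (f, m) in self.parent_map.items():
            for p in (f, m):
                if p is not None:
                    children[p].append(ind)
                    indegree[ind] += 1
        queue = sorted(i for i, d in indegree.items() if d == 0)
        rank: dict[str, int] = {}
        while queue:
            node = queue.pop(0)
            rank[node] = len(rank)
            for c in children[node]:
                indegree[c] -= 1
                if indegree[c] == 0:
                    queue.append(c)
        if len(rank) != len(self.parent_map):
            raise CyclicPedigreeError("pedigree contains a cycle")
        return rank

    @property
    def individuals(self) -> frozenset[str]:
        return frozenset(self.parent_map)

    def founders(self) -> list[str]:
        return sorted(
            i for i, (f, m) in self.parent_map.items() if f is None
        )

    def parents(self, ind: str) -> tuple[Optional[str], Optional[str]]:
        try:
            return self.parent_map[ind]
        except KeyError:
            raise UnknownIndividualError(f"unknown individual {ind!r}") from None

    def topological_order(self) -> list[str]:
        """Individuals ordered founders-first (parents precede children)."""
        return sorted(self.parent_map, key=self._topo_rank.__getitem__)


def kinship(ped: Pedigree, a: str, b: str) -> float:
    """Coefficient of kinship between ``a`` and ``b`` by the exact recursion.

    phi(x, x) = (1 + F_x) / 2 where F_x = phi(father_x, mother_x);
    phi(x, y) = (phi(father_x, y) + phi(mother_x, y)) / 2, recursing on
    whichever of the pair is further from the founders (so the other is
    never a descendant of it); founders are mutually unrelated.
    Symmetric and deterministic; memoised on unordered pairs.
    """
    for ind in (a, b):
        if ind not in ped.parent_map:
            raise UnknownIndividualError(f"unknown individual {ind!r}")
    rank = ped._topo_rank
    cache: dict[frozenset[str], float] = {}

    def phi(x: str, y: str) -> float:
        key = frozenset((x, y))
        if key in cache:
            return cache[key]
        if x == y:
            f, m = ped.parent_map[x]
            val = 0.5 if f is None else 0.5 * (1.0 + phi(f, m))
        else:
            # recurse through the individual later in topological order:
            # it cannot be an ancestor of the other.
            if rank[x] < rank[y]:
                x, y = y, x
            f, m = ped.parent_map[x]
            val = 0.0 if f is None else 0.5 * (phi(f, y) + phi(m, y))
        cache[key] = val
        return val

    return phi(a, b)


def inbreeding_coefficient(ped: Pedigree, child: str) -> float:
    """Inbreeding coefficient of ``child`` = kinship of its parents = F."""
    f, m = ped.parents(child)
    if f is None:
        raise PedigreeError(
            f"{child!r} is a founder: inbreeding coefficient requires two "
            "recorded parents"
        )
    return kinship(ped, f, m)


def gene_drop_kinship(
    ped: Pedigree, a: str, b: str, replicates: int = 1_000_000, seed: int = 0
) -> float:
    """Monte Carlo kinship by simulating allele transmission from founders.

    Each founder carries two unique allele labels; every child inherits one
    label chosen uniformly at random from each parent.  The estimate is the
    probability that one allele drawn at random from ``a`` and one from
    ``b`` (independent draws, so with replacement when ``a is b``) carry
    the same label.  Converges to :func:`kinship` as replicates grow; the
    standard error is binomial, sqrt(phi(1-phi)/replicates).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    for ind in (a, b):
        if ind not in ped.parent_map:
            raise UnknownIndividualError(f"unknown individual {ind!r}")
    rng = np.random.default_rng(seed)
    # alleles[ind] is a (2, replicates) int array of labels
    alleles: dict[str, np.ndarray] = {}
    label = 0
    for ind in ped.topological_order():
        f, m = ped.parent_map[ind]
        if f is None:
            alleles[ind] = np.broadcast_to(
                np.array([[label], [label + 1]]), (2, replicates)
            )
            label += 2
        else:
            paternal = np.where(
                rng.integers(0, 2, replicates, dtype=np.int8) == 0,
                alleles[f][0],
                alleles[f][1],
            )
            maternal = np.where(
                rng.integers(0, 2, replicates, dtype=np.int8) == 0,
                alleles[m][0],
                alleles[m][1],
            )
            alleles[ind] = np.stack([paternal, maternal])
    pick_a = rng.integers(0, 2, replicates)
    pick_b = rng.integers(0, 2, replicates)
    allele_a = alleles[a][pick_a, np.arange(replicates)]
    allele_b = alleles[b][pick_b, np.arange(replicates)]
    return float(np.mean(allele_a == allele_b))


def build_relationship_pedigree(
    rc: RelationshipClass,
) -> tuple[Pedigree, str, str, str]:
    """Canonical minimal pedigree realising a consanguineous union.

    Returns ``(pedigree, partner_1, partner_2, child)`` where the partners
    have the named relationship and ``child`` is their offspring, so that
    ``inbreeding_coefficient(ped, child) == rc.coefficient_F`` exactly.
    Founders are non-inbred and unrelated.
    """
    if rc is RelationshipClass.NON_CONSANGUINEOUS:
        raise PedigreeError(
            "non-consanguineous unions have no shared-ancestor pedigree"
        )
    F = lambda: (None, None)  # noqa: E731 - founder shorthand

    if rc is RelationshipClass.FIRST_COUSINS:
        pm = {
            "gf": F(), "gm": F(), "s1": F(), "s2": F(),
            "p1": ("gf", "gm"), "p2": ("gf", "gm"),
            "a": ("p1", "s1"), "b": ("p2", "s2"),
            "child": ("a", "b"),
        }
    elif rc is RelationshipClass.DOUBLE_FIRST_COUSINS:
        # two sibships intermarrying: a's parents are sibs of b's parents
        pm = {
            "gf1": F(), "gm1": F(), "gf2": F(), "gm2": F(),
            "p1": ("gf1", "gm1"), "p2": ("gf1", "gm1"),
            "q1": ("gf2", "gm2"), "q2": ("gf2", "gm2"),
            "a": ("p1", "q1"), "b": ("p2", "q2"),
            "child": ("a", "b"),
        }
    elif rc is RelationshipClass.FIRST_COUSINS_ONCE_REMOVED:
        pm = {
            "gf": F(), "gm": F(), "s1": F(), "s2": F(), "s3": F(),
            "p1": ("gf", "gm"), "p2": ("gf", "gm"),
            "c1": ("p1", "s1"), "b": ("p2", "s2"),
            "a": ("c1", "s3"),  # child of b's first cousin
            "child": ("a", "b"),
        }
    elif rc is RelationshipClass.SECOND_COUSINS:
        pm = {
            "gf": F(), "gm": F(), "s1": F(), "s2": F(), "s3": F(), "s4": F(),
            "p1": ("gf", "gm"), "p2": ("gf", "gm"),
            "c1": ("p1", "s1"), "c2": ("p2", "s2"),
            "a": ("c1", "s3"), "b": ("c2", "s4"),
            "child": ("a", "b"),
        }
    else:  # pragma: no cover - enum is exhaustive
        raise PedigreeError(f"unhandled relationship class {rc}")
    return Pedigree(pm), "a", "b", "child"


# -- LINKAGE/PED-style I/O ---------------------------------------------------

def read_ped(path: str | Path) -> Pedigree:
    """Read a pedigree from LINKAGE/PED-style whitespace-delimited columns.

    Accepts either ``individual father mother`` (3 columns) or the standard
    six-column layout ``family individual father mother sex phenotype``;
    sex and phenotype are ignored (unknown-sex tolerant).  ``0`` denotes a
    missing parent; an individual with one parent coded 0 and one recorded
    is rejected at :class:`Pedigree` construction.
    """
    parent_map: dict[str, tuple[Optional[str], Optional[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) >= 4:
                ind, father, mother = fields[1], fields[2], fields[3]
            elif len(fields) == 3:
                ind, father, mother = fields
            else:
                raise PedigreeError(
                    f"{path}:{lineno}: expected 3 or >=4 columns, "
                    f"got {len(fields)}"
                )
            parent_map[ind] = (
                None if father == "0" else father,
                None if mother == "0" else mother,
            )
    return Pedigree(parent_map)


def write_ped(ped: Pedigree, path: str | Path) -> None:
    """Write a pedigree in 6-column PED layout (family fixed, sex unknown)."""
    with open(path, "w") as fh:
        for ind in ped.topological_order():
            f, m = ped.parent_map[ind]
            fh.write(f"FAM1 {ind} {f or 0} {m or 0} 0 0\n")
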