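"""Pedigree representation, validation, and identity-by-descent expectations.

A :class:`Pedigree` is the backbone of every analysis stage: it carries sex,
affection status and age for each member, permits consanguinity loops
(mates sharing an ancestor), and computes kinship/inbreeding coefficients by
the standard recursive algorithm, from which expected PI-HAT values
(``2*phi``) are derived for validating genotype-based relatedness estimates.

Age-dependent effective status implements the convention used throughout the
pipeline: an unaffected relative younger than the onset-risk threshold
(default 50 years) is still at risk and therefore treated as ``unknown`` in
linkage and ``excluded`` from homozygosity mapping and exome segregation
filtering; affected members are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipResult",
    "effective_status",
    "PedigreeError",
]

SEXES = {"male", "female", "unknown"}
AFFECTIONS = {"affected", "unaffected", "unknown"}
STAGES = {"linkage", "homozygosity", "exome"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (missing parent, cycle, bad id)."""


@dataclass
class Individual:
    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"
    affection: str = "unknown"
    age_years: Optional[float] = None
    family_id: str = ""

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.id}")
        if self.affection not in AFFECTIONS:
            raise PedigreeError(f"invalid affection {self.affection!r} for {self.id}")
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"{self.id}: an individual has either both parents or neither"
            )
        if self.age_years is not None and self.age_years < 0:
            raise PedigreeError(f"{self.id}: negative age")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


@dataclass
class KinshipResult:
    pair: Tuple[str, str]
    phi: float
    inbreeding_F_i: float
    inbreeding_F_j: float

    @property
    def expected_pihat(self) -> float:
        return 2.0 * self.phi


class Pedigree:
    """A single family: members, parent-child structure, kinship.

    Founders are assumed mutually unrelated and non-inbred unless an explicit
    inbreeding coefficient is supplied via ``founder_inbreeding`` (used only
    for simulation stress tests).
    """

    def __init__(
        self,
        family_id: str,
        members: Iterable[Individual],
        founder_inbreeding: Optional[Dict[str, float]] = None,
    ) -> None:
        self.family_id = family_id
        self.members: Dict[str, Individual] = {}
        for ind in members:
            if ind.id in self.members:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            ind.family_id = family_id
            self.members[ind.id] = ind
        self.founder_inbreeding = dict(founder_inbreeding or {})
        self._phi_cache: Dict[Tuple[str, str], float] = {}
        self._validate()
        self._depth = self._compute_depths()

    # -- structure -------------------------------------------------------

    def _validate(self) -> None:
        for ind in self.members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self.members:
                    raise PedigreeError(
                        f"{ind.id}: parent {pid!r} not in family {self.family_id}"
                    )
        # acyclicity through time: DFS from each node up the parent graph
        state: Dict[str, int] = {}

        def visit(i: str) -> None:
            state[i] = 1
            ind = self.members[i]
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    continue
                s = state.get(pid)
                if s == 1:
                    raise PedigreeError(f"{pid}: individual is its own ancestor")
                if s is None:
                    visit(pid)
            state[i] = 2

        for i in self.members:
            if i not in state:
                visit(i)

    def _compute_depths(self) -> Dict[str, int]:
        depth: Dict[str, int] = {}

        def d(i: str) -> int:
            if i in depth:
                return depth[i]
            ind = self.members[i]
            if ind.is_founder:
                depth[i] = 0
            else:
                depth[i] = 1 + max(d(ind.father_id), d(ind.mother_id))
            return depth[i]

        for i in self.members:
            d(i)
        return depth

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.members

    def __getitem__(self, ind_id: str) -> Individual:
        try:
            return self.members[ind_id]
        except KeyError:
            raise PedigreeError(
                f"{ind_id!r} not in family {self.family_id}"
            ) from None

    def founders(self) -> List[Individual]:
        return [m for m in self.members.values() if m.is_founder]

    def nonfounders(self) -> List[Individual]:
        """Non-founders in topological (parents-first) order."""
        nf = [m for m in self.members.values() if not m.is_founder]
        return sorted(nf, key=lambda m: (self._depth[m.id], m.id))

    def ancestors(self, ind_id: str) -> set:
        out: set = set()
        stack = [ind_id]
        while stack:
            ind = self[stack.pop()]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in out:
                    out.add(pid)
                    stack.append(pid)
        return out

    def mate_pairs(self) -> List[Tuple[str, str]]:
        pairs = {
            tuple(sorted((m.father_id, m.mother_id)))
            for m in self.members.values()
            if not m.is_founder
        }
        return sorted(pairs)

    def consanguineous_unions(self) -> List[Tuple[str, str]]:
        """Mate pairs that share at least one ancestor (or are blood kin)."""
        out = []
        for a, b in self.mate_pairs():
            anc_a = self.ancestors(a) | {a}
            anc_b = self.ancestors(b) | {b}
            if anc_a & anc_b:
                out.append((a, b))
        return out

    # -- kinship ---------------------------------------------------------

    def _phi(self, i: str, j: str) -> float:
        key = (i, j) if i <= j else (j, i)
        cached = self._phi_cache.get(key)
        if cached is not None:
            return cached
        a, b = self[i], self[j]
        if i == j:
            val = 0.5 * (1.0 + self.inbreeding(i))
        else:
            # recurse on the deeper member; depth ordering guarantees it is
            # never an ancestor of the other
            if self._depth[i] < self._depth[j]:
                a, b = b, a
            if a.is_founder:
                val = 0.0  # two distinct founders: unrelated by assumption
            else:
                val = 0.5 * (self._phi(a.father_id, b.id) + self._phi(a.mother_id, b.id))
        self._phi_cache[key] = val
        return val

    def inbreeding(self, ind_id: str) -> float:
        ind = self[ind_id]
        if ind.is_founder:
            return float(self.founder_inbreeding.get(ind_id, 0.0))
        return self._phi(ind.father_id, ind.mother_id)

    def kinship(self, i: str, j: str) -> KinshipResult:
        """Kinship coefficient phi(i, j) with per-member inbreeding F.

        ``expected_pihat = 2*phi`` is the pedigree expectation of the
        genome-wide IBD proportion estimated by method-of-moments
        relatedness (0.5 for parent-offspring and full sibs of outbred
        parents, 0.125 for first cousins).
        """
        phi = self._phi(i, j)
        return KinshipResult(
            pair=(i, j),
            phi=phi,
            inbreeding_F_i=self.inbreeding(i),
            inbreeding_F_j=self.inbreeding(j),
        )


def effective_status(
    individual: Individual,
    age_threshold: float = 50.0,
    stage: str = "linkage",
) -> str:
    """Stage-specific analysis status for one family member.

    Affected members are always ``affected``.  Unaffected members younger
    than ``age_threshold`` (or with unknown age, conservatively) are still
    at risk of later onset: ``unknown`` for linkage, ``excluded`` for
    homozygosity mapping and exome segregation filtering.  Unaffected
    members at or above the threshold count as true unaffecteds.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(STAGES)}")
    if individual.affection == "affected":
        return "affected"
    young_label = "unknown" if stage == "linkage" else "excluded"
    if individual.affection == "unknown":
        return young_label
    # unaffected: age decides
    if individual.age_years is None or individual.age_years < age_threshold:
        return young_label
    return "unaffected"
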