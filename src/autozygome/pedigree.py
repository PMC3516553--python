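"""Pedigree structures and the consanguineous index-family fixture.

A pedigree is a directed acyclic graph of individuals; founders have no
parents and every non-founder has exactly two parents present in the
pedigree. The bundled family fixture mirrors the structure needed for
recessive mapping in a first-cousin marriage family: two affected siblings
(V1, V2) and their affected first cousin (V3), four unaffected carrier
parents (IV1-IV4), with both parental couples descending from one shared
founder couple so that a single founder haplotype can reach all three
affecteds in homozygous state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class PedMember:
    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "U"  # "M", "F" or "U"
    affected: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """Validated collection of :class:`PedMember` records.

    Raises :class:`PedigreeError` if a member references an absent parent,
    has only one parent, or is its own ancestor.
    """

    members: list[PedMember]
    family_id: str = "FAM1"
    _by_id: dict[str, PedMember] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            raise PedigreeError("duplicate individual ids")
        self._by_id = {m.id: m for m in self.members}
        for m in self.members:
            if (m.father_id is None) != (m.mother_id is None):
                raise PedigreeError(f"{m.id}: must have two parents or none")
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in self._by_id:
                    raise PedigreeError(f"{m.id}: parent {pid!r} not in pedigree")
        self.topological_order()  # raises on cycles

    def __contains__(self, individual: str) -> bool:
        return individual in self._by_id

    def __getitem__(self, individual: str) -> PedMember:
        return self._by_id[individual]

    @property
    def founders(self) -> list[PedMember]:
        return [m for m in self.members if m.is_founder]

    @property
    def affecteds(self) -> list[PedMember]:
        return [m for m in self.members if m.affected]

    def parents_of(self, individual: str) -> tuple[str, str] | None:
        m = self._by_id[individual]
        if m.is_founder:
            return None
        return m.father_id, m.mother_id  # type: ignore[return-value]

    def topological_order(self) -> list[PedMember]:
        """Members ordered parents-before-children; raises on cycles."""
        order: list[PedMember] = []
        state: dict[str, int] = {}  # 0 in progress, 1 done

        def visit(mid: str, stack: tuple[str, ...]) -> None:
            if state.get(mid) == 1:
                return
            if mid in stack:
                raise PedigreeError(f"{mid} is its own ancestor")
            m = self._by_id[mid]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(pid, stack + (mid,))
            state[mid] = 1
            order.append(m)

        for m in self.members:
            visit(m.id, ())
        return order

    def ancestors_of(self, individual: str) -> set[str]:
        out: set[str] = set()
        todo = [individual]
        while todo:
            m = self._by_id[todo.pop()]
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in out:
                    out.add(pid)
                    todo.append(pid)
        return out

    def lineage_path(self, ancestor: str, descendant: str) -> list[str] | None:
        """A parent-to-child chain ``[ancestor, ..., descendant]``, or None."""
        if ancestor == descendant:
            return [ancestor]
        m = self._by_id[descendant]
        for pid in (m.father_id, m.mother_id):
            if pid is None:
                continue
            sub = self.lineage_path(ancestor, pid)
            if sub is not None:
                return sub + [descendant]
        return None


def build_pedigree(members: Iterable[PedMember | tuple], family_id: str = "FAM1") -> Pedigree:
    """Generic builder from :class:`PedMember` objects or plain tuples."""
    built = [m if isinstance(m, PedMember) else PedMember(*m) for m in members]
    return Pedigree(built, family_id=family_id)


def build_family_pedigree() -> Pedigree:
    """The index-family fixture: three affecteds in a consanguineous family.

    IV1 and IV3 are brothers (sons of C1 x S1); their wives IV2 and IV4 each
    descend from the shared founder couple F1 x F2, so V1/V2 (siblings) and
    V3 (their first cousin) are all offspring of first-cousin marriages and
    a single F1 haplotype can be transmitted homozygously to all three.
    The exact arrangement of the real family's consanguinity loops is not
    fully known; this is the minimal structure consistent with the reported
    sibship and first-cousin relations.
    """
    members = [
        PedMember("F1", sex="M"),
        PedMember("F2", sex="F"),
        PedMember("S1", sex="F"),
        PedMember("S2", sex="M"),
        PedMember("S3", sex="M"),
        PedMember("C1", "F1", "F2", "M"),
        PedMember("C2", "F1", "F2", "F"),
        PedMember("C3", "F1", "F2", "F"),
        PedMember("IV1", "C1", "S1", "M"),
        PedMember("IV3", "C1", "S1", "M"),
        PedMember("IV2", "S2", "C2", "F"),
        PedMember("IV4", "S3", "C3", "F"),
        PedMember("V1", "IV1", "IV2", "F", affected=True),
        PedMember("V2", "IV1", "IV2", "F", affected=True),
        PedMember("V3", "IV3", "IV4", "M", affected=True),
    ]
    return Pedigree(members)


#: The four unaffected parents of the affecteds in the family fixture.
FAMILY_PARENTS = ("IV1", "IV2", "IV3", "IV4")
#: The three affected individuals in the family fixture.
FAMILY_AFFECTEDS = ("V1", "V2", "V3")
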