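"""Pedigree representation and segregation-relevant derived quantities.

The family is modelled as a directed acyclic graph of :class:`Individual`
records. Two derived quantities feed the linkage stage:

* *obligate carriers* — ungenotyped individuals whose carrier status is forced
  by Mendelian logic from their relatives (e.g. a deceased founder with carrier
  children by a non-carrier spouse);
* *informative meioses* — parent-to-child transmissions in which the
  segregation of a rare dominant variant with the phenotype can be scored.

The on-disk dialect is the classic 6-column PED file (family, id, father,
mother, sex, phenotype) with ``0`` for a missing parent and phenotype coded
``2``/``1``/``0``-or-``-9`` for affected/unaffected/unknown. Vital status and
generation, which PED cannot carry, live in an optional sidecar TSV with
columns ``id``, ``generation``, ``alive``, ``genotyped``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import InconsistencyError, PedParseError, DataError, ValidationError


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    Founders have both parent ids ``None``; non-founders have both parent ids
    set and present in the pedigree (enforced by :class:`Pedigree`).
    """

    id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex
    affected: Affection
    alive: bool = True
    genotyped: bool = True
    generation: int | None = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class MeiosisSet:
    """Phase-known informative meioses as (parent_id, child_id) pairs."""

    meioses: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_informative(self) -> int:
        return len(self.meioses)


class Pedigree:
    """A validated family graph.

    Validation enforces: unique ids; parent links resolve and are acyclic;
    a parent referenced as father is male and as mother female (when sex is
    known); either both parents are present or neither; at least one founder.
    """

    def __init__(self, individuals: Iterable[Individual], name: str = "family"):
        self.name = name
        self.individuals: list[Individual] = list(individuals)
        self._index: dict[str, Individual] = {}
        self._children: dict[str, list[str]] = {}
        self._validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    def get(self, individual_id: str) -> Individual:
        return self._index[individual_id]

    # -- derived views ------------------------------------------------------
    def founders(self) -> list[Individual]:
        return [i for i in self.individuals if i.is_founder]

    def children_of(self, individual_id: str) -> list[Individual]:
        return [self._index[c] for c in self._children.get(individual_id, [])]

    def genotyped_ids(self) -> list[str]:
        return [i.id for i in self.individuals if i.genotyped]

    def affected_ids(self) -> list[str]:
        return [i.id for i in self.individuals if i.affected is Affection.AFFECTED]

    def co_parent(self, parent_id: str, child_id: str) -> str | None:
        child = self._index[child_id]
        if child.father_id == parent_id:
            return child.mother_id
        if child.mother_id == parent_id:
            return child.father_id
        raise ValidationError(f"{parent_id} is not a parent of {child_id}")

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        seen: set[str] = set()
        for ind in self.individuals:
            if ind.id in seen:
                raise DataError(f"duplicate individual id {ind.id!r}")
            seen.add(ind.id)
            self._index[ind.id] = ind
        for ind in self.individuals:
            if (ind.father_id is None) != (ind.mother_id is None):
                raise DataError(
                    f"{ind.id}: exactly one parent given; pedigree members must "
                    "have both parents or neither"
                )
            for pid, expected_sex in ((ind.father_id, Sex.MALE), (ind.mother_id, Sex.FEMALE)):
                if pid is None:
                    continue
                if pid not in self._index:
                    raise DataError(f"{ind.id}: unknown parent id {pid!r}")
                parent = self._index[pid]
                if parent.sex is not Sex.UNKNOWN and parent.sex is not expected_sex:
                    raise DataError(
                        f"{ind.id}: parent {pid} has sex {parent.sex.value}, "
                        f"expected {expected_sex.value}"
                    )
                self._children.setdefault(pid, []).append(ind.id)
        if not any(i.is_founder for i in self.individuals):
            raise DataError("pedigree has no founder")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {i.id: WHITE for i in self.individuals}

        def visit(start: str) -> None:
            stack = [(start, iter(self._parents(start)))]
            colour[start] = GREY
            while stack:
                node, parents = stack[-1]
                for p in parents:
                    if colour[p] == GREY:
                        raise DataError(f"pedigree contains a cycle through {p}")
                    if colour[p] == WHITE:
                        colour[p] = GREY
                        stack.append((p, iter(self._parents(p))))
                        break
                else:
                    colour[node] = BLACK
                    stack.pop()

        for ind in self.individuals:
            if colour[ind.id] == WHITE:
                visit(ind.id)

    def _parents(self, individual_id: str) -> list[str]:
        ind = self._index[individual_id]
        return [p for p in (ind.father_id, ind.mother_id) if p is not None]


# ---------------------------------------------------------------------------
# PED I/O
# ---------------------------------------------------------------------------

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_AFF_CODES = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED,
              "0": Affection.UNKNOWN, "-9": Affection.UNKNOWN}


def read_ped(path: str | Path, meta: str | Path | None = None) -> Pedigree:
    """Read a 6-column whitespace-delimited PED file.

    Lines starting with ``#`` are comments. ``meta``, if given, is a sidecar
    TSV (columns ``id``, optional ``generation``, ``alive``, ``genotyped``)
    carrying what PED cannot express; individuals absent from the sidecar
    default to alive and genotyped.
    """
    path = Path(path)
    meta_map: dict[str, dict] = {}
    if meta is not None:
        mdf = pd.read_csv(meta, sep="\t", dtype={"id": str})
        meta_map = {row["id"]: row for _, row in mdf.iterrows()}

    individuals: list[Individual] = []
    family_name = "family"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedParseError(
                    f"expected >=6 whitespace-delimited columns, got {len(fields)}",
                    line=lineno,
                )
            fam, iid, father, mother, sex, pheno = fields[:6]
            family_name = fam
            if pheno not in _AFF_CODES:
                raise PedParseError(f"unknown phenotype code {pheno!r}", line=lineno)
            m = meta_map.get(iid, {})
            individuals.append(
                Individual(
                    id=iid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
                    affected=_AFF_CODES[pheno],
                    alive=bool(int(m.get("alive", 1))),
                    genotyped=bool(int(m.get("genotyped", 1))),
                    generation=(int(m["generation"])
                                if m.get("generation") not in (None, "")
                                and not pd.isna(m.get("generation")) else None),
                )
            )
    return Pedigree(individuals, name=family_name)


def write_ped(ped: Pedigree, path: str | Path) -> None:
    """Write the canonical 6-column dialect (inverse of :func:`read_ped`)."""
    sex_out = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_out = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1", Affection.UNKNOWN: "0"}
    with open(path, "w") as fh:
        for ind in ped:
            fh.write(
                f"{ped.name} {ind.id} {ind.father_id or 0} {ind.mother_id or 0} "
                f"{sex_out[ind.sex]} {aff_out[ind.affected]}\n"
            )


def load_family_fixture() -> Pedigree:
    """The packaged 25-member four-generation family reconstruction."""
    data = importlib.resources.files("famseg") / "data"
    with importlib.resources.as_file(data / "family_hgf.ped") as ped_path, \
            importlib.resources.as_file(data / "family_hgf_meta.tsv") as meta_path:
        return read_ped(ped_path, meta=meta_path)


#: Default 10-sample exome subset used in the worked examples: the proband
#: (IV-2) plus nine relatives spanning generations II-IV, mixing affected and
#: unaffected members. One plausible choice; the published drawing marks the
#: sequenced members only graphically.
WES_SAMPLE_IDS = (
    "II-1", "II-2", "II-3", "III-1", "III-2",
    "III-6", "IV-1", "IV-2", "IV-3", "IV-4",
)


# ---------------------------------------------------------------------------
# Carrier inference and meiosis counting
# ---------------------------------------------------------------------------

def obligate_carriers(
    ped: Pedigree,
    carriers: Mapping[str, bool],
    use_affection_proxy: bool = True,
) -> set[str]:
    """Infer carrier status of ungenotyped individuals by Mendelian forcing.

    ``carriers`` maps genotyped individual ids to carrier status (True if the
    individual bears >=1 copy of the variant). The inference iterates to a
    fixed point with two forcing rules for a rare dominant variant:

    * a carrier child with one known non-carrier parent forces the other
      parent to be a carrier;
    * a child of two known non-carriers is forced non-carrier.

    Under full penetrance (``use_affection_proxy``), affection status of
    ungenotyped individuals seeds the inference (affected => carrier,
    unaffected => non-carrier) — needed for deceased founder couples where
    neither member is genotyped.

    Returns the set of ungenotyped individuals inferred to be carriers.
    Raises :class:`InconsistencyError` on contradiction.
    """
    status: dict[str, bool] = {}
    for iid, val in carriers.items():
        if iid not in ped:
            raise ValidationError(f"carrier status given for unknown individual {iid!r}")
        status[iid] = bool(val)
    if use_affection_proxy:
        for ind in ped:
            if ind.id in status or ind.genotyped:
                continue
            if ind.affected is Affection.AFFECTED:
                status[ind.id] = True
            elif ind.affected is Affection.UNAFFECTED:
                status[ind.id] = False

    def force(iid: str, value: bool) -> bool:
        if iid in status:
            if status[iid] != value:
                raise InconsistencyError(
                    f"{iid} forced to be both carrier and non-carrier"
                )
            return False
        status[iid] = value
        return True

    changed = True
    while changed:
        changed = False
        for child in ped:
            if child.is_founder:
                continue
            c_stat = status.get(child.id)
            f, m = child.father_id, child.mother_id
            f_stat, m_stat = status.get(f), status.get(m)
            if c_stat is True:
                # exactly one parent must carry a rare dominant variant
                if f_stat is False and m_stat is None:
                    changed |= force(m, True)
                elif m_stat is False and f_stat is None:
                    changed |= force(f, True)
                elif f_stat is False and m_stat is False:
                    raise InconsistencyError(
                        f"carrier {child.id} has two non-carrier parents"
                    )
            if f_stat is False and m_stat is False and c_stat is None:
                changed |= force(child.id, False)

    return {
        iid for iid, val in status.items()
        if val and not ped.get(iid).genotyped and not carriers.get(iid, False)
    }


def informative_meioses(ped: Pedigree, carriers: Mapping[str, bool]) -> MeiosisSet:
    """Collect phase-known informative meioses.

    ``carriers`` must cover genotyped individuals and already include resolved
    obligate carriers (see :func:`obligate_carriers`). One meiosis is scored
    per genotyped child with a known call whose parents have known status and
    exactly one of them is a carrier; children of two carriers (phase
    unresolvable) or of two non-carriers (no transmission to observe)
    contribute none.
    """
    out = MeiosisSet()
    for child in ped:
        if child.is_founder or not child.genotyped:
            continue
        if child.id not in carriers:
            continue  # e.g. missing genotype call at this site
        f_stat = carriers.get(child.father_id)
        m_stat = carriers.get(child.mother_id)
        if f_stat is None or m_stat is None:
            continue
        if f_stat and not m_stat:
            out.meioses.append((child.father_id, child.id))
        elif m_stat and not f_stat:
            out.meioses.append((child.mother_id, child.id))
    return out
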