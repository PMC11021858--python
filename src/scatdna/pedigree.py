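"""Mendelian parentage screening and pedigree inbreeding.

Parent-offspring pairs are screened by opposing homozygosity (loci where the
two genotypes are homozygous for different alleles — impossible under
Mendelian transmission absent genotyping error), and candidate parent pairs
by trio incompatibility (loci where the offspring genotype cannot be built
from one allele of each parent). Candidate parents are restricted by the
detection timeline: an individual is eligible in year y if detected in any
year up to y and not recorded dead before y. Inbreeding coefficients are
Wright's F computed from the pedigree by the kinship recursion
(F of an individual equals the kinship of its parents), which is equivalent
to path counting on arbitrary acyclic pedigrees.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import RunConfig
from .genotyping import HET, HOM1, HOM2, MISSING

_CALLED = {HOM1, HET, HOM2}
_HOM = {HOM1, HOM2}

Genotype = Mapping[str, str]  # locus -> hom1|het|hom2|missing


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual in a pedigree with parents, timing and fate."""

    individual_id: str
    sex: str  # M | F | unknown
    dam_id: str | None = None
    sire_id: str | None = None
    birth_year: int | None = None
    fate: str = "unknown"  # harvested | natural_death | alive | unknown
    death_year: int | None = None


@dataclass(frozen=True)
class ParentScreenResult:
    """Outcome of screening one candidate (or pair) against an offspring."""

    candidate: str
    offspring: str
    n_compared: int
    oh_count: int
    trio_count: int | None = None
    verdict: str = "consistent"  # consistent | excluded


class Pedigree:
    """An acyclic pedigree with lookup, validation and F computation."""

    def __init__(self, records: Iterable[PedigreeRecord]):
        self.records: dict[str, PedigreeRecord] = {}
        for r in records:
            if r.individual_id in self.records:
                raise ValueError(f"duplicate individual {r.individual_id}")
            self.records[r.individual_id] = r
        for r in self.records.values():
            for pid, want_sex, role in ((r.dam_id, "F", "dam"), (r.sire_id, "M", "sire")):
                if pid is None:
                    continue
                parent = self.records.get(pid)
                if parent is not None and parent.sex not in (want_sex, "unknown"):
                    raise ValueError(
                        f"{role} {pid} of {r.individual_id} has sex {parent.sex}"
                    )
        self._check_acyclic()
        self._kinship_cache: dict[frozenset[str] | str, float] = {}

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 2:
                return
            if state.get(iid) == 1:
                raise ValueError(f"pedigree cycle involving {iid}: {stack}")
            state[iid] = 1
            rec = self.records.get(iid)
            if rec is not None:
                for pid in (rec.dam_id, rec.sire_id):
                    if pid is not None:
                        visit(pid, stack + [iid])
            state[iid] = 2

        for iid in self.records:
            visit(iid, [])

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        rec = self.records.get(iid)
        if rec is None:
            return None, None
        return rec.dam_id, rec.sire_id

    def kinship(self, a: str, b: str) -> float:
        """Malecot kinship coefficient between two individuals."""
        if a == b:
            key: frozenset[str] | str = a
            if key in self._kinship_cache:
                return self._kinship_cache[key]
            dam, sire = self.parents(a)
            phi = 0.0 if dam is None or sire is None else self.kinship(dam, sire)
            value = 0.5 * (1.0 + phi)
            self._kinship_cache[key] = value
            return value
        key = frozenset((a, b))
        if key in self._kinship_cache:
            return self._kinship_cache[key]
        # recurse on the individual whose parents do not include the other,
        # choosing the one further from founder status to guarantee progress
        if self._is_ancestor(a, b):
            younger, older = b, a
        else:
            younger, older = a, b
        dam, sire = self.parents(younger)
        if dam is None and sire is None:
            dam, sire = self.parents(older)
            younger, older = older, younger
        if dam is None and sire is None:
            value = 0.0
        else:
            terms = [self.kinship(p, older) for p in (dam, sire) if p is not None]
            value = sum(terms) / 2.0
        self._kinship_cache[key] = value
        return value

    def _is_ancestor(self, a: str, b: str) -> bool:
        """True iff a is an ancestor of b."""
        stack = [b]
        seen = set()
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            for pid in self.parents(cur):
                if pid == a:
                    return True
                if pid is not None:
                    stack.append(pid)
        return False

    def inbreeding(self, iid: str) -> float:
        """Wright's inbreeding coefficient F = kinship(dam, sire)."""
        dam, sire = self.parents(iid)
        if dam is None or sire is None:
            return 0.0
        return self.kinship(dam, sire)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "individual_id": r.individual_id, "sex": r.sex,
                "dam_id": r.dam_id or "", "sire_id": r.sire_id or "",
                "birth_year": r.birth_year if r.birth_year is not None else "",
                "fate": r.fate,
                "death_year": r.death_year if r.death_year is not None else "",
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows, columns=[
            "individual_id", "sex", "dam_id", "sire_id", "birth_year",
            "fate", "death_year",
        ])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Pedigree":
        df = pd.read_csv(path, dtype=str).fillna("")
        records = []
        for _, r in df.iterrows():
            records.append(PedigreeRecord(
                individual_id=r["individual_id"],
                sex=r["sex"],
                dam_id=r["dam_id"] or None,
                sire_id=r["sire_id"] or None,
                birth_year=int(float(r["birth_year"])) if r["birth_year"] else None,
                fate=r.get("fate", "unknown") or "unknown",
                death_year=int(float(r["death_year"])) if r.get("death_year") else None,
            ))
        return cls(records)


def pedigree_f(pedigree: Pedigree, individual_id: str) -> float:
    """Pedigree inbreeding coefficient of one individual (0 for founders)."""
    return pedigree.inbreeding(individual_id)


# -- genotype-based screening -------------------------------------------------

def opposing_homozygosity(g1: Genotype, g2: Genotype) -> tuple[int, int]:
    """Count loci where both genotypes are homozygous for different alleles.

    Returns (oh_count, n_compared) over co-called loci only. True
    parent-offspring pairs have zero opposing homozygosity absent error.
    """
    shared = [loc for loc, c in g1.items() if c in _CALLED
              and g2.get(loc, MISSING) in _CALLED]
    if not shared:
        raise ValueError("no co-called loci between the two genotypes")
    oh = sum(
        1 for loc in shared
        if g1[loc] in _HOM and g2[loc] in _HOM and g1[loc] != g2[loc]
    )
    return oh, len(shared)


def trio_incompatibility(
    offspring: Genotype, dam: Genotype, sire: Genotype
) -> tuple[int, int]:
    """Count loci where the offspring cannot receive one allele from each parent.

    Returns (incompatible_count, n_compared) over loci called in all three
    genotypes.
    """
    shared = [
        loc for loc, c in offspring.items()
        if c in _CALLED and dam.get(loc, MISSING) in _CALLED
        and sire.get(loc, MISSING) in _CALLED
    ]
    if not shared:
        raise ValueError("no jointly called loci for the trio")

    def alleles(call: str) -> set[int]:
        return {HOM1: {1}, HOM2: {0}, HET: {0, 1}}[call]

    count = 0
    for loc in shared:
        child = offspring[loc]
        d, s = alleles(dam[loc]), alleles(sire[loc])
        reachable = {frozenset((a, b)) if a != b else frozenset((a,))
                     for a in d for b in s}
        child_set = {HOM1: frozenset((1,)), HOM2: frozenset((0,)),
                     HET: frozenset((0, 1))}[child]
        if child_set not in reachable:
            count += 1
    return count, len(shared)


@dataclass(frozen=True)
class ParentAssignment:
    """Result of candidate parent-pair search for one offspring."""

    offspring: str
    dam: str | None
    sire: str | None
    trio_count: int | None
    oh_sum: int | None
    status: str  # assigned | ambiguous | none
    reason: str = ""


def candidate_parents(
    offspring_birth_year: int,
    roster: Mapping[str, tuple[str, frozenset[int]]],
    deaths: Mapping[str, int] | None = None,
) -> tuple[list[str], list[str]]:
    """Split candidates into (dams, sires) alive and detected by the birth year.

    ``roster`` maps individual -> (sex, years_detected); ``deaths`` maps
    individual -> death year. An individual is eligible in year y if first
    detected in any year <= y and not recorded dead before y.
    """
    deaths = deaths or {}
    dams, sires = [], []
    for iid, (sex, years) in roster.items():
        if not years or min(years) > offspring_birth_year:
            continue
        death = deaths.get(iid)
        if death is not None and death < offspring_birth_year:
            continue
        if sex == "F":
            dams.append(iid)
        elif sex == "M":
            sires.append(iid)
    return sorted(dams), sorted(sires)


def assign_parents(
    offspring_id: str,
    offspring_genotype: Genotype,
    dams: Mapping[str, Genotype],
    sires: Mapping[str, Genotype],
    config: RunConfig | None = None,
    excluded_pairs: set[tuple[str, str]] | None = None,
) -> ParentAssignment:
    """Pick the best Mendelian-consistent parent pair for one offspring.

    Pairs failing the opposing-homozygosity tolerance (either parent) or the
    trio tolerance are excluded, as is any (dam, sire) pair listed in
    ``excluded_pairs`` (e.g. incestuous pairings ruled out by an already
    reconstructed pedigree); among survivors the pair minimising
    (trio_count, total OH) wins. A tie on that key is reported as ambiguous
    rather than a forced assignment.
    """
    config = config or RunConfig()
    excluded_pairs = excluded_pairs or set()
    if not dams or not sires:
        return ParentAssignment(offspring_id, None, None, None, None,
                                "none", "no candidates in window")
    scored = []
    for (dam_id, dam_g), (sire_id, sire_g) in itertools.product(
        sorted(dams.items()), sorted(sires.items())
    ):
        if dam_id == sire_id or (dam_id, sire_id) in excluded_pairs:
            continue
        oh_d, _ = opposing_homozygosity(dam_g, offspring_genotype)
        oh_s, _ = opposing_homozygosity(sire_g, offspring_genotype)
        if oh_d > config.max_oh or oh_s > config.max_oh:
            continue
        trio, _ = trio_incompatibility(offspring_genotype, dam_g, sire_g)
        if trio > config.max_trio:
            continue
        scored.append(((trio, oh_d + oh_s), dam_id, sire_id))
    if not scored:
        return ParentAssignment(offspring_id, None, None, None, None,
                                "none", "all candidate pairs excluded")
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    best_key = scored[0][0]
    best = [s for s in scored if s[0] == best_key]
    if len(best) > 1:
        return ParentAssignment(offspring_id, None, None, best_key[0], best_key[1],
                                "ambiguous", f"{len(best)} pairs tie")
    _, dam_id, sire_id = best[0]
    return ParentAssignment(offspring_id, dam_id, sire_id,
                            best_key[0], best_key[1], "assigned")


def reconstruct_pedigree(
    genotypes: Mapping[str, Genotype],
    sexes: Mapping[str, str],
    birth_years: Mapping[str, int],
    years_detected: Mapping[str, frozenset[int]] | None = None,
    deaths: Mapping[str, int] | None = None,
    min_parent_age: int = 2,
    config: RunConfig | None = None,
) -> dict[str, ParentAssignment]:
    """Sequential exclusion-based pedigree reconstruction.

    Offspring are processed in increasing birth year. For each, candidates
    are restricted by the detection timeline (detected by the birth year,
    not dead before it) and adult status (at least ``min_parent_age`` years
    older). Candidate pairs that the partially reconstructed pedigree marks
    as first-degree kin of each other — a dam who is the sire's daughter or
    mother or full sibling — are ruled out as incestuous pairings, which
    wild wolf packs avoid; this is what lets a pup's full sister be told
    apart from its mother, whom pure exclusion statistics cannot separate.
    """
    config = config or RunConfig()
    deaths = deaths or {}
    years_detected = years_detected or {
        iid: frozenset({birth_years[iid]}) for iid in genotypes if iid in birth_years
    }
    links: dict[str, tuple[str | None, str | None]] = {}

    def first_degree(a: str, b: str) -> bool:
        pa, pb = links.get(a, (None, None)), links.get(b, (None, None))
        if a in pb or b in pa:
            return True
        return pa != (None, None) and pa == pb

    results: dict[str, ParentAssignment] = {}
    order = sorted(birth_years, key=lambda i: (birth_years[i], i))
    for iid in order:
        if iid not in genotypes:
            continue
        by = birth_years[iid]
        roster = {
            o: (sexes.get(o, "unknown"), years_detected.get(o, frozenset()))
            for o in genotypes if o != iid
            and by - birth_years.get(o, by) >= min_parent_age
        }
        dams, sires = candidate_parents(by, roster, deaths)
        excluded = {
            (d, s) for d in dams for s in sires if first_degree(d, s)
        }
        res = assign_parents(
            iid, genotypes[iid],
            {d: genotypes[d] for d in dams},
            {s: genotypes[s] for s in sires},
            config, excluded_pairs=excluded,
        )
        results[iid] = res
        if res.status == "assigned":
            links[iid] = (res.dam, res.sire)
    return results


def screen_all_pairs(
    genotypes: Mapping[str, Genotype], config: RunConfig | None = None
) -> pd.DataFrame:
    """Opposing-homozygosity screen over every ordered (candidate, offspring) pair."""
    config = config or RunConfig()
    rows = []
    for a, b in itertools.combinations(sorted(genotypes), 2):
        oh, n = opposing_homozygosity(genotypes[a], genotypes[b])
        rows.append({
            "candidate": a, "offspring": b, "oh_count": oh, "n_compared": n,
            "verdict": "excluded" if oh > config.max_oh else "consistent",
        })
    return pd.DataFrame(rows, columns=["candidate", "offspring", "oh_count",
                                       "n_compared", "verdict"])
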