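"""Replicated amplicon SNP genotyping and individual identification.

Genotypes are called per PCR replicate from allele read counts, then
combined across the three replicates with the noninvasive-genetics consensus
rule: a heterozygote must be seen in at least two of three replicates, a
homozygote in all three. Samples missing more than 20% of autosomal loci are
discarded. Sex comes from a Y-chromosome marker, species from three
diagnostic loci with wolf- versus coyote-specific alleles. QC-passed
genotypes are clustered into individuals by a mismatch-bounded matching
graph, and the panel's discriminatory power is summarised by the probability
of identity (PID) and its full-sibling variant (PIDsibs).

The module also provides generic SNP-matrix filters (locus missingness,
minor allele frequency, an exact Hardy-Weinberg test, greedy r^2 linkage
pruning, sample missingness) mirroring the standard PLINK workflow.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import RunConfig

HOM1, HET, HOM2, NOCALL, MISSING = "hom1", "het", "hom2", "nocall", "missing"

# genotype coding used in matrices: copies of allele 1 (A1)
_CODE = {HOM1: 2.0, HET: 1.0, HOM2: 0.0}
_DECODE = {2.0: HOM1, 1.0: HET, 0.0: HOM2}


@dataclass(frozen=True)
class LocusDef:
    """One locus of the amplicon panel."""

    locus_id: str
    locus_type: str  # autosomal_snp | species_diagnostic | y_marker
    allele1: str = "A"
    allele2: str = "B"
    # for species_diagnostic loci: which allele is fixed in which species
    diagnostic_alleles: Mapping[str, str] | None = None


@dataclass(frozen=True)
class Panel:
    """The SNP panel: autosomal SNPs, species diagnostics, one Y marker."""

    loci: tuple[LocusDef, ...]

    def __post_init__(self) -> None:
        y = [l for l in self.loci if l.locus_type == "y_marker"]
        if len(y) != 1:
            raise ValueError(f"panel must contain exactly one y_marker, found {len(y)}")
        for l in self.loci:
            if l.locus_type == "species_diagnostic" and not l.diagnostic_alleles:
                raise ValueError(f"diagnostic locus {l.locus_id} lacks an allele table")

    @property
    def autosomal(self) -> tuple[LocusDef, ...]:
        return tuple(l for l in self.loci if l.locus_type == "autosomal_snp")

    @property
    def diagnostic(self) -> tuple[LocusDef, ...]:
        return tuple(l for l in self.loci if l.locus_type == "species_diagnostic")

    @property
    def y_marker(self) -> LocusDef:
        return next(l for l in self.loci if l.locus_type == "y_marker")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for l in self.loci:
            diag = l.diagnostic_alleles or {}
            rows.append({
                "locus_id": l.locus_id, "locus_type": l.locus_type,
                "allele1": l.allele1, "allele2": l.allele2,
                "wolf_allele": diag.get("wolf", ""),
                "coyote_allele": diag.get("coyote", ""),
            })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Panel":
        loci = []
        for _, r in df.iterrows():
            diag = None
            if r["locus_type"] == "species_diagnostic":
                diag = {"wolf": r["wolf_allele"], "coyote": r["coyote_allele"]}
            loci.append(LocusDef(str(r["locus_id"]), str(r["locus_type"]),
                                 str(r["allele1"]), str(r["allele2"]), diag))
        return cls(tuple(loci))

    @classmethod
    def default(cls, n_autosomal: int = 35) -> "Panel":
        """Study-style panel: 35 autosomal SNPs + 3 diagnostics + 1 Y marker."""
        loci = [LocusDef(f"snp{i:02d}", "autosomal_snp") for i in range(1, n_autosomal + 1)]
        loci += [
            LocusDef(f"diag{i}", "species_diagnostic",
                     diagnostic_alleles={"wolf": "A", "coyote": "B"})
            for i in (1, 2, 3)
        ]
        loci.append(LocusDef("ymark", "y_marker"))
        return cls(tuple(loci))


@dataclass
class MultilocusGenotype:
    """Consensus genotype of one sample (or merged individual)."""

    sample_id: str
    calls: dict[str, str]          # autosomal locus -> hom1|het|hom2|missing
    sex: str = "unknown"           # M | F | unknown
    species: str = "ambiguous"     # wolf | coyote | ambiguous
    n_autosomal: int = 0

    @property
    def missing_fraction(self) -> float:
        if self.n_autosomal == 0:
            return 1.0
        n_missing = sum(1 for c in self.calls.values() if c == MISSING)
        return n_missing / self.n_autosomal

    @property
    def qc_pass(self) -> bool:
        return qc_sample(self)


@dataclass
class Individual:
    """A genotype cluster: one wolf, its member samples and detections."""

    individual_id: str
    sample_ids: list[str]
    consensus: dict[str, str]
    sex: str
    sex_conflict: bool
    first_detection: pd.Timestamp | None = None
    last_detection: pd.Timestamp | None = None
    years_detected: frozenset[int] = frozenset()


# -- replicate-level calling -------------------------------------------------

def call_replicate(n1: int, n2: int, config: RunConfig | None = None) -> str:
    """Call one locus in one replicate from its two allele read counts.

    With depth = n1 + n2 and r = n1/depth: depth below ``min_depth`` is a
    nocall; r >= hom_ratio is hom1 and r <= 1 - hom_ratio is hom2; r within
    the [het_low, het_high] band is het; anything else (an imbalanced
    intermediate ratio) is a nocall.
    """
    config = config or RunConfig()
    if n1 < 0 or n2 < 0:
        raise ValueError("negative read counts")
    depth = n1 + n2
    if depth < config.min_depth:
        return NOCALL
    r = n1 / depth
    if r >= config.hom_ratio:
        return HOM1
    if r <= 1.0 - config.hom_ratio:
        return HOM2
    if config.het_low <= r <= config.het_high:
        return HET
    return NOCALL


def consensus(replicate_calls: Sequence[str]) -> str:
    """Consensus of up to three replicate calls.

    Heterozygote: at least two of three replicates het. Homozygote: all
    three replicates agree on the same homozygote. Anything else is missing.
    """
    calls = list(replicate_calls)
    if len(calls) > 3:
        raise ValueError("more than three replicates")
    if sum(1 for c in calls if c == HET) >= 2:
        return HET
    for hom in (HOM1, HOM2):
        if len(calls) == 3 and all(c == hom for c in calls):
            return hom
    return MISSING


def qc_sample(genotype: MultilocusGenotype, config: RunConfig | None = None) -> bool:
    """Sample QC: fail iff the missing-locus fraction strictly exceeds 20%."""
    config = config or RunConfig()
    return genotype.missing_fraction <= config.max_missing_fraction


def assign_sex(
    y_depths: Sequence[int], qc_passed: bool, config: RunConfig | None = None
) -> str:
    """Sex from per-replicate Y-marker depths.

    Male: Y amplified at ``sex_min_depth`` or more in at least
    ``sex_min_replicates`` replicates. Female: Y absent in every replicate
    *and* the autosomal genotype passed QC (guards against calling females
    from failed amplifications). Otherwise unknown.
    """
    config = config or RunConfig()
    positives = sum(1 for d in y_depths if d >= config.sex_min_depth)
    if positives >= config.sex_min_replicates:
        return "M"
    if all(d == 0 for d in y_depths) and qc_passed:
        return "F"
    return "unknown"


def species_diagnostic(
    diagnostic_calls: Mapping[str, str], panel: Panel
) -> str:
    """Species from the three wolf-versus-coyote diagnostic loci.

    Each non-missing diagnostic locus votes for the species whose fixed
    allele it carries (heterozygous calls are ambiguous votes and abstain);
    majority wins, ties or no information give ambiguous.
    """
    votes = {"wolf": 0, "coyote": 0}
    for locus in panel.diagnostic:
        call = diagnostic_calls.get(locus.locus_id, MISSING)
        if call in (MISSING, NOCALL, HET):
            continue
        carried = locus.allele1 if call == HOM1 else locus.allele2
        for sp, allele in (locus.diagnostic_alleles or {}).items():
            if carried == allele:
                votes[sp] += 1
    if votes["wolf"] > votes["coyote"]:
        return "wolf"
    if votes["coyote"] > votes["wolf"]:
        return "coyote"
    return "ambiguous"


def genotype_samples(
    allele_counts: pd.DataFrame,
    panel: Panel,
    config: RunConfig | None = None,
) -> list[MultilocusGenotype]:
    """Full per-sample calling: replicate calls -> consensus -> QC -> sex/species.

    ``allele_counts`` has columns sample_id, replicate, locus_id,
    allele1_count, allele2_count. Loci absent from a sample's table are
    missing. Returns one MultilocusGenotype per sample (QC status via
    ``qc_pass``).
    """
    config = config or RunConfig()
    autosomal_ids = [l.locus_id for l in panel.autosomal]
    diag_ids = [l.locus_id for l in panel.diagnostic]
    y_id = panel.y_marker.locus_id
    out = []
    for sample_id, sub in allele_counts.groupby("sample_id", sort=True):
        by_locus: dict[str, list[str]] = {}
        for _, r in sub.iterrows():
            call = call_replicate(int(r["allele1_count"]), int(r["allele2_count"]), config)
            by_locus.setdefault(str(r["locus_id"]), []).append(call)
        calls = {loc: consensus(by_locus.get(loc, [])) for loc in autosomal_ids}
        diag_calls = {loc: consensus(by_locus.get(loc, [])) for loc in diag_ids}
        geno = MultilocusGenotype(
            sample_id=str(sample_id),
            calls=calls,
            n_autosomal=len(autosomal_ids),
        )
        qc = qc_sample(geno, config)
        y_rows = sub.loc[sub["locus_id"] == y_id]
        y_depths_by_rep = {int(r["replicate"]): int(r["allele1_count"]) + int(r["allele2_count"])
                           for _, r in y_rows.iterrows()}
        y_depths = [y_depths_by_rep.get(rep, 0) for rep in (1, 2, 3)]
        geno.sex = assign_sex(y_depths, qc, config)
        geno.species = species_diagnostic(diag_calls, panel)
        out.append(geno)
    return out


# -- allele frequencies and probability of identity --------------------------

def allele_frequencies(genotypes: Sequence[MultilocusGenotype]) -> dict[str, float]:
    """Per-locus frequency of allele 1, from one genotype per individual.

    p = (2*#hom1 + #het) / (2 * #called). Loci with no called individuals are
    excluded with a warning.
    """
    loci = sorted({loc for g in genotypes for loc in g.calls})
    freqs: dict[str, float] = {}
    for loc in loci:
        calls = [g.calls.get(loc, MISSING) for g in genotypes]
        called = [c for c in calls if c in _CODE]
        if not called:
            warnings.warn(f"locus {loc}: no called individuals, excluded")
            continue
        n1 = sum(2 for c in called if c == HOM1) + sum(1 for c in called if c == HET)
        freqs[loc] = n1 / (2 * len(called))
    return freqs


def pid_locus(allele_freqs: Sequence[float]) -> float:
    """Expected probability of identity at one locus.

    PID = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2 — the probability that two
    unrelated individuals drawn from Hardy-Weinberg proportions share a
    genotype.
    """
    p = np.asarray(allele_freqs, dtype=float)
    _check_freqs(p)
    hom = float(np.sum(p ** 4))
    het = sum((2 * p[i] * p[j]) ** 2 for i, j in itertools.combinations(range(len(p)), 2))
    return hom + het


def pid_sibs_locus(allele_freqs: Sequence[float]) -> float:
    """Probability of identity between full siblings at one locus.

    PIDsib = 0.25 + 0.5*sum(p^2) + 0.5*(sum(p^2))^2 - 0.25*sum(p^4); always
    at least as large as the unrelated-pair PID.
    """
    p = np.asarray(allele_freqs, dtype=float)
    _check_freqs(p)
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 0.25 + 0.5 * s2 + 0.5 * s2 ** 2 - 0.25 * s4


def _check_freqs(p: np.ndarray) -> None:
    if (p < 0).any() or (p > 1).any():
        raise ValueError("allele frequencies outside [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies sum to {p.sum()}, not 1")


def pid_expected(freqs: Mapping[str, float]) -> tuple[dict[str, float], float]:
    """Per-locus and multilocus (product) PID over a biallelic panel."""
    per_locus = {loc: pid_locus([p, 1.0 - p]) for loc, p in freqs.items()}
    return per_locus, float(np.prod(list(per_locus.values()))) if per_locus else 1.0


def pid_sibs(freqs: Mapping[str, float]) -> tuple[dict[str, float], float]:
    """Per-locus and multilocus (product) PIDsibs over a biallelic panel."""
    per_locus = {loc: pid_sibs_locus([p, 1.0 - p]) for loc, p in freqs.items()}
    return per_locus, float(np.prod(list(per_locus.values()))) if per_locus else 1.0


# -- individual matching and detection histories ------------------------------

def genotype_distance(g1: MultilocusGenotype, g2: MultilocusGenotype) -> tuple[int, int]:
    """(mismatching loci, co-called loci) between two consensus genotypes."""
    shared = [loc for loc, c in g1.calls.items()
              if c in _CODE and g2.calls.get(loc, MISSING) in _CODE]
    mismatches = sum(1 for loc in shared if g1.calls[loc] != g2.calls[loc])
    return mismatches, len(shared)


def match_individuals(
    genotypes: Sequence[MultilocusGenotype],
    config: RunConfig | None = None,
) -> list[Individual]:
    """Cluster QC-passed sample genotypes into individuals.

    Two samples match when they share at least ``min_shared_loci`` co-called
    loci and differ at no more than ``max_mismatch`` of them; individuals are
    the connected components of the match graph. The per-individual consensus
    is the per-locus majority call (ties -> missing). Components containing
    both male and female members are kept but flagged, never silently merged
    or split.
    """
    config = config or RunConfig()
    passed = [g for g in genotypes if qc_sample(g, config)]
    graph = nx.Graph()
    graph.add_nodes_from(range(len(passed)))
    for i, j in itertools.combinations(range(len(passed)), 2):
        mism, shared = genotype_distance(passed[i], passed[j])
        if shared >= config.min_shared_loci and mism <= config.max_mismatch:
            graph.add_edge(i, j)
    individuals = []
    components = sorted(nx.connected_components(graph),
                        key=lambda c: min(passed[i].sample_id for i in c))
    for k, comp in enumerate(components, start=1):
        members = sorted((passed[i] for i in comp), key=lambda g: g.sample_id)
        cons: dict[str, str] = {}
        loci = sorted({loc for g in members for loc in g.calls})
        for loc in loci:
            votes = pd.Series([g.calls[loc] for g in members
                               if g.calls.get(loc, MISSING) in _CODE])
            if votes.empty:
                cons[loc] = MISSING
                continue
            counts = votes.value_counts()
            top = counts[counts == counts.max()]
            cons[loc] = top.index[0] if len(top) == 1 else MISSING
        sexes = {g.sex for g in members} - {"unknown"}
        conflict = sexes == {"M", "F"}
        sex = sexes.pop() if len(sexes) == 1 else "unknown"
        individuals.append(Individual(
            individual_id=f"ind{k:03d}",
            sample_ids=[g.sample_id for g in members],
            consensus=cons,
            sex=sex,
            sex_conflict=conflict,
        ))
    return individuals


def _year_of(date: pd.Timestamp, year_mode: str) -> int:
    """Calendar year, or biological year starting 1 May (labelled by onset)."""
    if year_mode == "biological":
        return date.year if date.month >= 5 else date.year - 1
    return date.year


def detection_history(
    individuals: Sequence[Individual],
    sample_dates: Mapping[str, pd.Timestamp],
    config: RunConfig | None = None,
) -> list[Individual]:
    """Attach first/last detection dates and per-year detection flags.

    A year is flagged iff at least one member sample is dated in it. Member
    samples without a date are excluded with a warning.
    """
    config = config or RunConfig()
    out = []
    for ind in individuals:
        dates = []
        for sid in ind.sample_ids:
            d = sample_dates.get(sid)
            if d is None or pd.isna(d):
                warnings.warn(f"sample {sid} of {ind.individual_id} has no date; excluded")
                continue
            dates.append(pd.Timestamp(d))
        years = frozenset(_year_of(d, config.year_mode) for d in dates)
        out.append(Individual(
            individual_id=ind.individual_id,
            sample_ids=ind.sample_ids,
            consensus=ind.consensus,
            sex=ind.sex,
            sex_conflict=ind.sex_conflict,
            first_detection=min(dates) if dates else None,
            last_detection=max(dates) if dates else None,
            years_detected=years,
        ))
    return out


def roster_to_frame(individuals: Sequence[Individual]) -> pd.DataFrame:
    rows = [
        {
            "individual_id": ind.individual_id,
            "n_samples": len(ind.sample_ids),
            "sample_ids": ";".join(ind.sample_ids),
            "sex": ind.sex,
            "sex_conflict": ind.sex_conflict,
            "first_detection": ind.first_detection.date().isoformat()
            if ind.first_detection is not None else "",
            "last_detection": ind.last_detection.date().isoformat()
            if ind.last_detection is not None else "",
            "years_detected": ";".join(str(y) for y in sorted(ind.years_detected)),
        }
        for ind in individuals
    ]
    return pd.DataFrame(rows, columns=[
        "individual_id", "n_samples", "sample_ids", "sex", "sex_conflict",
        "first_detection", "last_detection", "years_detected",
    ])


def genotypes_to_matrix(
    genotypes: Sequence[MultilocusGenotype] | Sequence[Individual],
) -> pd.DataFrame:
    """Samples-or-individuals x loci matrix coded as copies of allele 1."""
    rows = {}
    for g in genotypes:
        calls = g.calls if isinstance(g, MultilocusGenotype) else g.consensus
        gid = g.sample_id if isinstance(g, MultilocusGenotype) else g.individual_id
        rows[gid] = {loc: _CODE.get(c, np.nan) for loc, c in calls.items()}
    return pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)


# -- SNP-matrix filters -------------------------------------------------------

def hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Given genotype counts, conditions on the observed allele counts and sums
    the probabilities of all heterozygote counts no more probable than the
    observed one:

        P(h | n, nA) = n! / (nAA! nAB! nBB!) * 2^h * nA! nB! / (2n)!

    Monomorphic samples return p = 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype counts")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0

    def log_prob(h: int) -> float:
        aa = (n_a - h) // 2
        bb = (n_b - h) // 2
        return (
            gammaln(n + 1) - gammaln(aa + 1) - gammaln(h + 1) - gammaln(bb + 1)
            + h * np.log(2.0)
            + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
        )

    h_max = min(n_a, n_b)
    hs = list(range(h_max % 2, h_max + 1, 2))
    logs = np.array([log_prob(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hs.index(n_ab)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def filter_snps(
    matrix: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """PLINK-style locus and sample filters on a 0/1/2 genotype matrix.

    In order: drop loci with missingness > ``max_locus_missing``; drop loci
    with minor allele frequency < ``min_maf``; drop loci with exact HWE
    p < ``hwe_alpha``; greedily prune one locus of every pair with genotype
    correlation r^2 > ``ld_r2`` (keeping the lower-missingness locus); drop
    samples with missingness > ``max_sample_missing``.
    """
    config = config or RunConfig()
    m = matrix.copy()

    miss = m.isna().mean(axis=0)
    m = m.loc[:, miss <= config.max_locus_missing]

    def maf(col: pd.Series) -> float:
        vals = col.dropna()
        if vals.empty:
            return 0.0
        p = vals.sum() / (2 * len(vals))
        return min(p, 1 - p)

    m = m.loc[:, [c for c in m.columns if maf(m[c]) >= config.min_maf]]

    keep = []
    for c in m.columns:
        vals = m[c].dropna()
        n_aa = int((vals == 2).sum())
        n_ab = int((vals == 1).sum())
        n_bb = int((vals == 0).sum())
        if vals.empty or hwe_exact(n_aa, n_ab, n_bb) >= config.hwe_alpha:
            keep.append(c)
    m = m[keep]

    # greedy pairwise r^2 pruning; no genomic windows (panel loci are unlinked
    # by design, coordinates are meaningless at this scale)
    dropped: set[str] = set()
    cols = list(m.columns)
    miss_rate = m.isna().mean(axis=0)
    for i, a in enumerate(cols):
        if a in dropped:
            continue
        for b in cols[i + 1:]:
            if b in dropped:
                continue
            pair = m[[a, b]].dropna()
            if len(pair) < 3 or pair[a].std() == 0 or pair[b].std() == 0:
                continue
            r2 = pair[a].corr(pair[b]) ** 2
            if r2 > config.ld_r2:
                victim = a if miss_rate[a] > miss_rate[b] else b
                dropped.add(victim)
                if victim == a:
                    break
    m = m.drop(columns=sorted(dropped))

    sample_miss = m.isna().mean(axis=1)
    m = m.loc[sample_miss <= config.max_sample_missing]

    if m.shape[1] == 0:
        raise ValueError("no loci survive the filters")
    return m
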