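"""Synthetic scat-DNA datasets with known ground truth.

The generator emulates the structure of a multi-year noninvasive wolf study:
a founder pair colonises, breeds annually and suffers harvest and natural
mortality (with an optional immigrant male replacing a dead breeding male);
genotypes descend by Mendelian gene dropping over a biallelic amplicon panel
with a Y-chromosome sex marker and species-diagnostic loci; individual diets
are drawn from a pack-level Dirichlet (high concentration and a shared mean
for the island-like preset, low concentration for the mainland-like preset);
scats carry multi-prey item sets, triplicate PCR read counts with
sequencing-depth noise and trace contamination, and triplicate genotyping
replicates with allelic dropout, false alleles and locus failure.

Everything is seed-deterministic and emitted in exactly the file formats the
pipeline consumes, alongside a ground-truth record for verification.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .genotyping import HET, HOM1, HOM2, Panel
from .io import (SampleSheetRow, ReferenceRecord, write_category_map,
                 write_reference_fasta, write_sample_sheet)
from .pedigree import Pedigree, PedigreeRecord

CATEGORIES = ("sea_otter", "ungulates", "voles", "seabirds", "fish", "other")

TAXA_BY_CATEGORY: dict[str, tuple[str, ...]] = {
    "sea_otter": ("Enhydra lutris",),
    "ungulates": ("Alces alces", "Odocoileus hemionus"),
    "voles": ("Microtus pennsylvanicus",),
    "seabirds": ("Larus glaucescens", "Uria aalge"),
    "fish": ("Oncorhynchus keta",),
    "other": ("Castor canadensis",),
}

PREDATOR_TAXON = "Canis lupus"
CONTAMINANT_TAXON = "Homo sapiens"

# pack-level diet means follow the reported composition of the two study
# packs: the island pack dominated by sea otter with seabirds second, the
# mainland pack by ungulates with voles second
ISLAND_DIET_MEAN = {
    "sea_otter": 0.60, "seabirds": 0.13, "fish": 0.10,
    "ungulates": 0.05, "voles": 0.04, "other": 0.08,
}
MAINLAND_DIET_MEAN = {
    "sea_otter": 0.14, "seabirds": 0.08, "fish": 0.05,
    "ungulates": 0.50, "voles": 0.19, "other": 0.04,
}


@dataclass
class SimConfig:
    """All knobs of the generator; defaults give the island-like scenario."""

    # demography
    n_founders: int = 2
    start_year: int = 2016
    n_years: int = 7
    litter_mean: float = 4.0          # Poisson litter size (0 allowed)
    litter_fixed: int | None = None   # overrides litter_mean when set
    harvest_prob: float = 0.15        # per-individual per-year
    natural_death_prob: float = 0.05
    immigrant_breeder: bool = True    # immigrant male replaces a dead breeding male
    min_parent_age: int = 2           # adults only as breeders

    # genotypes
    n_autosomal_loci: int = 35
    founder_freq_low: float = 0.3     # founder allele frequencies ~ U(low, high)
    founder_freq_high: float = 0.7

    # diet
    diet_means: Mapping[str, float] = field(default_factory=lambda: dict(ISLAND_DIET_MEAN))
    dirichlet_alpha: float = 60.0     # island-like concentration; mainland ~ 2.5
    scats_per_individual_year: int = 4
    items_per_scat_mean: float = 1.5  # zero-truncated Poisson

    # metabarcoding reads
    read_depth_mean: float = 500.0    # negative binomial per replicate
    read_depth_dispersion: float = 5.0
    contamination_rate: float = 0.05      # per scat
    contamination_fraction: float = 0.002  # of sample reads, strictly < the 0.5% floor
    contamination_replicates: int = 1      # trace contamination hits one replicate

    # genotyping reads
    geno_depth_mean: float = 200.0
    geno_depth_dispersion: float = 5.0
    dropout_rate: float = 0.1         # per heterozygous replicate
    false_allele_rate: float = 0.01
    locus_failure_rate: float = 0.05  # whole-locus amplification failure per sample

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("harvest_prob", "natural_death_prob", "contamination_rate",
                     "dropout_rate", "false_allele_rate", "locus_failure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if self.read_depth_mean <= 0 or self.geno_depth_mean <= 0:
            raise ValueError("read depths must be positive")
        if not 0 <= self.founder_freq_low <= self.founder_freq_high <= 1:
            raise ValueError("founder frequency bounds out of order")
        if self.contamination_fraction >= 0.005:
            raise ValueError("contamination_fraction must stay below the 0.5% floor")

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


def island_config(**overrides) -> SimConfig:
    """Island-like preset: shared diet mean, high Dirichlet concentration."""
    return SimConfig(**overrides)


def mainland_config(**overrides) -> SimConfig:
    """Mainland-like preset: divergent individual diets (low concentration)."""
    defaults = dict(diet_means=dict(MAINLAND_DIET_MEAN), dirichlet_alpha=2.5)
    defaults.update(overrides)
    return SimConfig(**defaults)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    pedigree: Pedigree
    alive_years: dict[str, list[int]]
    genotypes: dict[str, dict[str, str]]      # individual -> locus -> call
    sexes: dict[str, str]
    diets: dict[str, dict[str, float]]        # individual -> category -> prob
    scat_owner: dict[str, str]                # sample_id -> individual
    scat_items: dict[str, frozenset[str]]     # sample_id -> category set
    scat_dates: dict[str, pd.Timestamp]


# -- pedigree ----------------------------------------------------------------

def simulate_pedigree(
    config: SimConfig, seed: int | None = None, max_retries: int = 10
) -> tuple[Pedigree, dict[str, list[int]]]:
    """Simulate the pack pedigree and per-individual alive years.

    A founder pair colonises in the first study year and breeds annually;
    per-year survival draws apply to everyone; a dead breeding female is
    replaced by her oldest adult daughter, a dead breeding male by an
    immigrant (or the oldest adult son when ``immigrant_breeder`` is off).
    Regenerates (bounded retries) if the pack dies out before the study ends.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    for attempt in range(max_retries):
        result = _try_pedigree(config, rng)
        if result is not None:
            return result
        warnings.warn(f"pack went extinct (attempt {attempt + 1}); regenerating")
    raise RuntimeError(f"pack extinct in all {max_retries} attempts")


def _try_pedigree(
    config: SimConfig, rng: np.random.Generator
) -> tuple[Pedigree, dict[str, list[int]]] | None:
    records: dict[str, PedigreeRecord] = {}
    counter = {"F": 0, "M": 0}

    def new_id(sex: str) -> str:
        counter[sex] += 1
        return f"{sex}{counter[sex]:03d}"

    def add(sex: str, birth: int, dam=None, sire=None) -> str:
        iid = new_id(sex)
        records[iid] = PedigreeRecord(iid, sex, dam, sire, birth)
        return iid

    y0 = config.start_year
    dam0 = add("F", y0 - config.min_parent_age - 1)
    sire0 = add("M", y0 - config.min_parent_age - 1)
    breeders = {"F": dam0, "M": sire0}
    alive: set[str] = {dam0, sire0}
    alive_years: dict[str, list[int]] = {dam0: [], sire0: []}
    death: dict[str, tuple[int, str]] = {}
    pending_immigrant = False

    for year in range(y0, y0 + config.n_years):
        if pending_immigrant and breeders["M"] is None:
            imm = add("M", year - config.min_parent_age)
            alive.add(imm)
            alive_years[imm] = []
            breeders["M"] = imm
            pending_immigrant = False
        if breeders["F"] in alive and breeders["M"] in alive:
            size = (config.litter_fixed if config.litter_fixed is not None
                    else int(rng.poisson(config.litter_mean)))
            for _ in range(size):
                sex = "F" if rng.random() < 0.5 else "M"
                pup = add(sex, year, breeders["F"], breeders["M"])
                alive.add(pup)
                alive_years[pup] = []
        for iid in sorted(alive):
            alive_years[iid].append(year)
        # end-of-year survival draws
        for iid in sorted(alive):
            u = rng.random()
            if u < config.harvest_prob:
                death[iid] = (year, "harvested")
            elif u < config.harvest_prob + config.natural_death_prob:
                death[iid] = (year, "natural_death")
        for iid in list(death):
            alive.discard(iid)
        for role in ("F", "M"):
            if breeders[role] is not None and breeders[role] not in alive:
                mate = breeders["M" if role == "F" else "F"]
                breeders[role] = _replacement(
                    role, records, alive, year + 1, config, mate
                )
                if role == "F" and breeders[role] is None:
                    # all adult females are first-degree kin of the sitting
                    # male: he is deposed and an immigrant male arrives, so a
                    # daughter can breed without incest (observed breeder-
                    # turnover pattern in closed island packs)
                    breeders["F"] = _replacement(role, records, alive,
                                                 year + 1, config, None)
                    if breeders["F"] is not None:
                        breeders["M"] = None
                if role == "M" and breeders[role] is None and config.immigrant_breeder:
                    pending_immigrant = True
        if not alive and year < y0 + config.n_years - 1:
            return None

    final: list[PedigreeRecord] = []
    for iid, rec in records.items():
        if iid in death:
            dyear, fate = death[iid]
            final.append(dataclasses.replace(rec, fate=fate, death_year=dyear))
        else:
            final.append(dataclasses.replace(rec, fate="alive"))
    return Pedigree(final), alive_years


def _first_degree(records, a: str, b: str) -> bool:
    """Parent, offspring or full sibling (incest-avoidance radius)."""
    ra, rb = records[a], records[b]
    if a in (rb.dam_id, rb.sire_id) or b in (ra.dam_id, ra.sire_id):
        return True
    return (ra.dam_id is not None and ra.dam_id == rb.dam_id
            and ra.sire_id is not None and ra.sire_id == rb.sire_id)


def _replacement(role, records, alive, year, config, mate) -> str | None:
    """Oldest eligible adult of the role, avoiding first-degree kin of the mate."""
    eligible = [
        iid for iid in sorted(alive)
        if records[iid].sex == role
        and (records[iid].birth_year is None
             or year - records[iid].birth_year >= config.min_parent_age)
        and (mate is None or mate not in alive or not _first_degree(records, iid, mate))
    ]
    if not eligible:
        return None
    # oldest first; ties broken by id for determinism
    eligible.sort(key=lambda i: (records[i].birth_year or -10_000, i))
    return eligible[0]


# -- genotypes ---------------------------------------------------------------

def simulate_genotypes(
    pedigree: Pedigree, config: SimConfig, seed: int | None = None
) -> tuple[dict[str, dict[str, str]], np.ndarray]:
    """Gene-drop genotypes down the pedigree.

    Founders (anyone without recorded parents, including immigrants) draw
    Hardy-Weinberg genotypes at per-locus allele-1 frequencies sampled
    uniformly from the configured band; offspring inherit one uniformly
    random allele per parent per locus. Returns (genotypes, founder
    frequencies); the Y marker and the diagnostic loci are implicit in sex
    and species (all simulated individuals are wolves).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    loci = [f"snp{i:02d}" for i in range(1, config.n_autosomal_loci + 1)]
    freqs = rng.uniform(config.founder_freq_low, config.founder_freq_high,
                        size=config.n_autosomal_loci)
    # allele-pair representation during the drop: (a, b) with 1 = allele 1
    pairs: dict[str, np.ndarray] = {}

    order = _topological_order(pedigree)
    for iid in order:
        dam, sire = pedigree.parents(iid)
        if dam is None or sire is None:
            a = rng.random(config.n_autosomal_loci) < freqs
            b = rng.random(config.n_autosomal_loci) < freqs
        else:
            pick_d = rng.integers(0, 2, size=config.n_autosomal_loci)
            pick_s = rng.integers(0, 2, size=config.n_autosomal_loci)
            a = pairs[dam][pick_d, np.arange(config.n_autosomal_loci)]
            b = pairs[sire][pick_s, np.arange(config.n_autosomal_loci)]
        pairs[iid] = np.vstack([a, b])

    genotypes: dict[str, dict[str, str]] = {}
    for iid, pair in pairs.items():
        dose = pair.sum(axis=0)
        genotypes[iid] = {
            loc: (HOM1 if d == 2 else HET if d == 1 else HOM2)
            for loc, d in zip(loci, dose)
        }
    return genotypes, freqs


def _topological_order(pedigree: Pedigree) -> list[str]:
    order, seen = [], set()

    def visit(iid: str) -> None:
        if iid in seen:
            return
        seen.add(iid)
        for pid in pedigree.parents(iid):
            if pid is not None:
                visit(pid)
        order.append(iid)

    for iid in sorted(pedigree.records):
        visit(iid)
    return order


# -- diets, scats and metabarcoding reads ------------------------------------

def simulate_diets(
    individuals: Sequence[str], config: SimConfig, seed: int | None = None
) -> dict[str, dict[str, float]]:
    """Per-individual diet vectors ~ Dirichlet(alpha * pack mean)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mean = np.array([config.diet_means.get(c, 0.0) for c in CATEGORIES], dtype=float)
    if mean.sum() <= 0:
        raise ValueError("diet means sum to zero")
    mean /= mean.sum()
    # Dirichlet parameters must be positive; zero-mean categories get a
    # vanishing pseudo-count so the draw stays well-defined
    alpha = np.maximum(config.dirichlet_alpha * mean, 1e-6)
    return {
        iid: dict(zip(CATEGORIES, rng.dirichlet(alpha)))
        for iid in sorted(individuals)
    }


def _negbin(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial draw parameterised by mean and dispersion k."""
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _zt_poisson(rng: np.random.Generator, mean: float, upper: int) -> int:
    """Zero-truncated Poisson draw, capped at ``upper``."""
    for _ in range(1000):
        k = int(rng.poisson(mean))
        if 1 <= k <= upper:
            return k
    return 1


def simulate_scats_and_reads(
    truth_diets: dict[str, dict[str, float]],
    alive_years: dict[str, list[int]],
    config: SimConfig,
    seed: int | None = None,
    study_area: str = "island",
) -> tuple[pd.DataFrame, list[SampleSheetRow], dict]:
    """Simulate scats with triplicate metabarcoding read tables.

    Each scat draws its item set from its owner's diet (distinct categories,
    zero-truncated Poisson count), a species per category, and per-replicate
    multinomial read counts over predator + items at negative-binomial depth.
    Trace contamination is injected per config: strictly below the 0.5%
    abundance floor and confined to one replicate, so the published filters
    are exactly sufficient to remove it.

    Returns (taxon count table, sample sheet rows, scat ground truth) where
    the ground truth maps sample_id -> (owner, category set, date).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mean_cats = np.array([1.0 if config.diet_means.get(c, 0) > 0 else 0.0
                          for c in CATEGORIES])
    rows = []
    sheet: list[SampleSheetRow] = []
    truth: dict[str, tuple[str, frozenset[str], pd.Timestamp]] = {}
    n = 0
    for iid in sorted(truth_diets):
        diet = np.array([truth_diets[iid][c] for c in CATEGORIES])
        years = alive_years.get(iid, [])
        for year in years:
            for _ in range(config.scats_per_individual_year):
                n += 1
                sid = f"S{n:05d}"
                day = int(rng.integers(0, 365))
                date = pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=day)
                k = _zt_poisson(rng, config.items_per_scat_mean,
                                int(mean_cats.sum()))
                probs = diet / diet.sum()
                cats = rng.choice(len(CATEGORIES), size=k, replace=False, p=probs)
                cat_names = frozenset(CATEGORIES[c] for c in cats)
                taxa = [
                    TAXA_BY_CATEGORY[c][rng.integers(0, len(TAXA_BY_CATEGORY[c]))]
                    for c in sorted(cat_names)
                ]
                # predator reads get the same total mass as all prey items
                weights = np.array([1.0] + [1.0 / len(taxa)] * len(taxa))
                weights /= weights.sum()
                names = [PREDATOR_TAXON] + taxa
                total = 0
                for rep in (1, 2, 3):
                    depth = max(_negbin(rng, config.read_depth_mean,
                                        config.read_depth_dispersion), 50)
                    counts = rng.multinomial(depth, weights)
                    total += depth
                    for taxon, c in zip(names, counts):
                        if c > 0:
                            rows.append((sid, rep, taxon, int(c)))
                if rng.random() < config.contamination_rate:
                    c_reads = max(1, int(config.contamination_fraction * total))
                    rep = int(rng.integers(1, 4))
                    rows.append((sid, rep, CONTAMINANT_TAXON, c_reads))
                sheet.append(SampleSheetRow(sid, date, study_area))
                truth[sid] = (iid, cat_names, date)
    counts = pd.DataFrame(rows, columns=["sample_id", "replicate", "taxon", "count"])
    return counts, sheet, truth


# -- genotyping reads --------------------------------------------------------

def simulate_genotype_reads(
    genotypes: dict[str, dict[str, str]],
    sexes: dict[str, str],
    scat_owner: dict[str, str],
    config: SimConfig,
    seed: int | None = None,
    panel: Panel | None = None,
) -> pd.DataFrame:
    """Per-replicate allele-count tables for every scat sample.

    Per (sample, locus): whole-locus amplification failure with the
    configured probability (degraded-template mode); otherwise per replicate
    a negative-binomial depth, allelic dropout of one random allele of a
    heterozygote with probability ``dropout_rate``, and multinomial counts
    with ``false_allele_rate`` leakage to the absent allele. The Y marker
    amplifies only in males (per-replicate failure); the diagnostic loci are
    fixed for the wolf allele.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    panel = panel or Panel.default(config.n_autosomal_loci)
    f = config.false_allele_rate
    rows = []
    for sid in sorted(scat_owner):
        iid = scat_owner[sid]
        geno = genotypes[iid]
        for locus in panel.autosomal:
            if rng.random() < config.locus_failure_rate:
                continue
            call = geno[locus.locus_id]
            for rep in (1, 2, 3):
                depth = _negbin(rng, config.geno_depth_mean,
                                config.geno_depth_dispersion)
                if depth == 0:
                    continue
                if call == HET:
                    if rng.random() < config.dropout_rate:
                        kept = int(rng.integers(0, 2))  # 0 -> allele1 kept
                        probs = (1 - f, f) if kept == 0 else (f, 1 - f)
                    else:
                        probs = (0.5, 0.5)
                elif call == HOM1:
                    probs = (1 - f, f)
                else:
                    probs = (f, 1 - f)
                n1, n2 = rng.multinomial(depth, probs)
                rows.append((sid, rep, locus.locus_id, int(n1), int(n2)))
        for locus in panel.diagnostic:
            if rng.random() < config.locus_failure_rate:
                continue
            for rep in (1, 2, 3):
                depth = _negbin(rng, config.geno_depth_mean,
                                config.geno_depth_dispersion)
                if depth == 0:
                    continue
                n1, n2 = rng.multinomial(depth, (1 - f, f))
                rows.append((sid, rep, locus.locus_id, int(n1), int(n2)))
        if sexes[iid] == "M":
            for rep in (1, 2, 3):
                if rng.random() < config.locus_failure_rate:
                    continue
                depth = _negbin(rng, config.geno_depth_mean,
                                config.geno_depth_dispersion)
                if depth > 0:
                    rows.append((sid, rep, panel.y_marker.locus_id, depth, 0))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "replicate", "locus_id",
                 "allele1_count", "allele2_count"],
    )


# -- full dataset ------------------------------------------------------------

def simulate_dataset(
    config: SimConfig, seed: int | None = None, study_area: str = "island"
) -> tuple[GroundTruth, dict[str, pd.DataFrame | list]]:
    """Simulate a complete dataset: pedigree, genotypes, diets, scats, reads.

    Returns the ground truth and a dict of tables keyed by file stem
    (taxon_counts, allele_counts, sample sheet rows, panel).
    """
    base = np.random.default_rng(config.seed if seed is None else seed)
    s_ped, s_gen, s_diet, s_scat, s_reads = base.integers(0, 2**31 - 1, size=5)
    pedigree, alive_years = simulate_pedigree(config, int(s_ped))
    genotypes, _freqs = simulate_genotypes(pedigree, config, int(s_gen))
    sexes = {iid: rec.sex for iid, rec in pedigree.records.items()}
    diets = simulate_diets(list(pedigree.records), config, int(s_diet))
    taxon_counts, sheet, scat_truth = simulate_scats_and_reads(
        diets, alive_years, config, int(s_scat), study_area
    )
    scat_owner = {sid: t[0] for sid, t in scat_truth.items()}
    scat_items = {sid: t[1] for sid, t in scat_truth.items()}
    scat_dates = {sid: t[2] for sid, t in scat_truth.items()}
    allele_counts = simulate_genotype_reads(
        genotypes, sexes, scat_owner, config, int(s_reads)
    )
    truth = GroundTruth(
        pedigree=pedigree,
        alive_years=alive_years,
        genotypes=genotypes,
        sexes=sexes,
        diets=diets,
        scat_owner=scat_owner,
        scat_items=scat_items,
        scat_dates=scat_dates,
    )
    tables = {
        "taxon_counts": taxon_counts,
        "allele_counts": allele_counts,
        "sample_sheet": sheet,
        "panel": Panel.default(config.n_autosomal_loci),
    }
    return truth, tables


def individual_scenario(
    seed: int,
    n_individuals: int = 20,
    samples_per_individual: int = 5,
    config: SimConfig | None = None,
) -> tuple[dict[str, str], dict[str, dict[str, str]], pd.DataFrame, Panel]:
    """Fixed-size genotyping scenario: n individuals, k scat samples each.

    Simulates a pedigree (regenerating until it holds at least
    ``n_individuals``), gene-drops genotypes, and emits noisy triplicate
    allele-count tables for ``samples_per_individual`` samples per
    individual. Returns (sample -> owner, true genotypes, allele counts,
    panel).
    """
    config = config or SimConfig()
    base = np.random.default_rng(seed)
    for _ in range(20):
        s_ped, s_gen, s_reads = base.integers(0, 2**31 - 1, size=3)
        pedigree, _years = simulate_pedigree(config, int(s_ped))
        if len(pedigree.records) >= n_individuals:
            break
    else:
        raise RuntimeError(f"could not grow a pedigree of {n_individuals}")
    chosen = list(_topological_order(pedigree))[:n_individuals]
    genotypes, _ = simulate_genotypes(pedigree, config, int(s_gen))
    genotypes = {iid: genotypes[iid] for iid in chosen}
    sexes = {iid: pedigree.records[iid].sex for iid in chosen}
    owner = {
        f"S{i:05d}": iid
        for i, iid in enumerate(
            (iid for iid in chosen for _ in range(samples_per_individual)), start=1
        )
    }
    panel = Panel.default(config.n_autosomal_loci)
    counts = simulate_genotype_reads(genotypes, sexes, owner, config,
                                     int(s_reads), panel)
    return owner, genotypes, counts, panel


def category_map() -> dict[str, str]:
    """Taxon -> category map covering every simulated prey taxon."""
    return {t: c for c, taxa in TAXA_BY_CATEGORY.items() for t in taxa}


def reference_database(seed: int = 0, length: int = 100) -> list[ReferenceRecord]:
    """Synthetic 12S reference FASTA matching the simulated taxa.

    Random sequences are mutually dissimilar (far below the 90% family
    band), so each taxon maps uniquely.
    """
    rng = np.random.default_rng(seed)
    taxa = [(PREDATOR_TAXON, "Canis", "Canidae"),
            ("Canis latrans", "Canis", "Canidae"),
            (CONTAMINANT_TAXON, "Homo", "Hominidae")]
    genus_family = {
        "Enhydra lutris": ("Enhydra", "Mustelidae"),
        "Alces alces": ("Alces", "Cervidae"),
        "Odocoileus hemionus": ("Odocoileus", "Cervidae"),
        "Microtus pennsylvanicus": ("Microtus", "Cricetidae"),
        "Larus glaucescens": ("Larus", "Laridae"),
        "Uria aalge": ("Uria", "Alcidae"),
        "Oncorhynchus keta": ("Oncorhynchus", "Salmonidae"),
        "Castor canadensis": ("Castor", "Castoridae"),
    }
    taxa += [(sp, g, f) for sp, (g, f) in genus_family.items()]
    records = []
    for i, (species, genus, family) in enumerate(taxa, start=1):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        records.append(ReferenceRecord(f"ref{i:02d}", seq, species, genus, family))
    return records


def write_dataset(
    truth: GroundTruth,
    tables: dict,
    outdir: str | Path,
    seed: int = 0,
) -> None:
    """Write the complete dataset in the on-disk formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables["taxon_counts"].to_csv(outdir / "taxon_counts.tsv", sep="\t", index=False)
    tables["allele_counts"].to_csv(outdir / "allele_counts.tsv", sep="\t", index=False)
    write_sample_sheet(tables["sample_sheet"], outdir / "sample_sheet.tsv")
    tables["panel"].to_frame().to_csv(outdir / "panel.csv", index=False)
    write_category_map(category_map(), outdir / "category_map.csv")
    write_reference_fasta(reference_database(seed), outdir / "reference.fasta")

    gt = outdir / "ground_truth"
    gt.mkdir(exist_ok=True)
    truth.pedigree.to_csv(gt / "pedigree.csv")
    geno_rows = [
        {"individual_id": iid, **calls} for iid, calls in truth.genotypes.items()
    ]
    pd.DataFrame(geno_rows).to_csv(gt / "genotypes.tsv", sep="\t", index=False)
    diet_rows = [
        {"individual_id": iid, **d} for iid, d in truth.diets.items()
    ]
    pd.DataFrame(diet_rows).to_csv(gt / "diets.tsv", sep="\t", index=False)
    owner_rows = [
        {"sample_id": sid, "individual_id": truth.scat_owner[sid],
         "items": ";".join(sorted(truth.scat_items[sid]))}
        for sid in sorted(truth.scat_owner)
    ]
    pd.DataFrame(owner_rows).to_csv(gt / "scat_truth.tsv", sep="\t", index=False)
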