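"""Taxonomic assignment of 12S amplicon reads and scat classification.

Reads are assigned by exhaustive global-alignment identity against a small
curated reference FASTA. Rank follows the protocol's identity bands: a
unique 100% best hit is called to species; 100% ties within one genus (or
one family) collapse to that genus (family); hits in [99, 100)% fall back to
the genus of the best hit, [90, 99)% to its family, and anything below 90%
is unassigned. Per-sample filtering then applies the 2-of-3 PCR replicate
consensus and the 0.5% within-sample relative-abundance floor before each
scat is classified by its predator content.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .config import RunConfig
from .io import ReferenceRecord

_VALID = set("ACGTN")


@dataclass(frozen=True)
class ReadCluster:
    """A dereplicated read with its count in one PCR replicate."""

    sample_id: str
    replicate: int
    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.replicate not in (1, 2, 3):
            raise ValueError(f"replicate {self.replicate} outside {{1,2,3}}")
        if self.count < 1:
            raise ValueError(f"count {self.count} < 1")
        bad = set(self.sequence.upper()) - _VALID
        if bad:
            raise ValueError(f"non-ACGTN characters {sorted(bad)}")


@dataclass(frozen=True)
class TaxonCall:
    """A taxonomic assignment for reads of one sample."""

    taxon_name: str
    rank: str  # species | genus | family | unassigned
    best_identity: float
    reads: int
    replicates_detected: frozenset[int] = frozenset()


@dataclass
class ScatClassification:
    """Predator/prey content of one scat after all filters."""

    sample_id: str
    predator: str | None
    prey_taxa: list[TaxonCall]
    status: str  # wolf_diet | predator_only | non_target | failed


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


def _identity_one_strand(query: str, reference: str) -> float:
    alignment = _ALIGNER.align(query, reference)[0]
    q, r = alignment[0], alignment[1]
    matches = sum(
        1 for a, b in zip(q, r) if a == b and a not in ("-", "N")
    )
    return 100.0 * matches / len(q)


def compute_identity(query: str, reference: str) -> float:
    """Percent identity between two sequences under global alignment.

    Identity is matches over aligned columns (gaps included in the
    denominator); N never matches. Both strands are scored and the maximum
    is returned, so orientation does not matter.
    """
    query = query.upper()
    reference = reference.upper()
    if not query or not reference:
        raise ValueError("empty sequence")
    for name, seq in (("query", query), ("reference", reference)):
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"{name} contains non-ACGTN characters {sorted(bad)}")
    forward = _identity_one_strand(query, reference)
    reverse = _identity_one_strand(str(Seq(query).reverse_complement()), reference)
    return max(forward, reverse)


def assign_taxon(
    cluster: ReadCluster,
    refdb: Sequence[ReferenceRecord],
    config: RunConfig | None = None,
) -> TaxonCall:
    """Assign one read cluster against the reference database.

    Always returns a call; unresolvable reads come back with rank
    ``unassigned`` and are excluded downstream.
    """
    if not refdb:
        raise ValueError("empty reference database")
    config = config or RunConfig()
    identities = [(compute_identity(cluster.sequence, r.sequence), r) for r in refdb]
    best = max(i for i, _ in identities)
    reps = frozenset({cluster.replicate})

    if best >= config.species_identity:
        ties = [r for i, r in identities if i >= config.species_identity]
        species = {r.species for r in ties}
        if len(species) == 1:
            return TaxonCall(ties[0].species, "species", best, cluster.count, reps)
        genera = {r.genus for r in ties}
        if len(genera) == 1:
            return TaxonCall(ties[0].genus, "genus", best, cluster.count, reps)
        families = {r.family for r in ties}
        if len(families) == 1:
            return TaxonCall(ties[0].family, "family", best, cluster.count, reps)
        return TaxonCall("", "unassigned", best, cluster.count, reps)

    best_rec = max(identities, key=lambda ir: ir[0])[1]
    if best >= config.genus_identity:
        return TaxonCall(best_rec.genus, "genus", best, cluster.count, reps)
    if best >= config.family_identity:
        return TaxonCall(best_rec.family, "family", best, cluster.count, reps)
    return TaxonCall("", "unassigned", best, cluster.count, reps)


def assign_sample_reads(
    clusters: Iterable[ReadCluster],
    refdb: Sequence[ReferenceRecord],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Assign every read cluster and tabulate reads per (sample, replicate, taxon).

    Unassigned clusters are dropped. Returns columns sample_id, replicate,
    taxon, rank, count.
    """
    config = config or RunConfig()
    cache: dict[str, TaxonCall] = {}
    rows = []
    for cl in clusters:
        key = cl.sequence.upper()
        if key not in cache:
            cache[key] = assign_taxon(cl, refdb, config)
        call = cache[key]
        if call.rank == "unassigned":
            continue
        rows.append(
            {
                "sample_id": cl.sample_id,
                "replicate": cl.replicate,
                "taxon": call.taxon_name,
                "rank": call.rank,
                "count": cl.count,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["sample_id", "replicate", "taxon", "rank", "count"])
    df = pd.DataFrame(rows)
    return (
        df.groupby(["sample_id", "replicate", "taxon", "rank"], as_index=False)["count"]
        .sum()
    )


def replicate_consensus(
    sample_counts: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """Apply the 2-of-3 PCR replicate consensus within one sample.

    ``sample_counts`` holds one sample's rows (replicate, taxon, count). A
    taxon is retained iff it was detected in at least
    ``config.min_taxon_replicates`` replicates; with exactly two successful
    replicates this means detection in both. Samples with fewer than two
    successful replicates fail (empty frame with ``attrs['failed']`` set).

    Idempotent: applying the consensus twice equals applying it once.
    """
    config = config or RunConfig()
    out_cols = ["taxon", "reads", "replicates_detected"]
    if sample_counts.empty:
        out = pd.DataFrame(columns=out_cols)
        out.attrs["failed"] = True
        return out
    n_replicates = sample_counts["replicate"].nunique()
    if n_replicates < 2:
        out = pd.DataFrame(columns=out_cols)
        out.attrs["failed"] = True
        return out
    grouped = sample_counts.groupby("taxon").agg(
        reads=("count", "sum"),
        replicates_detected=("replicate", lambda s: frozenset(s)),
    )
    keep = grouped[grouped["replicates_detected"].map(len) >= config.min_taxon_replicates]
    out = keep.reset_index()[out_cols]
    out.attrs["failed"] = False
    return out


def abundance_filter(
    retained: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """Drop taxa below the 0.5% within-sample relative-abundance floor.

    The denominator is the post-consensus read total for the sample, summed
    over replicates. The comparison is strict: a taxon at exactly the
    threshold is retained. Idempotent because surviving proportions are
    unchanged relative to the surviving total only when nothing is removed;
    the filter is applied once against the original total.
    """
    config = config or RunConfig()
    if retained.empty:
        out = retained.copy()
        out.attrs["failed"] = True
        return out
    total = int(retained["reads"].sum())
    if total == 0:
        out = retained.iloc[0:0].copy()
        out.attrs["failed"] = True
        return out
    out = retained.loc[retained["reads"] / total >= config.abundance_threshold].copy()
    out.attrs["failed"] = False
    out.attrs["sample_total_reads"] = total
    return out


def classify_scat(
    sample_id: str,
    filtered: pd.DataFrame,
    config: RunConfig | None = None,
) -> ScatClassification:
    """Classify one scat by its predator and prey content.

    The predator is the configured canid taxon with the highest read share;
    its reads are removed from the prey list, as are configured contaminant
    taxa. A scat whose predator is the focal species and that retains at
    least one prey taxon enters the diet dataset.
    """
    config = config or RunConfig()
    if filtered.attrs.get("failed", False) or filtered.empty:
        return ScatClassification(sample_id, None, [], "failed")
    taxa = filtered.loc[~filtered["taxon"].isin(config.contaminant_taxa)]
    canids = taxa.loc[taxa["taxon"].isin(config.predator_taxa)]
    if canids.empty:
        return ScatClassification(sample_id, None, [], "non_target")
    predator = canids.loc[canids["reads"].idxmax(), "taxon"]
    prey_rows = taxa.loc[~taxa["taxon"].isin(config.predator_taxa)]
    prey = [
        TaxonCall(
            r["taxon"], "species", 100.0, int(r["reads"]),
            frozenset(r["replicates_detected"]),
        )
        for _, r in prey_rows.iterrows()
    ]
    if predator != config.focal_predator:
        return ScatClassification(sample_id, predator, prey, "non_target")
    if not prey:
        return ScatClassification(sample_id, predator, [], "predator_only")
    return ScatClassification(sample_id, predator, prey, "wolf_diet")


def classify_all(
    counts: pd.DataFrame, config: RunConfig | None = None
) -> list[ScatClassification]:
    """Run consensus -> abundance filter -> classification per sample.

    ``counts`` holds columns sample_id, replicate, taxon, count for every
    sample.
    """
    config = config or RunConfig()
    out = []
    for sample_id, sub in counts.groupby("sample_id", sort=True):
        retained = replicate_consensus(sub, config)
        filtered = abundance_filter(retained, config)
        out.append(classify_scat(str(sample_id), filtered, config))
    return out


def classifications_to_frame(classifications: Iterable[ScatClassification]) -> pd.DataFrame:
    """Tabulate classifications (one row per scat, prey as ';'-joined list)."""
    rows = [
        {
            "sample_id": c.sample_id,
            "status": c.status,
            "predator": c.predator if c.predator else "",
            "prey_taxa": ";".join(t.taxon_name for t in c.prey_taxa),
        }
        for c in classifications
    ]
    return pd.DataFrame(rows, columns=["sample_id", "status", "predator", "prey_taxa"])


def frame_to_classifications(df: pd.DataFrame) -> list[ScatClassification]:
    out = []
    for _, r in df.iterrows():
        prey = [
            TaxonCall(t, "species", 100.0, 0)
            for t in str(r["prey_taxa"]).split(";")
            if t and t != "nan"
        ]
        out.append(
            ScatClassification(
                str(r["sample_id"]), r["predator"] or None, prey, r["status"]
            )
        )
    return out
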