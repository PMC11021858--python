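"""Readers and writers for all on-disk formats.

Conventions: tab-separated UTF-8 tables with a header row; FASTA for
sequences (taxonomy encoded in the header as ``id|species|genus|family``);
CSV for the prey-category map, the SNP panel definition and pedigrees.
Every reader validates its domain and names the offending record on failure;
read-after-write is the identity for every format.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import RunConfig

_VALID_NUCLEOTIDES = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class ReferenceRecord:
    """One entry of the 12S reference database with its taxonomy."""

    sequence_id: str
    sequence: str
    species: str
    genus: str
    family: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"reference {self.sequence_id!r}: empty sequence")
        for fld in ("sequence_id", "species", "genus", "family"):
            if not getattr(self, fld):
                raise FormatError(f"reference {self.sequence_id!r}: empty {fld}")
        bad = set(self.sequence) - _VALID_NUCLEOTIDES
        if bad:
            raise FormatError(
                f"reference {self.sequence_id!r}: non-ACGTN characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class SampleSheetRow:
    """Metadata for one field-collected scat or tissue sample."""

    sample_id: str
    collection_date: pd.Timestamp
    study_area: str
    latitude: float | None = None
    longitude: float | None = None


def read_reference_fasta(path: str | Path) -> list[ReferenceRecord]:
    """Read a taxonomy-annotated reference FASTA.

    Headers must encode taxonomy as ``id|species|genus|family``. Sequences
    are upper-cased; non-ACGTN characters are rejected.
    """
    path = Path(path)
    records: list[ReferenceRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        parts = rec.description.split("|")
        if len(parts) != 4 or not all(p.strip() for p in parts):
            raise FormatError(
                f"{path}: record {i} header {rec.description!r} is not "
                "'id|species|genus|family'"
            )
        seq_id, species, genus, family = (p.strip() for p in parts)
        records.append(
            ReferenceRecord(seq_id, str(rec.seq).upper(), species, genus, family)
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    for rec in records:
        if rec.sequence_id in seen:
            raise FormatError(f"{path}: duplicate sequence_id {rec.sequence_id!r}")
        seen.add(rec.sequence_id)
    return records


def write_reference_fasta(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.sequence_id}|{r.species}|{r.genus}|{r.family}",
            description="",
        )
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


_REPLICATES = {1, 2, 3}


def read_replicate_counts(
    path: str | Path,
    key_column: str,
    count_columns: tuple[str, ...] = ("count",),
) -> pd.DataFrame:
    """Read a per-replicate count table keyed by (sample_id, replicate, key).

    ``key_column`` names the third key ("taxon" for metabarcoding tables,
    "locus_id" for allele-count tables); ``count_columns`` are validated as
    non-negative integers. Samples missing one or more of the three PCR
    replicates are kept but flagged in the ``incomplete`` attribute
    (``df.attrs["incomplete"]``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "replicate", key_column, *count_columns}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad_rep = df.loc[~df["replicate"].isin(_REPLICATES)]
    if not bad_rep.empty:
        row = bad_rep.iloc[0]
        raise FormatError(
            f"{path}: sample {row['sample_id']!r} has replicate "
            f"{row['replicate']!r} outside {{1, 2, 3}}"
        )
    for col in count_columns:
        if not pd.api.types.is_integer_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any() or (coerced % 1 != 0).any():
                raise FormatError(f"{path}: column {col!r} is not integral")
            df[col] = coerced.astype(int)
        negative = df.loc[df[col] < 0]
        if not negative.empty:
            row = negative.iloc[0]
            raise FormatError(
                f"{path}: sample {row['sample_id']!r} {key_column} "
                f"{row[key_column]!r} has negative {col} {row[col]}"
            )
    reps = df.groupby("sample_id")["replicate"].agg(lambda s: frozenset(s))
    df.attrs["incomplete"] = sorted(reps.index[reps.map(len) < 3])
    return df


def read_taxon_counts(path: str | Path) -> pd.DataFrame:
    """Per-replicate taxon read counts: sample_id, replicate, taxon, count."""
    return read_replicate_counts(path, key_column="taxon")


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Per-replicate allele read counts: sample_id, replicate, locus_id,
    allele1_count, allele2_count."""
    return read_replicate_counts(
        path, key_column="locus_id", count_columns=("allele1_count", "allele2_count")
    )


def read_sample_sheet(
    path: str | Path, study_areas: Iterable[str] | None = None
) -> list[SampleSheetRow]:
    """Read sample metadata (sample_id, collection_date, study_area[, lat, lon])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "collection_date", "study_area"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    allowed = set(study_areas) if study_areas is not None else None
    rows: list[SampleSheetRow] = []
    for _, r in df.iterrows():
        try:
            date = pd.Timestamp(r["collection_date"])
        except ValueError as exc:
            raise FormatError(
                f"{path}: sample {r['sample_id']!r} has unparseable date "
                f"{r['collection_date']!r}"
            ) from exc
        if pd.isna(date):
            raise FormatError(f"{path}: sample {r['sample_id']!r} has missing date")
        area = str(r["study_area"])
        if allowed is not None and area not in allowed:
            raise FormatError(
                f"{path}: sample {r['sample_id']!r} study_area {area!r} not in "
                f"{sorted(allowed)}"
            )
        lat = float(r["latitude"]) if "latitude" in df.columns and pd.notna(r.get("latitude")) else None
        lon = float(r["longitude"]) if "longitude" in df.columns and pd.notna(r.get("longitude")) else None
        rows.append(SampleSheetRow(str(r["sample_id"]), date, area, lat, lon))
    return rows


def write_sample_sheet(rows: Iterable[SampleSheetRow], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "collection_date": [r.collection_date.date().isoformat() for r in rows],
            "study_area": [r.study_area for r in rows],
            "latitude": [r.latitude for r in rows],
            "longitude": [r.longitude for r in rows],
        }
    ).to_csv(path, sep="\t", index=False)


def read_category_map(path: str | Path) -> dict[str, str]:
    """Read the prey-category map CSV (taxon,category) into a dict."""
    df = pd.read_csv(path)
    required = {"taxon", "category"}
    if missing := required - set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["taxon"].duplicated().any():
        dup = df.loc[df["taxon"].duplicated(), "taxon"].iloc[0]
        raise FormatError(f"{path}: taxon {dup!r} mapped twice")
    return dict(zip(df["taxon"].astype(str), df["category"].astype(str)))


def write_category_map(mapping: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"taxon": list(mapping), "category": list(mapping.values())}
    ).to_csv(path, index=False)


def read_genotype_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples x loci genotype matrix coded as copies of allele 1
    (0/1/2, blank = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = set(df.stack().dropna().unique())
    if not values <= {0, 1, 2, 0.0, 1.0, 2.0}:
        raise FormatError(f"{path}: genotype codes outside {{0, 1, 2, NA}}: {values}")
    return df.astype("float64")


def write_genotype_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.0f")


def write_report(results: dict[str, pd.DataFrame], path: str | Path,
                 config: RunConfig | None = None) -> None:
    """Write a machine-readable run report.

    ``results`` maps section names (e.g. ``wpoo``, ``overlap``, ``roster``,
    ``detection_history``, ``pedigree``) to tables. The report is a single
    JSON document with per-section records plus run provenance (config hash
    and seed), so two runs with identical config and seed are byte-identical.
    """
    doc: dict[str, Any] = {"sections": {}}
    for name, df in results.items():
        doc["sections"][name] = json.loads(df.to_json(orient="records"))
    if config is not None:
        doc["provenance"] = {"config_hash": config.config_hash(), "seed": config.seed}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
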