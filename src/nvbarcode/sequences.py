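"""Barcode sequence I/O, validation, filtering and per-sequence statistics.

Sequences are DNA barcodes (for fungi, typically the ITS region, 500-800 bp)
over the canonical alphabet {A, C, G, T}. Taxonomy metadata is a five-rank
label (class, order, family, genus, species) joined to FASTA records by id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

CANONICAL = frozenset("ACGT")
#: IUPAC ambiguity codes plus gap characters removed under "drop-ambiguous".
AMBIGUOUS = frozenset("NRYSWKMBDHV") | frozenset("-.")

RANKS = ("class_", "order", "family", "genus", "species")


@dataclass(frozen=True)
class TaxonomyLabel:
    """Five-rank taxonomy; any rank may be empty ("" = unknown)."""

    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def is_complete(self) -> bool:
        return all(getattr(self, r) for r in RANKS)

    def rank(self, name: str) -> str:
        """Label at ``name``, accepting both 'class' and 'class_'."""
        return getattr(self, "class_" if name in ("class", "class_") else name)


@dataclass(frozen=True)
class SequenceRecord:
    """One barcode sequence with id and optional taxonomy."""

    id: str
    seq: str
    taxonomy: TaxonomyLabel | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")


@dataclass(frozen=True)
class SeqStats:
    length: int
    gc_fraction: float


Policy = Literal["strict", "drop-ambiguous"]


def validate_sequence(raw: str, policy: Policy = "drop-ambiguous") -> str:
    """Canonicalize a raw sequence string to the {A,C,G,T} alphabet.

    Uppercases and maps U to T under both policies. ``strict`` raises on any
    other non-canonical character (naming its 1-based position);
    ``drop-ambiguous`` removes IUPAC ambiguity codes and gaps, renumbering
    positions over the retained characters.
    """
    if not raw:
        raise ValueError("empty sequence")
    s = raw.upper().replace("U", "T")
    if set(s) <= CANONICAL:
        return s
    if policy == "strict":
        for i, c in enumerate(s, start=1):
            if c not in CANONICAL:
                raise ValueError(
                    f"non-canonical character {c!r} at position {i} under strict policy"
                )
    kept = []
    dropped = 0
    for i, c in enumerate(raw.upper().replace("U", "T"), start=1):
        if c in CANONICAL:
            kept.append(c)
        elif c in AMBIGUOUS:
            dropped += 1
        else:
            raise ValueError(f"unrecognized character {c!r} at position {i}")
    if not kept:
        raise ValueError("no canonical characters remain after dropping ambiguity codes")
    if dropped:
        logger.debug("dropped %d ambiguous characters", dropped)
    return "".join(kept)


def read_fasta(
    path: str | Path,
    taxonomy: str | Path | None = None,
    policy: Policy = "drop-ambiguous",
) -> list[SequenceRecord]:
    """Read a FASTA file (and optional taxonomy TSV) into SequenceRecords.

    The header token before the first whitespace becomes the id; sequences are
    uppercased and canonicalized under ``policy``. Ids must be unique.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tax = read_taxonomy(taxonomy) if taxonomy is not None else {}
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        seq = validate_sequence(str(entry.seq), policy=policy)
        records.append(SequenceRecord(entry.id, seq, tax.get(entry.id)))
    if not records:
        raise ValueError(f"no FASTA entries in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyLabel]:
    """Read a taxonomy TSV with header ``id class order family genus species``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "class", "order", "family", "genus", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
    return {
        row["id"]: TaxonomyLabel(
            class_=row["class"], order=row["order"], family=row["family"],
            genus=row["genus"], species=row["species"],
        )
        for _, row in df.iterrows()
    }


def write_taxonomy(records: Iterable[SequenceRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        t = r.taxonomy or TaxonomyLabel()
        rows.append({"id": r.id, "class": t.class_, "order": t.order,
                     "family": t.family, "genus": t.genus, "species": t.species})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_dataset(
    records: list[SequenceRecord],
    require_full_taxonomy: bool = True,
    min_specimens_per_species: int = 1,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Filter records by taxonomy completeness and species specimen count.

    First drops records with incomplete (or absent) taxonomy when
    ``require_full_taxonomy`` is set, then drops every record of any species
    represented by fewer than ``min_specimens_per_species`` specimens.
    Returns the retained records and a removal log with columns (id, reason).
    """
    kept = list(records)
    log: list[dict[str, str]] = []
    if require_full_taxonomy:
        retained = []
        for r in kept:
            if r.taxonomy is not None and r.taxonomy.is_complete():
                retained.append(r)
            else:
                log.append({"id": r.id, "reason": "incomplete_taxonomy"})
        kept = retained
    if min_specimens_per_species > 1:
        counts: dict[str, int] = {}
        for r in kept:
            sp = r.taxonomy.species if r.taxonomy else ""
            counts[sp] = counts.get(sp, 0) + 1
        retained = []
        for r in kept:
            sp = r.taxonomy.species if r.taxonomy else ""
            if counts[sp] >= min_specimens_per_species:
                retained.append(r)
            else:
                log.append({"id": r.id, "reason": "species_below_min_specimens"})
        kept = retained
    if not kept:
        logger.warning("filter_dataset removed every record")
    return kept, pd.DataFrame(log, columns=["id", "reason"])


def seq_stats(rec: SequenceRecord) -> SeqStats:
    """Length (bp) and GC fraction of a validated sequence."""
    n = len(rec.seq)
    gc = sum(1 for c in rec.seq if c in "GC")
    return SeqStats(length=n, gc_fraction=gc / n)


def relabel(rec: SequenceRecord, taxonomy: TaxonomyLabel) -> SequenceRecord:
    return replace(rec, taxonomy=taxonomy)
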