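"""Domain types and file I/O for barcode datasets.

A *dataset* is an ordered collection of specimen records: one COI-5P
barcode sequence joined to its specimen metadata (species label, genus,
subfamily, BIN id, coordinates, collection site, and quality-control
flags).  Sequences are expected to be pre-aligned (or uniformly trimmed
to equal length); alignment itself is outside the scope of this package.

File formats:

* barcodes: plain FASTA (single-line or wrapped);
* metadata: UTF-8 tab-delimited with header
  ``specimen_id species genus subfamily bin_id latitude longitude site
  flags`` where ``flags`` is a semicolon-separated subset of
  ``{contaminant, misidentified, error}`` and missing values are ``.``
  or empty;
* partitions (specimen -> MOTU maps): tab-delimited with header
  ``specimen_id motu_id``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

VALID_FLAGS = frozenset({"contaminant", "misidentified", "error"})

METADATA_COLUMNS = [
    "specimen_id",
    "species",
    "genus",
    "subfamily",
    "bin_id",
    "latitude",
    "longitude",
    "site",
    "flags",
]

# full IUPAC nucleotide alphabet; anything outside ACGT is treated as
# missing by pairwise deletion downstream
_SEQ_ALPHABET = frozenset("ACGTNRYSWKMBDHV-?")


@dataclass(frozen=True)
class SpecimenRecord:
    """One barcode sequence with its labels, coordinates and QC state."""

    specimen_id: str
    sequence: str
    species: str = ""
    genus: str = ""
    subfamily: str = ""
    bin_id: str = ""
    latitude: float | None = None
    longitude: float | None = None
    site: str = ""
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValueError("specimen_id must be nonempty")
        if not self.sequence:
            raise ValueError(f"{self.specimen_id}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _SEQ_ALPHABET
        if bad:
            raise ValueError(
                f"{self.specimen_id}: invalid sequence characters {sorted(bad)}"
            )
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.specimen_id}: latitude {self.latitude} out of range")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"{self.specimen_id}: longitude {self.longitude} out of range")
        unknown = set(self.flags) - VALID_FLAGS
        if unknown:
            raise ValueError(f"{self.specimen_id}: unknown QC flags {sorted(unknown)}")

    @property
    def ungapped_length(self) -> int:
        """Number of non-gap characters (gap rule for the length filter)."""
        return len(self.sequence) - self.sequence.count("-")

    @property
    def has_coordinates(self) -> bool:
        return self.latitude is not None and self.longitude is not None


@dataclass
class Dataset:
    """Ordered collection of specimen records with unique ids."""

    records: list[SpecimenRecord]
    alignment_length: int | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.specimen_id in seen:
                raise ValueError(f"duplicate id: {rec.specimen_id}")
            seen.add(rec.specimen_id)
        if self.alignment_length is not None:
            for rec in self.records:
                if len(rec.sequence) != self.alignment_length:
                    raise ValueError(
                        f"{rec.specimen_id}: length {len(rec.sequence)} != "
                        f"alignment_length {self.alignment_length}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpecimenRecord]:
        return iter(self.records)

    def __getitem__(self, specimen_id: str) -> SpecimenRecord:
        for rec in self.records:
            if rec.specimen_id == specimen_id:
                return rec
        raise KeyError(specimen_id)

    @property
    def ids(self) -> list[str]:
        return [rec.specimen_id for rec in self.records]

    def to_metadata_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "specimen_id": rec.specimen_id,
                    "species": rec.species,
                    "genus": rec.genus,
                    "subfamily": rec.subfamily,
                    "bin_id": rec.bin_id,
                    "latitude": rec.latitude,
                    "longitude": rec.longitude,
                    "site": rec.site,
                    "flags": ";".join(sorted(rec.flags)),
                }
            )
        return pd.DataFrame(rows, columns=METADATA_COLUMNS)


@dataclass
class FilterReport:
    """Accounting of the record-level quality filter.

    Each input record is counted exactly once, by the first rule it
    fails, in the order short -> stop codon -> QC flag.
    """

    n_input: int
    n_kept: int
    n_removed_short: int
    n_removed_stop: int
    n_removed_flagged: int
    removed_ids: list[str]

    def __post_init__(self) -> None:
        total = (
            self.n_kept
            + self.n_removed_short
            + self.n_removed_stop
            + self.n_removed_flagged
        )
        if total != self.n_input:
            raise ValueError("FilterReport counts do not sum to n_input")


@dataclass
class Partition:
    """A total mapping of specimens to MOTU ids (one MOTU per specimen)."""

    assignment: dict[str, str]
    method_name: str = ""
    parameters: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, motu in self.assignment.items():
            if not sid or not str(motu):
                raise ValueError("empty specimen or MOTU id in partition")

    def __len__(self) -> int:
        return len(self.assignment)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.assignment == other.assignment

    @property
    def n_motus(self) -> int:
        return len(set(self.assignment.values()))

    def motus(self) -> dict[str, frozenset[str]]:
        """MOTU id -> specimen set."""
        out: dict[str, set[str]] = {}
        for sid, motu in self.assignment.items():
            out.setdefault(motu, set()).add(sid)
        return {m: frozenset(s) for m, s in out.items()}

    def sets(self) -> set[frozenset[str]]:
        return set(self.motus().values())

    def restrict(self, ids: Iterable[str]) -> "Partition":
        keep = set(ids)
        return Partition(
            {s: m for s, m in self.assignment.items() if s in keep},
            method_name=self.method_name,
            parameters=dict(self.parameters),
        )


# ---------------------------------------------------------------------------
# Readers / writers


def _parse_missing(value: object) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    text = str(value).strip()
    return "" if text == "." else text


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a specimen-metadata TSV, validating the header."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata TSV missing columns: {missing}")
    return df


def load_dataset(fasta_path: str | Path, metadata_path: str | Path) -> Dataset:
    """Join a FASTA file of barcodes to its metadata TSV.

    One record per FASTA entry, in FASTA order; metadata rows are matched
    on ``specimen_id`` and records lacking a metadata row get empty
    labels.  Duplicate FASTA ids are a hard error.
    """
    meta = read_metadata(metadata_path)
    meta_by_id: dict[str, dict] = {}
    for row in meta.to_dict("records"):
        sid = str(row["specimen_id"]).strip()
        if sid in meta_by_id:
            raise ValueError(f"duplicate id in metadata: {sid}")
        meta_by_id[sid] = row

    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        sid = entry.id
        if sid in seen:
            raise ValueError(f"duplicate id in FASTA: {sid}")
        seen.add(sid)
        row = meta_by_id.get(sid, {})
        flags_text = _parse_missing(row.get("flags", ""))
        flags = frozenset(f for f in flags_text.split(";") if f)
        lat_text = _parse_missing(row.get("latitude", ""))
        lon_text = _parse_missing(row.get("longitude", ""))
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                sequence=str(entry.seq),
                species=_parse_missing(row.get("species", "")),
                genus=_parse_missing(row.get("genus", "")),
                subfamily=_parse_missing(row.get("subfamily", "")),
                bin_id=_parse_missing(row.get("bin_id", "")),
                latitude=float(lat_text) if lat_text else None,
                longitude=float(lon_text) if lon_text else None,
                site=_parse_missing(row.get("site", "")),
                flags=flags,
            )
        )
    lengths = {len(r.sequence) for r in records}
    aln = lengths.pop() if len(lengths) == 1 else None
    return Dataset(records, alignment_length=aln)


def write_dataset(ds: Dataset, fasta_path: str | Path, metadata_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for rec in ds.records:
            fh.write(f">{rec.specimen_id}\n{rec.sequence}\n")
    df = ds.to_metadata_frame()
    df["latitude"] = df["latitude"].map(lambda v: "" if v is None or pd.isna(v) else f"{v:.6f}")
    df["longitude"] = df["longitude"].map(lambda v: "" if v is None or pd.isna(v) else f"{v:.6f}")
    df.to_csv(metadata_path, sep="\t", index=False)


def read_partition(tsv_path: str | Path) -> Partition:
    """Read a specimen -> MOTU table (columns ``specimen_id``, ``motu_id``).

    Lines starting with ``#`` (parameter echoes) are skipped.  A specimen
    listed twice is an error.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    for col in ("specimen_id", "motu_id"):
        if col not in df.columns:
            raise ValueError(f"partition TSV missing column: {col}")
    assignment: dict[str, str] = {}
    for sid, motu in zip(df["specimen_id"], df["motu_id"]):
        if sid in assignment:
            raise ValueError(f"specimen listed twice in partition: {sid}")
        assignment[sid] = motu
    return Partition(assignment, method_name=str(Path(tsv_path).stem))


def write_partition(p: Partition, tsv_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        if p.method_name or p.parameters:
            params = " ".join(f"{k}={v}" for k, v in sorted(p.parameters.items()))
            fh.write(f"# method={p.method_name} {params}".rstrip() + "\n")
        fh.write("specimen_id\tmotu_id\n")
        for sid in sorted(p.assignment):
            fh.write(f"{sid}\t{p.assignment[sid]}\n")


# ---------------------------------------------------------------------------
# Quality filters


def _has_stop_free_frame(sequence: str, translation_table: int) -> bool:
    """True if at least one forward reading frame has no internal stop.

    Barcode amplicons may start mid-codon, so all three forward frames
    are tried; codons containing ambiguous characters never count as
    stops.  The trailing partial codon is ignored.
    """
    stops = set(CodonTable.unambiguous_dna_by_id[translation_table].stop_codons)
    seq = sequence.replace("-", "").replace("?", "")
    for frame in range(3):
        sub = seq[frame:]
        n_codons = len(sub) // 3
        has_stop = False
        for i in range(n_codons):
            codon = sub[3 * i : 3 * i + 3]
            # exclude a terminal stop: only internal stops disqualify
            if codon in stops and i < n_codons - 1:
                has_stop = True
                break
        if not has_stop:
            return True
    return False


def filter_records(
    ds: Dataset, min_len: int = 600, translation_table: int = 5
) -> tuple[Dataset, FilterReport]:
    """Remove short, stop-codon-bearing and QC-flagged records.

    Rules are applied in order and each record is counted once by the
    first rule it fails: (1) ungapped length < ``min_len``; (2) internal
    stop codon in *all three* forward frames under the given
    mitochondrial code (default 5, invertebrate mitochondrial); (3) any
    QC flag set.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept: list[SpecimenRecord] = []
    removed_ids: list[str] = []
    n_short = n_stop = n_flagged = 0
    for rec in ds.records:
        if rec.ungapped_length < min_len:
            n_short += 1
            removed_ids.append(rec.specimen_id)
        elif not _has_stop_free_frame(rec.sequence, translation_table):
            n_stop += 1
            removed_ids.append(rec.specimen_id)
        elif rec.flags:
            n_flagged += 1
            removed_ids.append(rec.specimen_id)
        else:
            kept.append(rec)
    report = FilterReport(
        n_input=len(ds),
        n_kept=len(kept),
        n_removed_short=n_short,
        n_removed_stop=n_stop,
        n_removed_flagged=n_flagged,
        removed_ids=removed_ids,
    )
    return Dataset(kept, alignment_length=ds.alignment_length), report


def filter_ambiguous(ds: Dataset, max_n_fraction: float = 0.01) -> tuple[Dataset, list[str]]:
    """Optional filter dropping records whose N fraction exceeds a bound.

    Mirrors the barcode-compliance rule under which records with more
    than 1% ambiguous bases are excluded from cluster registration.
    Returns the filtered dataset and the dropped ids.
    """
    kept, dropped = [], []
    for rec in ds.records:
        n_frac = rec.sequence.count("N") / max(rec.ungapped_length, 1)
        (dropped if n_frac > max_n_fraction else kept).append(rec)
    return (
        Dataset(kept, alignment_length=ds.alignment_length),
        [r.specimen_id for r in dropped],
    )


def assign_interim_names(ds: Dataset) -> Dataset:
    """Name unidentified lineages '<genus-or-subfamily> sp. N' by BIN.

    Unidentified records (empty species) sharing a BIN get the same
    interim name; N counts up in order of first appearance of each BIN
    within each genus (falling back to subfamily when the genus is
    unknown).  Identified records are untouched.
    """
    problems = [
        r.specimen_id
        for r in ds.records
        if not r.species and (not r.bin_id or not (r.genus or r.subfamily))
    ]
    if problems:
        raise ValueError(
            "unidentified records need a BIN and a genus or subfamily: "
            + ", ".join(problems)
        )
    counters: dict[str, int] = {}
    names: dict[tuple[str, str], str] = {}
    new_records: list[SpecimenRecord] = []
    for rec in ds.records:
        if rec.species:
            new_records.append(rec)
            continue
        group = rec.genus or rec.subfamily
        key = (group, rec.bin_id)
        if key not in names:
            counters[group] = counters.get(group, 0) + 1
            names[key] = f"{group} sp. {counters[group]}"
        new_records.append(replace(rec, species=names[key]))
    return Dataset(new_records, alignment_length=ds.alignment_length)
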