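"""Reading, validating and writing multi-locus alignment data.

Input formats are pre-aligned per-locus FASTA files plus a delimited
strain-metadata table (strain id, group label, optional population and
WGS84 decimal-degree coordinates).  Loci are tagged ``hkg`` (chromosomal
housekeeping genes) or ``sym`` (accessory symbiotic genes); concatenates
are built per category over the strains shared by every member locus.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("groupsep")

#: nucleotide alphabet accepted in alignments: canonical bases, gap, and
#: the IUPAC ambiguity letters.
IUPAC_LETTERS = frozenset("ACGTUNRYSWKMBDHV-")

CATEGORIES = ("hkg", "sym")


class ValidationError(ValueError):
    """Raised when an input file violates an alignment/metadata invariant."""


@dataclass
class LocusAlignment:
    """One gene's aligned sequences keyed by strain id."""

    locus_name: str
    category: str
    sequences: dict[str, str]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if self.category not in ("hkg", "sym", "custom"):
            raise ValidationError(
                f"{self.locus_name}: unknown category {self.category!r}"
            )
        if len(self.sequences) < 2:
            raise ValidationError(
                f"{self.locus_name}: alignment needs at least 2 sequences"
            )
        lengths = {sid: len(s) for sid, s in self.sequences.items()}
        ref = next(iter(lengths.values()))
        ragged = [sid for sid, n in lengths.items() if n != ref]
        if ragged:
            raise ValidationError(
                f"{self.locus_name}: ragged alignment — record(s) "
                f"{', '.join(sorted(ragged))} differ in length"
            )
        for sid, seq in self.sequences.items():
            for pos, ch in enumerate(seq):
                if ch not in IUPAC_LETTERS:
                    raise ValidationError(
                        f"{self.locus_name}/{sid}: non-IUPAC character "
                        f"{ch!r} at column {pos}"
                    )
        self.length = ref

    @property
    def strain_ids(self) -> list[str]:
        return list(self.sequences)

    def subset(self, strain_ids: Iterable[str]) -> "LocusAlignment":
        ids = list(strain_ids)
        missing = [s for s in ids if s not in self.sequences]
        if missing:
            raise ValidationError(
                f"{self.locus_name}: strains not in alignment: {missing}"
            )
        return LocusAlignment(
            self.locus_name, self.category, {s: self.sequences[s] for s in ids}
        )


@dataclass
class StrainMetadata:
    strain_id: str
    group: str
    population: str | None = None
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise ValidationError(
                f"{self.strain_id}: latitude out of range: {self.latitude}"
            )
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise ValidationError(
                f"{self.strain_id}: longitude out of range: {self.longitude}"
            )


@dataclass
class ConcatenateAlignment:
    """Loci joined column-wise over their shared strains.

    ``partition_bounds`` records each member locus's half-open, 0-based
    column interval in the concatenate.
    """

    loci: list[str]
    category: str
    sequences: dict[str, str]
    partition_bounds: list[tuple[str, int, int]]

    @property
    def length(self) -> int:
        return self.partition_bounds[-1][2] if self.partition_bounds else 0

    @property
    def locus_name(self) -> str:
        # lets a concatenate stand wherever a LocusAlignment is accepted
        return f"concat_{self.category}"

    @property
    def strain_ids(self) -> list[str]:
        return list(self.sequences)


def read_locus_alignment(path: str | Path, locus_name: str, category: str) -> LocusAlignment:
    """Read one pre-aligned FASTA file.

    Record ids are taken as everything before the first whitespace;
    letters are upper-cased.  Raises :class:`ValidationError` on ragged
    alignments, duplicate ids or non-IUPAC characters.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        if sid in sequences:
            raise ValidationError(f"{locus_name}: duplicate strain id {sid!r}")
        sequences[sid] = str(rec.seq).upper()
    return LocusAlignment(locus_name, category, sequences)


def write_alignment(aln: LocusAlignment | ConcatenateAlignment, path: str | Path) -> None:
    """Write an alignment as FASTA (unwrapped lines, one per record)."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in aln.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(records)


def read_metadata(path: str | Path, delimiter: str | None = None) -> list[StrainMetadata]:
    """Read the strain metadata table (CSV/TSV, delimiter sniffed by default).

    Mandatory columns: ``strain_id``, ``group``.  Optional: ``population``,
    ``latitude``, ``longitude`` (decimal degrees).
    """
    df = pd.read_csv(path, sep=delimiter, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("strain_id", "group"):
        if col not in df.columns:
            raise ValidationError(f"missing column: {col}")
    out: list[StrainMetadata] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["strain_id"]).strip()
        if sid in seen:
            raise ValidationError(f"duplicate strain_id in metadata: {sid!r}")
        seen.add(sid)
        lat = row.get("latitude")
        lon = row.get("longitude")
        out.append(
            StrainMetadata(
                strain_id=sid,
                group=str(row["group"]).strip(),
                population=(
                    str(row["population"]).strip()
                    if "population" in df.columns and pd.notna(row.get("population"))
                    else None
                ),
                latitude=float(lat) if pd.notna(lat) else None,
                longitude=float(lon) if pd.notna(lon) else None,
            )
        )
    return out


def write_metadata(meta: Sequence[StrainMetadata], path: str | Path) -> None:
    pd.DataFrame(
        {
            "strain_id": [m.strain_id for m in meta],
            "group": [m.group for m in meta],
            "population": [m.population for m in meta],
            "latitude": [m.latitude for m in meta],
            "longitude": [m.longitude for m in meta],
        }
    ).to_csv(path, index=False)


def groups_from_metadata(meta: Sequence[StrainMetadata]) -> dict[str, list[str]]:
    """Map group label -> member strain ids, in metadata order."""
    groups: dict[str, list[str]] = {}
    for m in meta:
        groups.setdefault(m.group, []).append(m.strain_id)
    return groups


def concatenate(
    loci: Sequence[LocusAlignment], category: str = "custom"
) -> ConcatenateAlignment:
    """Join loci column-wise over the strains present in every locus.

    Strains missing from any member locus are dropped (with a warning)
    so every pairwise distance on the concatenate is defined.
    """
    if not loci:
        raise ValidationError("concatenate needs at least one locus")
    names = [l.locus_name for l in loci]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate locus names: {names}")
    shared = set(loci[0].sequences)
    union = set(loci[0].sequences)
    for l in loci[1:]:
        shared &= set(l.sequences)
        union |= set(l.sequences)
    if not shared:
        raise ValidationError("no shared strains across loci")
    dropped = sorted(union - shared)
    if dropped:
        logger.warning(
            "concatenate(%s): dropping strains missing from some loci: %s",
            ",".join(names), ", ".join(dropped),
        )
    # keep a deterministic, input-independent strain order
    order = sorted(shared)
    bounds: list[tuple[str, int, int]] = []
    start = 0
    for l in loci:
        bounds.append((l.locus_name, start, start + l.length))
        start += l.length
    sequences = {
        sid: "".join(l.sequences[sid] for l in loci) for sid in order
    }
    return ConcatenateAlignment(names, category, sequences, bounds)


def fasta_roundtrip_string(aln: LocusAlignment | ConcatenateAlignment) -> str:
    """Alignment serialized as FASTA text (used for determinism checks)."""
    buf = io.StringIO()
    for sid, seq in aln.sequences.items():
        buf.write(f">{sid}\n{seq}\n")
    return buf.getvalue()
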