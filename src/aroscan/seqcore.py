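"""Sequence and interval primitives shared by every scan.

The stickers-and-spacers view of a disordered protein region treats the
aromatic residues F, Y and W as "stickers" (interaction-prone units) and the
stretches of non-aromatic residues between consecutive stickers as "spacers".
Everything downstream — periodic-block calling, the omega dispersion score,
the K-S periodicity scan, mutant design — consumes the primitives defined
here: validated protein records, 1-based inclusive intervals, sticker
profiles, and composition tables.

Coordinate convention: all user-facing positions are 1-based inclusive
(residue numbering as printed in the literature). The BED export converts to
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Aromatic "sticker" residues.
AROMATICS: frozenset = frozenset("FYW")

#: Small inert residues used by default for the sticker-adjacency metric.
DEFAULT_INERT_SET: frozenset = frozenset("AGS")

#: Recognised interval annotation kinds.
INTERVAL_KINDS = ("IDR", "DOMAIN", "PLD", "BLOCK", "REGION", "AD")


class SequenceAlphabetError(ValueError):
    """A sequence contains a character outside the 20-letter alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """One canonical protein isoform: identifier plus amino-acid sequence.

    Parameters
    ----------
    id : str
        Whitespace-free identifier token.
    sequence : str
        Upper-case sequence over the 20 canonical amino acids. Ambiguity
        codes (B, J, O, U, X, Z) are rejected, never coerced: silent
        coercion would corrupt patterning statistics.
    source : str
        Free-text provenance tag (e.g. ``"synthetic"``, ``"uniprot"``).
    """

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"protein id must be a whitespace-free token, got {self.id!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        for i, ch in enumerate(self.sequence, start=1):
            if ch not in _AA_SET:
                raise SequenceAlphabetError(
                    f"record {self.id}: invalid residue {ch!r} at position {i} "
                    "(only the 20 canonical amino acids are accepted)"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """A closed residue interval on one protein, 1-based inclusive."""

    protein_id: str
    start: int
    end: int
    kind: str = "IDR"
    label: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}] on {self.protein_id}: "
                "need 1 <= start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def overlaps(a: Interval, b: Interval) -> bool:
    """True iff the two closed intervals share at least one residue.

    Overlap between annotation classes is defined as an overlap of at least
    one amino acid; this is the single overlap rule used package-wide.
    """
    if a.protein_id != b.protein_id:
        raise ValueError(
            f"cannot overlap intervals on different proteins: "
            f"{a.protein_id!r} vs {b.protein_id!r}"
        )
    return a.start <= b.end and b.start <= a.end


@dataclass(frozen=True)
class StickerProfile:
    """Ordered aromatic positions and derived spacers of one sequence span.

    ``positions`` are whole-protein 1-based indices of F/Y/W, strictly
    increasing. ``spacers[i]`` is the count of non-aromatic residues strictly
    between stickers i and i+1 (adjacent stickers give spacer 0). Terminal
    flanks before the first and after the last sticker are not spacers.
    """

    protein_id: str
    positions: tuple[int, ...]
    spacers: tuple[int, ...]
    n_aro: int
    length: int
    p_aro: float
    span_start: int = 1

    def __post_init__(self) -> None:
        assert len(self.spacers) == max(0, self.n_aro - 1)
        assert sum(self.spacers) + self.n_aro <= self.length


def find_stickers(record: ProteinRecord, span: Interval | None = None) -> StickerProfile:
    """Locate aromatic residues (F/Y/W) and compute inter-sticker spacers.

    When ``span`` is given only residues inside it are profiled, but sticker
    positions are reported in whole-protein coordinates.
    """
    if span is None:
        lo, hi = 1, len(record.sequence)
    else:
        if span.protein_id != record.id:
            raise ValueError(f"span protein {span.protein_id!r} != record {record.id!r}")
        if span.end > len(record.sequence):
            raise ValueError(
                f"span [{span.start},{span.end}] exceeds {record.id} length "
                f"{len(record.sequence)}"
            )
        lo, hi = span.start, span.end
    positions = tuple(
        i for i in range(lo, hi + 1) if record.sequence[i - 1] in AROMATICS
    )
    spacers = tuple(
        positions[i + 1] - positions[i] - 1 for i in range(len(positions) - 1)
    )
    length = hi - lo + 1
    n = len(positions)
    return StickerProfile(
        protein_id=record.id,
        positions=positions,
        spacers=spacers,
        n_aro=n,
        length=length,
        p_aro=n / length,
        span_start=lo,
    )


# ---------------------------------------------------------------------------
# Composition statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionTable:
    """Per-amino-acid frequency table, optionally with enrichment ratios.

    ``freqs`` sums to 1 over the 20 letters. ``enrichment[aa]`` is
    freq / background-freq; it is ``None`` (reported missing, never
    infinity) where the background frequency is zero.
    """

    freqs: Mapping[str, float]
    enrichment: Mapping[str, float | None] | None = None

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition frequencies sum to {total}, not 1")
        if any(v < 0 for v in self.freqs.values()):
            raise ValueError("negative frequency")

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "CompositionTable":
        total = float(sum(counts.values()))
        if total <= 0:
            raise ValueError("cannot build composition from zero counts")
        return cls(freqs={aa: counts.get(aa, 0) / total for aa in AMINO_ACIDS})

    @classmethod
    def from_records(cls, records: Iterable[ProteinRecord]) -> "CompositionTable":
        counts: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
        for rec in records:
            for ch in rec.sequence:
                counts[ch] += 1
        return cls.from_counts(counts)

    @classmethod
    def uniform(cls) -> "CompositionTable":
        return cls(freqs={aa: 1 / 20 for aa in AMINO_ACIDS})


def composition_enrichment(
    records: Iterable[ProteinRecord], background: CompositionTable
) -> CompositionTable:
    """Residue frequencies of ``records`` with enrichment vs a background.

    Enrichment is the observed frequency divided by the background frequency
    (e.g. the full-proteome composition). Where the background frequency is
    zero the ratio is undefined and reported as missing.
    """
    observed = CompositionTable.from_records(records)
    enrichment: dict[str, float | None] = {}
    for aa in AMINO_ACIDS:
        bg = background.freqs.get(aa, 0.0)
        obs = observed.freqs[aa]
        if bg > 0:
            enrichment[aa] = obs / bg
        else:
            enrichment[aa] = None if obs > 0 else 0.0
    return CompositionTable(freqs=observed.freqs, enrichment=enrichment)


@dataclass(frozen=True)
class FlankComposition:
    """Residue composition at fixed offsets around sticker positions.

    ``tables[k]`` is the composition at offset k (0 = the sticker itself);
    ``skipped[k]`` counts stickers whose offset-k flank fell outside the
    sequence and was excluded.
    """

    tables: Mapping[int, CompositionTable]
    skipped: Mapping[int, int]


def flank_composition(
    records: Sequence[ProteinRecord],
    profiles: Sequence[StickerProfile],
    offsets: Sequence[int] = (-2, -1, 0, 1, 2),
) -> FlankComposition:
    """Composition at positions -2..+2 around every sticker (0 = sticker)."""
    by_id = {r.id: r for r in records}
    counts: dict[int, dict[str, int]] = {k: {aa: 0 for aa in AMINO_ACIDS} for k in offsets}
    skipped = {k: 0 for k in offsets}
    for prof in profiles:
        rec = by_id[prof.protein_id]
        L = len(rec.sequence)
        for pos in prof.positions:
            for k in offsets:
                q = pos + k
                if 1 <= q <= L:
                    counts[k][rec.sequence[q - 1]] += 1
                else:
                    skipped[k] += 1
    tables = {
        k: CompositionTable.from_counts(c)
        for k, c in counts.items()
        if sum(c.values()) > 0
    }
    return FlankComposition(tables=tables, skipped=skipped)


def small_inert_adjacency(
    record: ProteinRecord,
    profile: StickerProfile,
    inert_set: frozenset | set = DEFAULT_INERT_SET,
) -> float:
    """Fraction of existing +/-1 sticker neighbours that are small inert residues.

    The set of "small inert" residues defaults to {A, G, S} and is
    configurable — the convention is not standardised in the field.
    """
    if profile.n_aro == 0:
        raise ValueError(
            f"{record.id}: small-inert adjacency undefined without stickers"
        )
    inert = frozenset(inert_set)
    L = len(record.sequence)
    n_neighbours = 0
    n_inert = 0
    for pos in profile.positions:
        for q in (pos - 1, pos + 1):
            if 1 <= q <= L:
                n_neighbours += 1
                if record.sequence[q - 1] in inert:
                    n_inert += 1
    return n_inert / n_neighbours


def aromatic_fraction(record: ProteinRecord, interval: Interval) -> float:
    """Fraction of F/Y/W residues inside a closed interval."""
    if interval.end > len(record.sequence):
        raise ValueError(
            f"interval [{interval.start},{interval.end}] exceeds {record.id} "
            f"length {len(record.sequence)}"
        )
    seg = record.sequence[interval.start - 1 : interval.end]
    return sum(1 for c in seg if c in AROMATICS) / len(seg)


def filter_aromatic_plds(
    records: Sequence[ProteinRecord],
    pld_intervals: Sequence[Interval],
    min_fraction: float = 0.10,
) -> list[Interval]:
    """Keep prion-like-domain intervals with aromatic content >= ``min_fraction``.

    Aromatic-rich PLDs are conventionally those with at least 10% aromatic
    content; the PLD intervals themselves come from an external predictor
    and are consumed here as annotations.
    """
    by_id = {r.id: r for r in records}
    kept = []
    for iv in pld_intervals:
        rec = by_id.get(iv.protein_id)
        if rec is None:
            logger.warning("PLD interval on unknown protein %s skipped", iv.protein_id)
            continue
        if aromatic_fraction(rec, iv) >= min_fraction:
            kept.append(iv)
    return kept


# ---------------------------------------------------------------------------
# I/O: FASTA and interval tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, source: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA into validated records, preserving file order."""
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            records.append(ProteinRecord(id=rec.id, sequence=seq, source=source))
        except SequenceAlphabetError as exc:
            raise SequenceAlphabetError(f"{path}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, sequence wrapped at 60 columns."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecs)


_INTERVAL_COLUMNS = ["protein_id", "start", "end", "kind", "label"]


def read_intervals(path: str | Path) -> list[Interval]:
    """Read a tab-separated interval table (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "label": str})
    missing = [c for c in _INTERVAL_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing interval columns {missing}")
    if "label" not in df.columns:
        df["label"] = ""
    df["label"] = df["label"].fillna("")
    return [
        Interval(
            protein_id=row.protein_id,
            start=int(row.start),
            end=int(row.end),
            kind=str(row.kind),
            label=str(row.label),
        )
        for row in df.itertuples(index=False)
    ]


def write_intervals(intervals: Iterable[Interval], path: str | Path) -> None:
    df = pd.DataFrame(
        [(iv.protein_id, iv.start, iv.end, iv.kind, iv.label) for iv in intervals],
        columns=_INTERVAL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Export intervals as BED (0-based half-open); conversion is bit-exact:
    chromStart = start - 1, chromEnd = end."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.label or iv.kind
            fh.write(f"{iv.protein_id}\t{iv.start - 1}\t{iv.end}\t{name}\n")


def read_bed(path: str | Path, kind: str = "REGION") -> list[Interval]:
    """Read a BED file back to 1-based inclusive intervals (inverse of write_bed)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            out.append(
                Interval(
                    protein_id=parts[0],
                    start=int(parts[1]) + 1,
                    end=int(parts[2]),
                    kind=kind,
                    label=parts[3] if len(parts) > 3 else "",
                )
            )
    return out
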