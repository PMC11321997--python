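"""Periodic aromatic block calling and the weighted periodicity score.

A periodic block is a maximal run of at least four aromatic stickers whose
internal spacers all fall within one spacer-length class. The three classes
(4-9, 10-20, 21-30 residues) come from stickers-and-spacers modelling of
associative biopolymers; spacers shorter than 4 or longer than 30 residues
always break runs. Blocks are called on the full protein, then intersected
with externally supplied IDR intervals, and the per-protein weighted count
of IDR-overlapping blocks (weights 1 / 1.1 / 1.2 by class) ranks proteins
by IDR periodicity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .seqcore import Interval, StickerProfile, overlaps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpacerClass:
    """One homogeneous spacer-length class with its score weight."""

    name: str
    lo: int
    hi: int
    weight: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"class {self.name}: lo {self.lo} > hi {self.hi}")

    def contains(self, spacer: int) -> bool:
        return self.lo <= spacer <= self.hi


#: Default spacer classes: short (4-9), medium (10-20), long (21-30), with
#: weights 1 / 1.1 / 1.2 — longer uniform spacing is less likely by chance.
DEFAULT_CLASSES: tuple[SpacerClass, ...] = (
    SpacerClass("A", 4, 9, 1.0),
    SpacerClass("B", 10, 20, 1.1),
    SpacerClass("C", 21, 30, 1.2),
)


def _check_disjoint(classes: Sequence[SpacerClass]) -> None:
    spans = sorted((c.lo, c.hi, c.name) for c in classes)
    for (lo1, hi1, n1), (lo2, hi2, n2) in zip(spans, spans[1:]):
        if lo2 <= hi1:
            raise ValueError(f"spacer classes {n1} and {n2} overlap")


@dataclass(frozen=True)
class PeriodicBlock:
    """A maximal homogeneous-spacer sticker run.

    ``start``/``end`` span the first to the last sticker of the run in
    whole-protein coordinates, so end - start + 1 = sum(spacers) + n_stickers.
    """

    protein_id: str
    spacer_class: str
    start: int
    end: int
    n_stickers: int
    spacer_list: tuple[int, ...]
    overlaps_idr: bool | None = None

    def __post_init__(self) -> None:
        assert self.n_stickers >= 4
        assert self.end - self.start + 1 == sum(self.spacer_list) + self.n_stickers

    @property
    def interval(self) -> Interval:
        return Interval(self.protein_id, self.start, self.end, kind="BLOCK",
                        label=self.spacer_class)


@dataclass(frozen=True)
class PeriodicityScore:
    """Weighted count of IDR-overlapping periodic blocks for one protein."""

    protein_id: str
    score: float
    n_blocks_by_class: tuple[int, ...]
    n_stickers: int = 0
    rank: int = 0


MIN_STICKERS_PER_BLOCK = 4


def detect_blocks(
    profile: StickerProfile,
    classes: Sequence[SpacerClass] = DEFAULT_CLASSES,
    min_stickers: int = MIN_STICKERS_PER_BLOCK,
) -> list[PeriodicBlock]:
    """Call periodic blocks from a whole-protein sticker profile.

    For each class independently, every maximal run of consecutive spacers
    all inside [lo, hi] with at least ``min_stickers - 1`` spacers is emitted
    as one block. Maximality means the run cannot be extended on either side
    by another in-class spacer; sub-runs are never emitted separately, so
    each class contributes at most one block per maximal run. A run mixing
    classes (e.g. spacers 5, 15, 5) yields no block. Blocks of different
    classes may overlap. Output sorted by (class, start).
    """
    _check_disjoint(classes)
    min_spacers = min_stickers - 1
    out: list[PeriodicBlock] = []
    spacers = profile.spacers
    for cls in classes:
        i = 0
        n = len(spacers)
        while i < n:
            if cls.contains(spacers[i]):
                j = i
                while j + 1 < n and cls.contains(spacers[j + 1]):
                    j += 1
                run_len = j - i + 1
                if run_len >= min_spacers:
                    first, last = profile.positions[i], profile.positions[j + 1]
                    out.append(
                        PeriodicBlock(
                            protein_id=profile.protein_id,
                            spacer_class=cls.name,
                            start=first,
                            end=last,
                            n_stickers=run_len + 1,
                            spacer_list=tuple(spacers[i : j + 1]),
                        )
                    )
                i = j + 1
            else:
                i += 1
    class_order = {c.name: k for k, c in enumerate(classes)}
    out.sort(key=lambda b: (class_order[b.spacer_class], b.start))
    return out


def filter_blocks_by_idr(
    blocks: Iterable[PeriodicBlock], idr_intervals: Iterable[Interval]
) -> list[PeriodicBlock]:
    """Annotate blocks with IDR overlap (>= 1 shared residue).

    Returns every input block with ``overlaps_idr`` set; downstream scoring
    uses only the overlapping ones. Proteins with no IDR annotation get all
    blocks flagged False (and a warning), since overlap is vacuously absent.
    """
    idr_by_protein: dict[str, list[Interval]] = {}
    for iv in idr_intervals:
        idr_by_protein.setdefault(iv.protein_id, []).append(iv)
    warned: set[str] = set()
    annotated = []
    for b in blocks:
        ivs = idr_by_protein.get(b.protein_id)
        if ivs is None:
            if b.protein_id not in warned:
                logger.warning(
                    "no IDR annotation for %s; its blocks cannot overlap an IDR",
                    b.protein_id,
                )
                warned.add(b.protein_id)
            annotated.append(replace(b, overlaps_idr=False))
        else:
            hit = any(overlaps(b.interval, iv) for iv in ivs)
            annotated.append(replace(b, overlaps_idr=hit))
    return annotated


def periodicity_score(
    idr_blocks: Sequence[PeriodicBlock],
    protein_id: str | None = None,
    classes: Sequence[SpacerClass] = DEFAULT_CLASSES,
) -> PeriodicityScore:
    """Weighted block count for one protein: score = 1.0*nA + 1.1*nB + 1.2*nC.

    ``idr_blocks`` must all belong to one protein and be IDR-overlapping.
    Pass ``protein_id`` explicitly to score a protein with zero blocks.
    """
    ids = {b.protein_id for b in idr_blocks}
    if len(ids) > 1:
        raise ValueError(f"blocks from multiple proteins: {sorted(ids)}")
    if protein_id is None:
        if not ids:
            raise ValueError("empty block list needs an explicit protein_id")
        protein_id = next(iter(ids))
    elif ids and next(iter(ids)) != protein_id:
        raise ValueError(f"blocks belong to {next(iter(ids))!r}, not {protein_id!r}")
    if any(b.overlaps_idr is False for b in idr_blocks):
        raise ValueError("periodicity_score expects only IDR-overlapping blocks")
    counts = tuple(
        sum(1 for b in idr_blocks if b.spacer_class == c.name) for c in classes
    )
    score = sum(c.weight * n for c, n in zip(classes, counts))
    return PeriodicityScore(
        protein_id=protein_id,
        score=round(score, 10),
        n_blocks_by_class=counts,
        n_stickers=sum(b.n_stickers for b in idr_blocks),
    )


def rank_proteins(scores: Iterable[PeriodicityScore]) -> list[PeriodicityScore]:
    """Order proteins by descending score; ties broken by total stickers in
    blocks (descending), then protein id (ascending). Ranks are 1-based."""
    ordered = sorted(
        scores, key=lambda s: (-s.score, -s.n_stickers, s.protein_id)
    )
    return [replace(s, rank=i) for i, s in enumerate(ordered, start=1)]


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def blocks_to_frame(blocks: Sequence[PeriodicBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                b.protein_id,
                b.spacer_class,
                b.start,
                b.end,
                b.n_stickers,
                ",".join(map(str, b.spacer_list)),
                b.overlaps_idr,
            )
            for b in blocks
        ],
        columns=[
            "protein_id", "class", "start", "end", "n_stickers", "spacers",
            "overlaps_idr",
        ],
    )


def scores_to_frame(scores: Sequence[PeriodicityScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.protein_id, s.score, *s.n_blocks_by_class, s.rank)
            for s in scores
        ],
        columns=["protein_id", "score", "nA", "nB", "nC", "rank"],
    )


def write_blocks(blocks: Sequence[PeriodicBlock], path: str | Path) -> None:
    blocks_to_frame(blocks).to_csv(path, sep="\t", index=False)


def write_scores(scores: Sequence[PeriodicityScore], path: str | Path) -> None:
    scores_to_frame(scores).to_csv(path, sep="\t", index=False)
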