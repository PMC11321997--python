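"""Designers for aromatic-patterning mutants of disordered regions.

Each designer takes a wild-type protein, a region interval to operate in,
and returns a variant with a machine-readable edit log. All designs are
substitutions or permutations confined to the region — never indels — so
the coordinates of flanking domains (e.g. a DNA-binding domain) are
preserved. The classes:

- ``aro_lite``      remove aromatics (replace with A, G or S);
- ``aro_perfect``   redistribute the native aromatics uniformly;
- ``aro_perfect_is``place aromatics at an exact inter-sticker spacing k,
                    topping up with tyrosines or trimming surplus;
- ``aro_plus``      split spacers longer than a cutoff by substituting in
                    tyrosines;
- ``shift_pattern`` translate every sticker by a fixed offset;
- ``scramble``      redraw sticker positions uniformly at random (seeded);
- ``tile``          cut the region into fixed-length overlapping tiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .omega import OmegaResult, binarize, omega_aro
from .seqcore import AROMATICS, Interval, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantRecord:
    """A designed variant: full-length sequence plus its edit log.

    ``edits`` are (position, from_residue, to_residue) in whole-protein
    1-based coordinates; applying them to the parent reproduces ``sequence``
    exactly. ``params`` records the designer's parameters (including the
    seed for stochastic designers). Omega summaries are attached on demand
    by :func:`annotate_omega`; they stay ``None`` until then.
    """

    parent_id: str
    variant_name: str
    sequence: str
    region: Interval
    edits: tuple[tuple[int, str, str], ...]
    params: dict
    omega_before: OmegaResult | None = None
    omega_after: OmegaResult | None = None


def apply_edits(parent_sequence: str, edits: Sequence[tuple[int, str, str]]) -> str:
    """Apply an edit log to a parent sequence (round-trip check helper)."""
    chars = list(parent_sequence)
    for pos, frm, to in edits:
        if chars[pos - 1] != frm:
            raise ValueError(
                f"edit log inconsistent at {pos}: parent has {chars[pos - 1]}, log says {frm}"
            )
        chars[pos - 1] = to
    return "".join(chars)


def _diff_edits(parent: str, variant: str) -> tuple[tuple[int, str, str], ...]:
    assert len(parent) == len(variant)
    return tuple(
        (i + 1, a, b) for i, (a, b) in enumerate(zip(parent, variant)) if a != b
    )


def _check_region(parent: ProteinRecord, region: Interval) -> None:
    if region.protein_id != parent.id:
        raise ValueError(f"region protein {region.protein_id!r} != parent {parent.id!r}")
    if region.end > len(parent.sequence):
        raise ValueError(
            f"region [{region.start},{region.end}] exceeds {parent.id} "
            f"length {len(parent.sequence)}"
        )


def _build(
    parent: ProteinRecord,
    region: Interval,
    new_region_seq: str,
    name: str,
    params: dict,
) -> VariantRecord:
    full = (
        parent.sequence[: region.start - 1]
        + new_region_seq
        + parent.sequence[region.end :]
    )
    assert len(full) == len(parent.sequence)
    return VariantRecord(
        parent_id=parent.id,
        variant_name=name,
        sequence=full,
        region=region,
        edits=_diff_edits(parent.sequence, full),
        params=params,
    )


def annotate_omega(
    variant: VariantRecord,
    parent: ProteinRecord,
    n_shuffles: int = 1000,
    seed: int = 0,
    **omega_kwargs,
) -> VariantRecord:
    """Attach before/after omega summaries over the design region.

    Regions failing the omega preconditions (e.g. an AroLITE variant with
    no aromatics left) get ``None`` with a note in ``params`` rather than
    an error, since "no longer scoreable" is an expected design outcome.
    """
    results: dict[str, OmegaResult | None] = {}
    notes = dict(variant.params)
    for key, seq in (("before", parent.sequence), ("after", variant.sequence)):
        mask = binarize(seq, variant.region)
        try:
            results[key] = omega_aro(
                mask, n_shuffles=n_shuffles, seed=seed,
                protein_id=variant.parent_id, span=variant.region, **omega_kwargs,
            )
        except ValueError as exc:
            results[key] = None
            notes[f"omega_{key}_undefined"] = str(exc)
    return replace(
        variant, params=notes,
        omega_before=results["before"], omega_after=results["after"],
    )


# ---------------------------------------------------------------------------
# Designers
# ---------------------------------------------------------------------------

def aro_lite(
    parent: ProteinRecord, region: Interval, replacement: str = "A"
) -> VariantRecord:
    """Replace every aromatic residue in the region with A, G or S."""
    _check_region(parent, region)
    if replacement not in {"A", "G", "S"}:
        raise ValueError(f"AroLITE replacement must be A, G or S, got {replacement!r}")
    seg = parent.sequence[region.start - 1 : region.end]
    new = "".join(replacement if c in AROMATICS else c for c in seg)
    if new == seg:
        logger.warning(
            "%s [%d,%d]: no aromatics in region, AroLITE is the identity",
            parent.id, region.start, region.end,
        )
    return _build(
        parent, region, new, f"AroLITE-{replacement}",
        {"designer": "aro_lite", "replacement": replacement},
    )


def _uniform_targets(length: int, n: int) -> list[int]:
    """Region-local target positions t_i = round((i - 0.5) * L / n), with
    collisions resolved by shifting right to the next free slot."""
    taken: set[int] = set()
    targets = []
    for i in range(1, n + 1):
        t = math.floor((i - 0.5) * length / n + 0.5)  # round half up, not to even
        t = max(1, min(length, t))
        while t in taken:
            t += 1
        if t > length:
            raise ValueError(f"cannot place {n} stickers uniformly in length {length}")
        taken.add(t)
        targets.append(t)
    return targets


def _rebuild_region(seg: str, sticker_letters: Sequence[str], targets: Sequence[int]) -> str:
    """Place sticker letters at target positions (region-local, 1-based);
    non-aromatic residues of ``seg`` fill the remaining positions in order."""
    L = len(seg)
    non_aro = [c for c in seg if c not in AROMATICS]
    out = [""] * L
    for letter, t in zip(sticker_letters, targets):
        out[t - 1] = letter
    it = iter(non_aro)
    for i in range(L):
        if out[i] == "":
            out[i] = next(it)
    return "".join(out)


def aro_perfect(parent: ProteinRecord, region: Interval) -> VariantRecord:
    """Disperse the native aromatics uniformly across the region.

    The region's residue multiset is exactly conserved: stickers move to
    evenly spaced target positions (keeping their N-to-C order) and the
    displaced non-aromatic residues fill the vacated positions preserving
    their relative order. Consecutive output spacers differ by at most 1.
    """
    _check_region(parent, region)
    seg = parent.sequence[region.start - 1 : region.end]
    letters = [c for c in seg if c in AROMATICS]
    n = len(letters)
    if n < 2:
        raise ValueError(
            f"AroPERFECT needs at least 2 aromatics in region, found {n}"
        )
    targets = _uniform_targets(len(seg), n)
    new = _rebuild_region(seg, letters, targets)
    return _build(parent, region, new, "AroPERFECT", {"designer": "aro_perfect", "n_aro": n})


def is_slots(region_length: int, k: int) -> list[int]:
    """Region-local sticker slots for exact spacing k: first slot at
    ceil((k+1)/2), then every k+1 residues."""
    first = math.ceil((k + 1) / 2)
    return list(range(first, region_length + 1, k + 1))


def aro_perfect_is(
    parent: ProteinRecord,
    region: Interval,
    k: int,
    fill: str = "Y",
    surplus: str = "A",
) -> VariantRecord:
    """Place aromatics at exactly k non-aromatic residues apart (IS-k).

    Slots sit at region-local positions ceil((k+1)/2), then every k+1
    residues. Native aromatics fill the slots in N-to-C order; if there are
    more slots than natives the remainder are filled with ``fill``
    (tyrosine); native aromatics in excess of the slots are converted to
    ``surplus`` (alanine) and logged. Length is conserved throughout.
    """
    _check_region(parent, region)
    if k < 1:
        raise ValueError(f"IS spacing k must be >= 1, got {k}")
    seg = parent.sequence[region.start - 1 : region.end]
    L = len(seg)
    if L < k + 1:
        raise ValueError(f"region length {L} < k + 1 = {k + 1}")
    slots = is_slots(L, k)
    if not slots:
        raise ValueError(f"no sticker slots fit in region of length {L} at k={k}")
    natives = [c for c in seg if c in AROMATICS]
    n, m = len(natives), len(slots)
    kept = natives[: min(n, m)]
    # fill pool: region residues with kept natives removed and surplus
    # natives converted in place, preserving relative order
    pool: list[str] = []
    consumed = 0
    for c in seg:
        if c in AROMATICS:
            if consumed < len(kept):
                consumed += 1      # this native moves to a slot
            else:
                pool.append(surplus)
        else:
            pool.append(c)
    letters = kept + [fill] * (m - len(kept))
    out = [""] * L
    for letter, t in zip(letters, slots):
        out[t - 1] = letter
    it = iter(pool)
    for i in range(L):
        if out[i] == "":
            out[i] = next(it)
    n_surplus = max(0, n - m)
    if n_surplus:
        logger.warning(
            "%s IS%d: %d native aromatics exceed the %d slots and were "
            "replaced with %s", parent.id, k, n_surplus, m, surplus,
        )
    return _build(
        parent, region, "".join(out), f"AroPERFECT-IS{k}",
        {"designer": "aro_perfect_is", "k": k, "fill": fill,
         "surplus": surplus, "n_native": n, "n_slots": m,
         "n_fill": max(0, m - n), "n_surplus": n_surplus},
    )


def _split_points(span_start: int, span_len: int, m: int) -> list[int]:
    """Positions (region-local) of m new stickers splitting a spacer of
    ``span_len`` residues starting at ``span_start`` into m+1 near-equal
    sub-spacers, remainders given to the leftmost sub-spacers."""
    q, r = divmod(span_len - m, m + 1)
    points = []
    cursor = span_start - 1
    for j in range(m):
        gap = q + (1 if j < r else 0)
        cursor += gap + 1
        points.append(cursor)
    return points


def aro_plus(
    parent: ProteinRecord,
    region: Interval,
    max_spacer: int = 15,
    max_subs: int | None = None,
) -> VariantRecord:
    """Substitute tyrosines into long spacers to raise periodicity.

    Every spacer longer than ``max_spacer`` (terminal flanks count as
    spacers bounded by the region edges, and an aromatic-free region is one
    such flank) is subdivided by substituting m = ceil((s+1)/(max+1)) - 1
    interior non-aromatic residues with Y — the fewest insertions that bring
    every sub-spacer to at most ``max_spacer``, placed to split near-evenly
    (left-biased on remainders). Processing runs N to C and stops after
    ``max_subs`` substitutions. Native stickers are never touched.
    """
    _check_region(parent, region)
    seg = list(parent.sequence[region.start - 1 : region.end])
    L = len(seg)
    aro_local = [i + 1 for i, c in enumerate(seg) if c in AROMATICS]
    # spacer spans: (start_local, length) of each non-aromatic stretch,
    # including terminal flanks bounded by the region edges
    bounds = [0] + aro_local + [L + 1]
    n_subs = 0
    for a, b in zip(bounds, bounds[1:]):
        s = b - a - 1
        if s <= max_spacer:
            continue
        m = math.ceil((s + 1) / (max_spacer + 1)) - 1
        for pos in _split_points(a + 1, s, m):
            if max_subs is not None and n_subs >= max_subs:
                break
            assert seg[pos - 1] not in AROMATICS
            seg[pos - 1] = "Y"
            n_subs += 1
    return _build(
        parent, region, "".join(seg), "AroPLUS",
        {"designer": "aro_plus", "max_spacer": max_spacer,
         "max_subs": max_subs, "n_subs": n_subs},
    )


def shift_pattern(
    parent: ProteinRecord, region: Interval, offset: int
) -> VariantRecord:
    """Translate every sticker in the region by ``offset`` residues.

    Each sticker swaps residues with the occupant of its target position,
    processed N-to-C for shifts toward the N terminus and C-to-N for shifts
    toward the C terminus, so swaps never cascade. Composition is conserved.
    Targets falling outside the region raise with the offending stickers.
    """
    _check_region(parent, region)
    seg = list(parent.sequence[region.start - 1 : region.end])
    L = len(seg)
    stickers = [i for i in range(1, L + 1) if seg[i - 1] in AROMATICS]
    bad = [s for s in stickers if not (1 <= s + offset <= L)]
    if bad:
        raise ValueError(
            f"shift by {offset} pushes stickers at region positions {bad} "
            f"outside the region [1,{L}]"
        )
    order = stickers if offset <= 0 else list(reversed(stickers))
    for s in order:
        t = s + offset
        if seg[t - 1] in AROMATICS and t != s:
            raise ValueError(
                f"shift by {offset} collides: target {t} of sticker {s} is aromatic"
            )
        seg[s - 1], seg[t - 1] = seg[t - 1], seg[s - 1]
    name = f"SHIFT{offset:+d}" if offset else "SHIFT+0"
    return _build(parent, region, "".join(seg), name,
                  {"designer": "shift_pattern", "offset": offset})


def scramble(parent: ProteinRecord, region: Interval, seed: int) -> VariantRecord:
    """Redraw sticker positions uniformly at random within the region.

    All C(L, n) position sets are equally likely (seeded). Sticker letter
    identities keep their N-to-C order and the non-aromatic residues fill
    the remaining positions preserving their order, so the region's residue
    multiset is conserved.
    """
    _check_region(parent, region)
    seg = parent.sequence[region.start - 1 : region.end]
    letters = [c for c in seg if c in AROMATICS]
    n = len(letters)
    if n < 1:
        raise ValueError("scramble needs at least one sticker in the region")
    rng = np.random.default_rng(seed)
    targets = sorted(int(x) + 1 for x in rng.choice(len(seg), size=n, replace=False))
    new = _rebuild_region(seg, letters, targets)
    return _build(parent, region, new, "AroSCRAMBLED",
                  {"designer": "scramble", "seed": seed})


def tile(
    parent: ProteinRecord,
    region: Interval,
    tile_len: int = 40,
    overlap: int = 20,
) -> list[VariantRecord]:
    """Cut the region into fixed-length tiles with fixed overlap.

    Tiles start at region-local positions 1, 1 + step, ... with
    step = tile_len - overlap, as long as the tile fits; an incomplete tail
    is dropped with a warning. Tile variants carry the tile subsequence and
    an empty edit log (extraction, not substitution).
    """
    _check_region(parent, region)
    if not (0 <= overlap < tile_len):
        raise ValueError(f"need 0 <= overlap < tile_len, got {overlap}/{tile_len}")
    L = region.length
    if L < tile_len:
        raise ValueError(f"region length {L} < tile length {tile_len}")
    step = tile_len - overlap
    out = []
    start = 1
    idx = 1
    while start + tile_len - 1 <= L:
        g_start = region.start + start - 1
        g_end = g_start + tile_len - 1
        out.append(
            VariantRecord(
                parent_id=parent.id,
                variant_name=f"TILE-{idx:02d}",
                sequence=parent.sequence[g_start - 1 : g_end],
                region=Interval(parent.id, g_start, g_end, kind="REGION",
                                label=f"tile{idx}"),
                edits=(),
                params={"designer": "tile", "tile_len": tile_len,
                        "overlap": overlap},
            )
        )
        start += step
        idx += 1
    tail = L - (start - step + tile_len - 1)
    if tail > 0:
        logger.warning(
            "%s [%d,%d]: %d-residue tail dropped (shorter than one tile step)",
            parent.id, region.start, region.end, tail,
        )
    return out


def edits_to_rows(variant: VariantRecord) -> list[tuple[str, int, str, str]]:
    """Edit-log rows for the ``variant  position  from  to`` TSV."""
    return [(variant.variant_name, pos, frm, to) for pos, frm, to in variant.edits]
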