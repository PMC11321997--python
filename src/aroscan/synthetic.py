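"""Seeded generators for synthetic proteomes with known patterning.

The generator emulates the statistical structure the analyses assume, with
ground-truth labels for recovery tests:

- ``bernoulli(p)`` — each position is aromatic independently with
  probability p, so spacers are geometric on {0, 1, 2, ...}: this realises
  the Poisson-process null of the K-S scan.
- ``fixed(k, jitter)`` — stickers at exact spacing k (optionally jittered),
  the idealised periodic signal.
- ``clustered(n_clusters)`` — stickers packed into a few contiguous runs,
  the segregated extreme that drives omega toward 1.

Non-sticker residues are drawn i.i.d. from a disorder-like background that
is serine/glycine/proline-rich, charge-depleted and aromatic-free. All
output is bit-reproducible under a fixed seed, which is recorded in every
file header.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seqcore import Interval, ProteinRecord, write_fasta, write_intervals

#: Disorder-like background over non-aromatic residues: rich in G/S/P/Q/N/A,
#: depleted of charged and hydrophobic residues, zero aromatics. Documented
#: package constants, not measured values.
DEFAULT_BACKGROUND: dict[str, float] = {
    "G": 0.15, "S": 0.15, "P": 0.12, "Q": 0.10, "N": 0.08, "A": 0.10,
    "T": 0.07, "H": 0.03, "M": 0.02, "L": 0.04, "V": 0.03, "I": 0.02,
    "C": 0.01, "K": 0.02, "R": 0.02, "D": 0.02, "E": 0.02,
}

#: Sticker letter weights; F and Y dominate aromatic content in disordered
#: regions, W is rare.
DEFAULT_ARO_WEIGHTS: dict[str, float] = {"F": 0.40, "Y": 0.45, "W": 0.15}


@dataclass(frozen=True)
class BernoulliStickers:
    """Independent aromatic occurrence at rate p (geometric spacers)."""
    p: float = 0.08
    label: str = "null"

    def __post_init__(self):
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"bernoulli p must be in (0,1), got {self.p}")


@dataclass(frozen=True)
class FixedStickers:
    """Exact spacing k between consecutive stickers, +/- uniform jitter <= j."""
    k: int = 10
    jitter: int = 0
    n_stickers: int = 20
    label: str = "periodic"

    def __post_init__(self):
        if self.k < 1 or self.jitter < 0 or self.jitter > self.k - 1:
            raise ValueError(f"invalid fixed-spacing model k={self.k} jitter={self.jitter}")
        if self.n_stickers < 2:
            raise ValueError("fixed-spacing model needs >= 2 stickers")


@dataclass(frozen=True)
class ClusteredStickers:
    """Stickers packed into contiguous runs (segregated extreme)."""
    n_stickers: int = 16
    n_clusters: int = 2
    terminal: bool = False
    label: str = "clustered"

    def __post_init__(self):
        if self.n_clusters < 1 or self.n_stickers < self.n_clusters:
            raise ValueError("need n_stickers >= n_clusters >= 1")


StickerModel = BernoulliStickers | FixedStickers | ClusteredStickers


@dataclass(frozen=True)
class SyntheticConfig:
    """One cohort of synthetic proteins sharing a sticker model.

    ``length`` is either a fixed residue count or an inclusive (lo, hi)
    range sampled uniformly. ``idr_covers_stickers`` controls whether the
    emitted IDR interval covers the sticker-bearing span (positives) or
    deliberately excludes it (negative controls for the IDR-overlap logic).
    """

    n_proteins: int = 200
    length: int | tuple[int, int] = 400
    model: StickerModel = field(default_factory=BernoulliStickers)
    background: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    aro_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ARO_WEIGHTS))
    tf_fraction: float = 0.3
    idr_covers_stickers: bool = True
    id_prefix: str = "syn"
    seed: int = 0

    def __post_init__(self):
        for name, table in (("background", self.background), ("aro_weights", self.aro_weights)):
            total = sum(table.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name} weights sum to {total}, not 1")
        if any(aa in "FYW" for aa in self.background):
            raise ValueError("background composition must be aromatic-free")
        if not (0.0 <= self.tf_fraction <= 1.0):
            raise ValueError("tf_fraction must be in [0,1]")


def _sample_length(cfg: SyntheticConfig, rng: np.random.Generator) -> int:
    if isinstance(cfg.length, int):
        return cfg.length
    lo, hi = cfg.length
    return int(rng.integers(lo, hi + 1))


def _sticker_positions(model: StickerModel, L: int, rng: np.random.Generator) -> np.ndarray:
    """0-based sticker positions for one protein under the given model."""
    if isinstance(model, BernoulliStickers):
        return np.flatnonzero(rng.random(L) < model.p)
    if isinstance(model, FixedStickers):
        n, k, j = model.n_stickers, model.k, model.jitter
        max_span = (n - 1) * (k + j + 1) + 1
        if max_span > L:
            raise ValueError(
                f"fixed spacing k={k} jitter={j} with {n} stickers needs up to "
                f"{max_span} residues, protein has {L}"
            )
        while True:
            gaps = (
                k + rng.integers(-j, j + 1, size=n - 1) if j > 0
                else np.full(n - 1, k)
            )
            span = int(gaps.sum()) + n
            if span <= L:
                break
        start = int(rng.integers(0, L - span + 1))
        pos = np.empty(n, dtype=np.int64)
        pos[0] = start
        pos[1:] = start + np.cumsum(gaps + 1)
        return pos
    if isinstance(model, ClusteredStickers):
        sizes = np.full(model.n_clusters, model.n_stickers // model.n_clusters)
        sizes[: model.n_stickers % model.n_clusters] += 1
        gap_budget = L - model.n_stickers
        if gap_budget < model.n_clusters - 1:
            raise ValueError("protein too short for the requested clusters")
        positions = []
        if model.terminal and model.n_clusters == 1:
            starts = [0]
        else:
            cuts = np.sort(rng.choice(gap_budget + 1, size=model.n_clusters, replace=False))
            starts = [int(c + sizes[:i].sum()) for i, c in enumerate(cuts)]
        for st, sz in zip(starts, sizes):
            positions.extend(range(st, st + int(sz)))
        return np.array(sorted(positions), dtype=np.int64)
    raise TypeError(f"unknown sticker model {model!r}")


def gen_sequence(
    cfg: SyntheticConfig, rng: np.random.Generator, index: int = 0
) -> tuple[ProteinRecord, dict]:
    """Generate one protein under the config's sticker model, with truth."""
    L = _sample_length(cfg, rng)
    bg_letters = np.array(sorted(cfg.background))
    bg_probs = np.array([cfg.background[a] for a in bg_letters])
    aro_letters = np.array(sorted(cfg.aro_weights))
    aro_probs = np.array([cfg.aro_weights[a] for a in aro_letters])

    chars = rng.choice(bg_letters, size=L, p=bg_probs)
    pos = _sticker_positions(cfg.model, L, rng)
    if pos.size:
        chars[pos] = rng.choice(aro_letters, size=pos.size, p=aro_probs)
    record = ProteinRecord(
        id=f"{cfg.id_prefix}{index:04d}", sequence="".join(chars), source="synthetic"
    )
    truth = {
        "protein_id": record.id,
        "model": type(cfg.model).__name__,
        "label": cfg.model.label,
        "params": ";".join(
            f"{k}={v}" for k, v in sorted(dataclasses.asdict(cfg.model).items())
            if k != "label"
        ),
        "length": L,
        "n_stickers": int(pos.size),
        "sticker_start": int(pos[0]) + 1 if pos.size else 0,
        "sticker_end": int(pos[-1]) + 1 if pos.size else 0,
    }
    return record, truth


def _idr_interval(cfg: SyntheticConfig, truth: dict, rng: np.random.Generator) -> Interval | None:
    """IDR annotation: covers the sticker span (positives) or excludes it."""
    L, s, e = truth["length"], truth["sticker_start"], truth["sticker_end"]
    pid = truth["protein_id"]
    if truth["n_stickers"] == 0 or not cfg.idr_covers_stickers:
        # a disordered stretch away from the stickers (or anywhere if none)
        if s > 40:
            return Interval(pid, 1, max(1, s - 1), kind="IDR", label="synthetic")
        if L - e >= 40:
            return Interval(pid, min(L, e + 1), L, kind="IDR", label="synthetic")
        return None
    lo = max(1, s - int(rng.integers(0, 11)))
    hi = min(L, e + int(rng.integers(0, 11)))
    return Interval(pid, lo, hi, kind="IDR", label="synthetic")


@dataclass(frozen=True)
class SyntheticCohort:
    """In-memory result of proteome generation, with ground truth."""

    records: list[ProteinRecord]
    idr_intervals: list[Interval]
    tf_ids: list[str]
    truth: pd.DataFrame
    seed: int


def gen_cohort(configs: Sequence[SyntheticConfig], seed: int = 0) -> SyntheticCohort:
    """Generate a proteome from one or more cohort configs.

    Each config contributes ``n_proteins`` records; per-config generators
    are spawned deterministically from the master seed, so adding a cohort
    never perturbs the previous ones.
    """
    records: list[ProteinRecord] = []
    intervals: list[Interval] = []
    truth_rows: list[dict] = []
    tf_ids: list[str] = []
    for c_idx, cfg in enumerate(configs):
        rng = np.random.default_rng([seed, cfg.seed, c_idx])
        for i in range(cfg.n_proteins):
            rec, truth = gen_sequence(
                dataclasses.replace(cfg, id_prefix=f"{cfg.id_prefix}{c_idx}_"),
                rng, index=i,
            )
            records.append(rec)
            truth["is_tf"] = bool(rng.random() < cfg.tf_fraction)
            truth_rows.append(truth)
            if truth["is_tf"]:
                tf_ids.append(rec.id)
            iv = _idr_interval(cfg, truth, rng)
            if iv is not None:
                intervals.append(iv)
    return SyntheticCohort(
        records=records,
        idr_intervals=intervals,
        tf_ids=tf_ids,
        truth=pd.DataFrame(truth_rows),
        seed=seed,
    )


def gen_proteome(
    configs: Sequence[SyntheticConfig], out_dir: str | Path, seed: int = 0
) -> SyntheticCohort:
    """Generate a proteome and write the file set the pipeline consumes:
    ``proteome.fasta``, ``idr.tsv``, ``tfs.tsv``, ``truth.tsv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = gen_cohort(configs, seed=seed)
    write_fasta(cohort.records, out / "proteome.fasta")
    write_intervals(cohort.idr_intervals, out / "idr.tsv")
    with open(out / "tfs.tsv", "w") as fh:
        fh.write(f"# seed={seed}\nprotein_id\n")
        for pid in cohort.tf_ids:
            fh.write(pid + "\n")
    truth = cohort.truth.copy()
    truth.insert(0, "seed", seed)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return cohort


def read_tf_list(path: str | Path) -> list[str]:
    """Read a TF identifier list (one id per line, '#' comments allowed)."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line == "protein_id":
                continue
            ids.append(line)
    return ids
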