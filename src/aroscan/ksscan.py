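"""Sliding-window K-S scan for regions of significant aromatic periodicity.

Under a null where aromatic residues occur independently at rate p along
the chain (a Bernoulli / Poisson-process picture), the spacer lengths
between consecutive aromatics are geometric on {0, 1, 2, ...} with success
probability p and mean (1 - p) / p. A sequence whose aromatics are more
regularly spaced than this produces an under-dispersed spacer distribution,
which a one-sample Kolmogorov-Smirnov test detects as a deviation from the
geometric expectation.

The scan applies the test to every 100-residue window (step 1), estimating
p from the within-window aromatic proportion. Runs of consecutive windows
whose P value falls below half the protein's mean window P are merged into
candidate regions; a region is significant when its best window holds at
least five aromatics and its minimum P is at most 0.01. The K-S tail used
is the standard continuous-null one, which is conservative on discrete
spacer data — the calibration tests quantify how conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kstwo

from .seqcore import AROMATICS, Interval, ProteinRecord, overlaps

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100
DEFAULT_MIN_P = 0.01
DEFAULT_MIN_ARO_BEST = 5


@dataclass(frozen=True)
class KSWindow:
    """One tested 100-residue window of the sliding K-S scan."""

    protein_id: str
    start: int
    window_len: int
    n_aro: int
    n_spacers: int
    p_aro_window: float
    ks_D: float
    p_value: float | None

    @property
    def end(self) -> int:
        return self.start + self.window_len - 1


@dataclass(frozen=True)
class PeriodicRegion:
    """A merged run of sub-threshold windows with its filter flags."""

    protein_id: str
    start: int
    end: int
    min_p: float
    best_window_start: int
    n_aro_best: int
    overlaps_idr: bool = False
    overlaps_domain: bool = False
    significant: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> Interval:
        return Interval(self.protein_id, self.start, self.end, kind="REGION")


def geometric_cdf(p_success: float, s) -> np.ndarray | float:
    """CDF of the geometric law on support {0, 1, 2, ...}: F(s) = 1 - (1-p)^(s+1).

    This is the spacer-length null when aromatics occur as a Bernoulli
    process at rate ``p_success``; its mean is (1 - p) / p.
    """
    if not (0.0 < p_success < 1.0):
        raise ValueError(f"geometric success probability must be in (0,1), got {p_success}")
    s_arr = np.asarray(s)
    if np.any(s_arr < 0) or np.any(s_arr != np.floor(s_arr)):
        raise ValueError("spacer lengths must be non-negative integers")
    out = 1.0 - (1.0 - p_success) ** (s_arr + 1.0)
    return out if out.ndim else float(out)


def ks_window_test(
    spacers: Sequence[int], p_aro_window: float
) -> tuple[float, float | None]:
    """One-sample K-S test of observed spacers against the geometric null.

    D is the supremum over the integer support of |empirical CDF - geometric
    CDF|; the two-sided P value comes from the standard one-sample K-S
    distribution at n = number of spacers. Windows with fewer than two
    spacers, or a degenerate aromatic proportion, are skipped (P missing).
    """
    n = len(spacers)
    if n < 2 or not (0.0 < p_aro_window < 1.0):
        return (float("nan"), None)
    sp = np.sort(np.asarray(spacers, dtype=np.int64))
    # empirical CDF evaluated on 0..max(spacers); sup beyond is attained at max
    support = np.arange(sp[-1] + 1)
    ecdf = np.searchsorted(sp, support, side="right") / n
    gcdf = geometric_cdf(p_aro_window, support)
    D = float(np.max(np.abs(ecdf - gcdf)))
    p = float(np.clip(kstwo.sf(D, n), 0.0, 1.0))
    return (D, p)


def scan_protein(
    record: ProteinRecord,
    window_len: int = DEFAULT_WINDOW,
    step: int = 1,
) -> list[KSWindow]:
    """Slide a window over one protein and K-S-test each window's spacers.

    Windows start at 1, 1 + step, ..., L - window_len + 1. Spacers are
    counted only when both flanking stickers lie inside the window, and the
    geometric success probability is the within-window aromatic proportion.
    Proteins shorter than the window give an empty result with a warning.
    """
    L = len(record.sequence)
    if L < window_len:
        logger.warning(
            "%s: length %d < window %d, no windows tested", record.id, L, window_len
        )
        return []
    positions = np.array(
        [i for i in range(1, L + 1) if record.sequence[i - 1] in AROMATICS],
        dtype=np.int64,
    )
    windows: list[KSWindow] = []
    for start in range(1, L - window_len + 2, step):
        end = start + window_len - 1
        lo = int(np.searchsorted(positions, start, side="left"))
        hi = int(np.searchsorted(positions, end, side="right"))
        inside = positions[lo:hi]
        n_aro = int(inside.size)
        p_aro = n_aro / window_len
        spacers = (np.diff(inside) - 1).tolist() if n_aro >= 2 else []
        D, p = ks_window_test(spacers, p_aro)
        windows.append(
            KSWindow(
                protein_id=record.id,
                start=start,
                window_len=window_len,
                n_aro=n_aro,
                n_spacers=len(spacers),
                p_aro_window=p_aro,
                ks_D=D,
                p_value=p,
            )
        )
    return windows


def call_regions(
    windows: Sequence[KSWindow],
    threshold: float | None = None,
    min_p_cutoff: float = DEFAULT_MIN_P,
    min_aro_best: int = DEFAULT_MIN_ARO_BEST,
    step: int = 1,
) -> list[PeriodicRegion]:
    """Merge consecutive sub-threshold windows into periodic regions.

    The threshold defaults to 0.5 x the mean of this protein's tested window
    P values (pass ``threshold`` to use e.g. a proteome-wide value instead).
    Maximal runs of consecutive tested windows with P strictly below the
    threshold become regions spanning first window start to last window end;
    untested windows break runs. Each region records its minimum P, the
    (first) argmin window and that window's aromatic count; ``significant``
    requires at least ``min_aro_best`` aromatics in the best window and
    minimum P at most ``min_p_cutoff``. All raw regions are returned so both
    the pre- and post-filter views can be audited.

    Because a region's span runs to the *end* of its last window, spans of
    window runs separated by fewer than ``window_len`` residues can overlap;
    such regions describe one overlapping stretch of sequence and are merged
    (minimum P and best window carried over), keeping regions disjoint and
    ordered within each protein.
    """
    if not windows:
        return []
    ids = {w.protein_id for w in windows}
    if len(ids) > 1:
        raise ValueError(f"windows from multiple proteins: {sorted(ids)}")
    tested = [w for w in windows if w.p_value is not None]
    if not tested:
        return []
    if threshold is None:
        threshold = 0.5 * float(np.mean([w.p_value for w in tested]))

    regions: list[PeriodicRegion] = []
    run: list[KSWindow] = []

    def flush(run: list[KSWindow]) -> None:
        if not run:
            return
        best = min(run, key=lambda w: (w.p_value, w.start))
        regions.append(
            PeriodicRegion(
                protein_id=best.protein_id,
                start=run[0].start,
                end=run[-1].end,
                min_p=best.p_value,
                best_window_start=best.start,
                n_aro_best=best.n_aro,
                significant=(best.n_aro >= min_aro_best and best.p_value <= min_p_cutoff),
            )
        )

    prev_start: int | None = None
    for w in sorted(windows, key=lambda w: w.start):
        below = w.p_value is not None and w.p_value < threshold
        contiguous = prev_start is not None and w.start == prev_start + step
        if below and run and contiguous:
            run.append(w)
        elif below:
            flush(run)
            run = [w]
        else:
            flush(run)
            run = []
        prev_start = w.start
    flush(run)

    merged: list[PeriodicRegion] = []
    for r in regions:
        if merged and r.start <= merged[-1].end:
            prev = merged[-1]
            keep_prev = prev.min_p <= r.min_p
            best = prev if keep_prev else r
            merged[-1] = replace(
                best,
                start=prev.start,
                end=max(prev.end, r.end),
                significant=(best.n_aro_best >= min_aro_best
                             and best.min_p <= min_p_cutoff),
            )
        else:
            merged.append(r)
    return merged


def annotate_regions(
    regions: Iterable[PeriodicRegion],
    idr_intervals: Iterable[Interval] = (),
    domain_intervals: Iterable[Interval] = (),
) -> list[PeriodicRegion]:
    """Set IDR / domain overlap flags by the >= 1 shared-residue rule."""
    idr_by: dict[str, list[Interval]] = {}
    dom_by: dict[str, list[Interval]] = {}
    for iv in idr_intervals:
        idr_by.setdefault(iv.protein_id, []).append(iv)
    for iv in domain_intervals:
        dom_by.setdefault(iv.protein_id, []).append(iv)
    out = []
    for r in regions:
        out.append(
            replace(
                r,
                overlaps_idr=any(
                    overlaps(r.interval, iv) for iv in idr_by.get(r.protein_id, ())
                ),
                overlaps_domain=any(
                    overlaps(r.interval, iv) for iv in dom_by.get(r.protein_id, ())
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def windows_to_frame(windows: Sequence[KSWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (w.protein_id, w.start, w.n_aro, w.n_spacers, w.p_aro_window,
             w.ks_D, w.p_value)
            for w in windows
        ],
        columns=["protein_id", "start", "n_aro", "n_spacers", "p_aro", "D", "p"],
    )


def regions_to_frame(regions: Sequence[PeriodicRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.protein_id, r.start, r.end, r.length, r.min_p,
             r.best_window_start, r.n_aro_best, r.overlaps_idr,
             r.overlaps_domain, r.significant)
            for r in regions
        ],
        columns=["protein_id", "start", "end", "length", "min_p",
                 "best_window_start", "n_aro_best", "overlaps_idr",
                 "overlaps_domain", "significant"],
    )


def write_windows(windows: Sequence[KSWindow], path: str | Path) -> None:
    windows_to_frame(windows).to_csv(path, sep="\t", index=False)


def write_regions(regions: Sequence[PeriodicRegion], path: str | Path) -> None:
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)
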