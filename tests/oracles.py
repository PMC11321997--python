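"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in the most literal way possible
(plain loops, no shared code with the package's vectorised or incremental
paths) so that agreement is meaningful.
"""

from __future__ import annotations

import itertools

from scipy.stats import kstwo


def oracle_blocks(positions, spacers, classes):
    """Enumerate every sticker sub-run and test the class predicate directly.

    Returns (class_name, start, end, n_stickers, spacer_tuple) tuples for
    every maximal homogeneous run with >= 4 stickers, sorted like the
    implementation's output.
    """
    out = []
    n = len(spacers)
    for cls in classes:
        def in_class(s, c=cls):
            return c.lo <= s <= c.hi
        for i in range(n):
            for j in range(i, n):
                run = spacers[i : j + 1]
                if not all(in_class(s) for s in run):
                    continue
                left_maximal = i == 0 or not in_class(spacers[i - 1])
                right_maximal = j == n - 1 or not in_class(spacers[j + 1])
                if left_maximal and right_maximal and len(run) >= 3:
                    out.append(
                        (cls.name, positions[i], positions[j + 1],
                         len(run) + 1, tuple(run))
                    )
    order = {c.name: k for k, c in enumerate(classes)}
    out.sort(key=lambda t: (order[t[0]], t[1]))
    return out


def oracle_ks(spacers, p_aro):
    """Direct recount of sup|F_emp - F_geom| plus the reference K-S tail."""
    n = len(spacers)
    best = 0.0
    for s in range(max(spacers) + 1):
        f_emp = sum(1 for x in spacers if x <= s) / n
        f_geo = 1.0 - (1.0 - p_aro) ** (s + 1)
        best = max(best, abs(f_emp - f_geo))
    return best, min(1.0, float(kstwo.sf(best, n)))


def oracle_delta(mask, g):
    """Loop-based delta: window asymmetry variance at blob size g."""
    L = len(mask)
    sigmas = []
    for i in range(L - g + 1):
        w = mask[i : i + g]
        f1 = sum(w) / g
        sigmas.append((f1 - (1 - f1)) ** 2)
    f = sum(mask) / L
    sigma_global = (f - (1 - f)) ** 2
    return sum((s - sigma_global) ** 2 for s in sigmas) / len(sigmas)


def oracle_omega(mask, g):
    L = len(mask)
    n = sum(mask)
    m = min(n, L - n)
    dmax = max(
        oracle_delta([0] * off + [1] * m + [0] * (L - m - off), g)
        for off in range(L - m + 1)
    )
    return oracle_delta(mask, g) / dmax


def enumerate_omegas(length, n_stickers, g):
    """Omega of every sticker arrangement of the given composition."""
    out = {}
    for pos in itertools.combinations(range(length), n_stickers):
        mask = [0] * length
        for p in pos:
            mask[p] = 1
        out[pos] = oracle_omega(mask, g)
    return out


def oracle_regions(window_rows, window_len, min_p_cutoff=0.01, min_aro_best=5):
    """Independent region caller from (start, p_or_None, n_aro) rows.

    Reimplements the merge rule literally: threshold is half the mean of
    available P values; runs of start-consecutive tested windows strictly
    below threshold merge; min-P window (first on ties) carries the
    aromatic-count filter.
    """
    tested_p = [p for _, p, _ in window_rows if p is not None]
    if not tested_p:
        return []
    threshold = 0.5 * sum(tested_p) / len(tested_p)
    regions = []
    current = []
    rows = sorted(window_rows)
    for idx, (start, p, n_aro) in enumerate(rows):
        below = p is not None and p < threshold
        prev_adjacent = idx > 0 and rows[idx - 1][0] == start - 1
        if below and current and prev_adjacent:
            current.append((start, p, n_aro))
        elif below:
            if current:
                regions.append(current)
            current = [(start, p, n_aro)]
        else:
            if current:
                regions.append(current)
            current = []
    if current:
        regions.append(current)
    out = []
    for run in regions:
        min_p = min(p for _, p, _ in run)
        best_start, _, best_aro = next(r for r in run if r[1] == min_p)
        out.append(
            {
                "start": run[0][0],
                "end": run[-1][0] + window_len - 1,
                "min_p": min_p,
                "best_window_start": best_start,
                "n_aro_best": best_aro,
                "significant": best_aro >= min_aro_best and min_p <= min_p_cutoff,
            }
        )
    # overlapping spans describe one stretch: merge, keeping the best window
    merged = []
    for r in out:
        if merged and r["start"] <= merged[-1]["end"]:
            prev = merged.pop()
            best = prev if prev["min_p"] <= r["min_p"] else r
            merged.append(
                {
                    "start": prev["start"],
                    "end": max(prev["end"], r["end"]),
                    "min_p": best["min_p"],
                    "best_window_start": best["best_window_start"],
                    "n_aro_best": best["n_aro_best"],
                    "significant": best["n_aro_best"] >= min_aro_best
                    and best["min_p"] <= min_p_cutoff,
                }
            )
        else:
            merged.append(r)
    return merged
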