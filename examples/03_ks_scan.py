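"""Sliding-window K-S scan for regions of significant periodicity.

Generates a 400-residue synthetic protein whose middle carries stickers at
exact spacing 10 (the flanks follow the Bernoulli null), scans it with
100-residue windows, and prints the called regions. A region is significant
when its best window has >= 5 aromatics and minimum P <= 0.01.
"""

import numpy as np

from aroscan import (
    FixedStickers,
    SyntheticConfig,
    call_regions,
    gen_sequence,
    scan_protein,
)

cfg = SyntheticConfig(
    n_proteins=1, length=400, model=FixedStickers(k=10, n_stickers=20)
)
rec, truth = gen_sequence(cfg, np.random.default_rng(42))
print(f"protein {rec.id}: stickers at exact spacing 10 in "
      f"[{truth['sticker_start']},{truth['sticker_end']}]")

windows = scan_protein(rec, window_len=100)
tested = [w for w in windows if w.p_value is not None]
print(f"{len(windows)} windows, {len(tested)} tested "
      f"(mean window P = {np.mean([w.p_value for w in tested]):.3f})")

for r in call_regions(windows):
    flag = "SIGNIFICANT" if r.significant else "below cutoff"
    print(f"region [{r.start},{r.end}] len {r.length}: min P = {r.min_p:.2e} "
          f"at window {r.best_window_start} ({r.n_aro_best} aromatics) -> {flag}")

# The called region should cover the fixed-spacing segment: regular spacers
# are far more concentrated than the geometric law predicts, so the K-S
# statistic rejects the Poisson-placement null there and nowhere else.
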