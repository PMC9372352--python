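"""Volume--Fazekas correlation statistics.

Spearman rank correlation relates WMH volume (%ICV) to the ordinal Fazekas
rating, and a paired subject-level bootstrap compares the manual and
algorithmic correlations: Δr = r(manual, score) - r(algorithm, score),
with a percentile 95% CI over bootstrap replicates. The difference is
called significant when the CI excludes 0; no multiplicity correction is
applied (the comparison is exploratory).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["spearman", "bootstrap_delta_r", "DeltaRResult"]


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    NaN for constant inputs (ranks undefined); requires >= 5 paired values.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if x.size < 5:
        raise ValueError("need at least 5 subjects for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class DeltaRResult:
    r_manual: float
    r_algo: float
    delta_r: float
    ci_low: float
    ci_high: float
    significant: bool
    n_boot: int
    n_dropped: int  # degenerate (constant-vector) replicates discarded


def bootstrap_delta_r(table: pd.DataFrame, n_boot: int = 1000,
                      seed: int = 0) -> DeltaRResult:
    """Paired bootstrap CI for the difference of two dependent Spearman r.

    `table` needs columns volume_manual, volume_algo, fazekas_score. Each
    replicate resamples subjects with replacement (keeping the per-subject
    triple together, since both correlations share subjects) and recomputes
    Δr = r(manual, score) - r(algo, score). The 95% CI is the 2.5/97.5
    percentile of replicates; replicates where any resampled vector is
    constant are dropped and counted.
    """
    required = {"volume_manual", "volume_algo", "fazekas_score"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    vm = table["volume_manual"].to_numpy(dtype=np.float64)
    va = table["volume_algo"].to_numpy(dtype=np.float64)
    fs = table["fazekas_score"].to_numpy(dtype=np.float64)
    n = vm.size
    if n < 5:
        raise ValueError("need at least 5 subjects")
    r_manual = spearman(vm, fs)
    r_algo = spearman(va, fs)
    delta = r_manual - r_algo

    rng = np.random.default_rng(seed)
    reps, dropped = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bm, ba, bf = vm[idx], va[idx], fs[idx]
        if np.ptp(bm) == 0 or np.ptp(ba) == 0 or np.ptp(bf) == 0:
            dropped += 1
            continue
        reps.append(spearman(bm, bf) - spearman(ba, bf))
    reps = np.asarray(reps)
    if reps.size == 0:
        raise ValueError("all bootstrap replicates degenerate")
    ci_low, ci_high = np.percentile(reps, [2.5, 97.5])
    significant = bool(ci_low > 0 or ci_high < 0)
    return DeltaRResult(r_manual=r_manual, r_algo=r_algo, delta_r=delta,
                        ci_low=float(ci_low), ci_high=float(ci_high),
                        significant=significant, n_boot=n_boot,
                        n_dropped=dropped)
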