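"""Independent oracles used by the tests.

Each oracle recomputes a quantity by a route independent of the library
path it checks: full enumeration for PWM scanning and p-values, the plain
statistics module for the Z-score, and exhaustive partition search for
2-cluster k-means.
"""

from __future__ import annotations

import bisect
import itertools
import statistics

import numpy as np


def brute_force_scan(regions, pwm, p_threshold, granularity=1e-3):
    """Enumerate every window of every region against a full 4^L table.

    Per-position log-odds are rounded to the granularity lattice (the
    scoring definition shared with the scanner); everything else — word
    enumeration, tail probabilities, window scoring — is done from scratch.
    Returns a list of (region_id, offset, strand, score_int, pvalue).
    """
    L = len(pwm)
    S = np.rint(np.log2(pwm.probs / pwm.background) / granularity).astype(
        np.int64
    )
    S_rc = S[::-1, ::-1]
    q = pwm.background
    hits = []
    for strand, M in (("+", S), ("-", S_rc)):
        # exact tail over all 4^L words
        mass: dict[int, float] = {}
        for word in itertools.product(range(4), repeat=L):
            s = int(sum(M[i, b] for i, b in enumerate(word)))
            p = float(np.prod([q[b] for b in word]))
            mass[s] = mass.get(s, 0.0) + p
        scores_sorted = sorted(mass)
        sf = {}
        acc = 0.0
        for s in reversed(scores_sorted):
            acc += mass[s]
            sf[s] = acc
        for rid, seq in regions.items():
            for o in range(len(seq) - L + 1):
                w = seq[o : o + L]
                if "N" in w:
                    continue
                sc = int(sum(M[i, "ACGT".index(c)] for i, c in enumerate(w)))
                idx = bisect.bisect_left(scores_sorted, sc)
                pv = sf[scores_sorted[idx]]
                if pv <= p_threshold:
                    hits.append((rid, o, strand, sc, pv))
    return hits


def zscore_oracle(x, null_counts):
    """z = (x - mu) / sigma via the statistics module (population sigma)."""
    mu = statistics.fmean(null_counts)
    sigma = statistics.pstdev(null_counts)
    return mu, sigma, (x - mu) / sigma if sigma > 0 else None


def best_two_partition(X):
    """Exhaustive minimum within-cluster-SS 2-partition of the rows of X.

    Enumerates all 2^(n-1) nontrivial splits; feasible for n <= ~14.
    Returns a boolean membership array for the optimal split.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    best_ss, best_mask = np.inf, None
    for bits in range(1, 2 ** (n - 1)):
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        ss = 0.0
        for m in (mask, ~mask):
            if m.any():
                c = X[m].mean(axis=0)
                ss += ((X[m] - c) ** 2).sum()
        if ss < best_ss:
            best_ss, best_mask = ss, mask
    return best_mask, best_ss
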