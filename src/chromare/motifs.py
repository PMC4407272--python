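"""PWM scanning, random-region null resampling and the motif Z-score.

The significance statistic here is z = (x - mu) / sigma, where x is the
observed number of motif occurrences in fixed-width windows around peak
summits, and mu and sigma are the mean and standard deviation of the same
count over N independent draws of random genomic regions matched in length
to the observed windows (default N = 100).  Occurrences are PWM log-odds
hits called at a p-value threshold; the p-value of a score is the exact
tail probability of a background-generated L-mer, computed by dynamic
programming over the discretised per-position score distribution.

Scores are defined on an integer lattice: each per-position log-odds (in
bits) is rounded to the configured granularity (default 1/1000 bit) at
matrix construction, and both scanning and the p-value DP work on those
integers.  The DP is therefore exact for the scores the scanner emits;
the only approximation relative to un-rounded log-odds is the per-position
rounding, bounded by L x granularity / 2 bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BASES, IntervalSet, Pwm

__all__ = [
    "MotifHit",
    "MotifZScore",
    "PwmScorer",
    "extract_windows",
    "scan_pwm",
    "pvalue_from_score",
    "count_occurrences",
    "sample_random_regions",
    "motif_zscore",
    "motif_enrichment",
    "MotifEnrichment",
    "region_sequences",
]

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, N -> 4; any other letter is an error."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _CODE[raw]
    if np.any(codes < 0):
        bad = chr(raw[int(np.argmax(codes < 0))])
        raise ValueError(f"invalid sequence letter {bad!r}")
    return codes


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    motif_id: str
    offset: int  # start of the match on the region's forward strand
    strand: str
    score: float  # log-odds, bits (on the granularity lattice)
    pvalue: float


@dataclass(frozen=True)
class MotifZScore:
    """Observed count against the resampled null: z = (x - mu) / sigma."""

    motif_id: str
    x: int
    mu: float
    sigma: float
    z: float | None  # None when sigma == 0 (undefined, flagged)
    n_draws: int
    null_counts: tuple[int, ...] = field(repr=False, default=())

    @property
    def defined(self) -> bool:
        return self.z is not None


class PwmScorer:
    """Integer-lattice log-odds scoring engine for one PWM.

    Holds the rounded per-position score matrices for the forward and
    reverse-complement orientations and their exact background score
    distributions (survival functions) for p-value lookup.
    """

    def __init__(self, pwm: Pwm, granularity: float = 1e-3):
        if np.any(pwm.probs <= 0):
            raise ValueError(
                f"PWM {pwm.motif_id} has zero probabilities; scanning "
                "requires a positive pseudocount"
            )
        self.pwm = pwm
        self.granularity = float(granularity)
        bits = np.log2(pwm.probs / pwm.background)
        self.int_scores = np.rint(bits / granularity).astype(np.int64)  # L x 4
        # complement of ACGT is TGCA: reverse both axes
        self.int_scores_rc = self.int_scores[::-1, ::-1]
        self._dist: dict[str, tuple[int, np.ndarray]] = {}

    @property
    def length(self) -> int:
        return self.int_scores.shape[0]

    def _matrix(self, strand: str) -> np.ndarray:
        if strand == "+":
            return self.int_scores
        if strand == "-":
            return self.int_scores_rc
        raise ValueError(f"invalid strand {strand!r}")

    def score_sf(self, strand: str = "+") -> tuple[int, np.ndarray]:
        """(min_score, survival) with survival[i] = P(S >= min_score + i)
        for a background-generated L-mer."""
        if strand not in self._dist:
            S = self._matrix(strand)
            q = self.pwm.background
            mins = S.min(axis=1)
            maxs = S.max(axis=1)
            lo, hi = int(mins.sum()), int(maxs.sum())
            dist = np.zeros(hi - lo + 1)
            dist[0] = 1.0
            cur_lo, cur_len = 0, 1
            for i in range(self.length):
                new_len = cur_len + int(maxs[i] - mins[i])
                new = np.zeros(new_len)
                for b in range(4):
                    off = int(S[i, b] - mins[i])
                    new[off : off + cur_len] += q[b] * dist[:cur_len]
                dist[:new_len] = new
                cur_len = new_len
                cur_lo += int(mins[i])
            sf = np.cumsum(dist[:cur_len][::-1])[::-1]
            self._dist[strand] = (lo, sf)
        return self._dist[strand]

    def pvalue(self, score_bits: float, strand: str = "+") -> float:
        """Exact tail probability that a background L-mer scores >= score."""
        if not np.isfinite(score_bits):
            raise ValueError("score must be finite")
        lo, sf = self.score_sf(strand)
        s_int = int(np.ceil(score_bits / self.granularity - 1e-9))
        if s_int <= lo:
            return 1.0
        idx = s_int - lo
        if idx >= len(sf):
            return 0.0
        return float(sf[idx])

    def score_threshold(self, p_threshold: float, strand: str = "+") -> int:
        """Smallest integer score whose p-value is <= p_threshold."""
        lo, sf = self.score_sf(strand)
        idx = int(np.searchsorted(-sf, -p_threshold, side="left"))
        return lo + idx  # idx == len(sf) => unattainable, no hits

    def scan_codes(self, codes: np.ndarray, strand: str,
                   p_threshold: float) -> tuple[np.ndarray, np.ndarray]:
        """Hit offsets and integer scores over a code array (N-aware)."""
        L = self.length
        n = len(codes)
        if n < L:
            return np.array([], dtype=int), np.array([], dtype=np.int64)
        S = self._matrix(strand)
        lut = np.concatenate([S, np.zeros((L, 1), dtype=np.int64)], axis=1)
        n_win = n - L + 1
        acc = np.zeros(n_win, dtype=np.int64)
        for i in range(L):
            acc += lut[i][codes[i : i + n_win]]
        # windows containing any N are skipped
        is_n = (codes == 4).astype(np.int64)
        csum = np.concatenate(([0], np.cumsum(is_n)))
        valid = (csum[L:] - csum[:-L]) == 0
        thr = self.score_threshold(p_threshold, strand)
        hits = np.flatnonzero(valid & (acc >= thr))
        return hits, acc[hits]


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------


def extract_windows(
    sites: IntervalSet, genome: Mapping[str, str], window: int = 200
) -> tuple[dict[str, str], set[str]]:
    """Sequences of [summit - window/2, summit + window/2) per site.

    Regions are truncated at chromosome ends; truncated region ids are
    returned alongside.  The default 200-bp window follows the usual
    summit-centred motif-scanning convention.
    """
    if window <= 0 or window % 2:
        raise ValueError("window must be a positive even width")
    regions: dict[str, str] = {}
    truncated: set[str] = set()
    for site_id, iv in zip(sites.ids(), sites):
        seq = genome.get(iv.chrom)
        if seq is None:
            raise ValueError(f"chromosome {iv.chrom!r} missing from genome")
        summit = iv.summit_pos
        if summit < 0 or summit >= len(seq):
            raise ValueError(
                f"summit of {site_id} beyond chromosome {iv.chrom}"
            )
        lo, hi = summit - window // 2, summit + window // 2
        clipped_lo, clipped_hi = max(lo, 0), min(hi, len(seq))
        if (clipped_lo, clipped_hi) != (lo, hi):
            truncated.add(site_id)
        regions[site_id] = seq[clipped_lo:clipped_hi]
    return regions, truncated


def region_sequences(
    regions: Sequence[tuple[str, int, int]], genome: Mapping[str, str],
    prefix: str = "r",
) -> dict[str, str]:
    """Slice (chrom, start, end) triples out of a genome."""
    return {
        f"{prefix}{i}": genome[chrom][start:end]
        for i, (chrom, start, end) in enumerate(regions)
    }


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def scan_pwm(
    regions: Mapping[str, str],
    pwm: Pwm,
    p_threshold: float = 1e-4,
    granularity: float = 1e-3,
    scorer: PwmScorer | None = None,
) -> list[MotifHit]:
    """Scan regions on both strands; a hit is a window whose log-odds score
    has background tail probability <= ``p_threshold``.

    Windows containing N are skipped.  Hits are sorted by region id, offset,
    then strand ('+' before '-').
    """
    if scorer is None:
        scorer = PwmScorer(pwm, granularity)
    L = scorer.length
    ids = list(regions)
    # concatenate regions with N separators so one pass scans them all
    sep = "N" * L
    flat = sep.join(regions[i] for i in ids)
    codes = encode_sequence(flat)
    starts = np.zeros(len(ids), dtype=np.int64)
    pos = 0
    for k, i in enumerate(ids):
        starts[k] = pos
        pos += len(regions[i]) + L
    hits: list[MotifHit] = []
    for strand in ("+", "-"):
        offs, scores = scorer.scan_codes(codes, strand, p_threshold)
        if offs.size == 0:
            continue
        region_idx = np.searchsorted(starts, offs, side="right") - 1
        local = offs - starts[region_idx]
        for o, ri, s in zip(local, region_idx, scores):
            bits = float(s * scorer.granularity)
            hits.append(
                MotifHit(ids[int(ri)], pwm.motif_id, int(o), strand, bits,
                         scorer.pvalue(bits, strand))
            )
    hits.sort(key=lambda h: (h.region_id, h.offset, h.strand))
    return hits


def pvalue_from_score(
    pwm: Pwm, score: float, strand: str = "+", granularity: float = 1e-3
) -> float:
    """Exact background tail probability of a log-odds score in bits."""
    return PwmScorer(pwm, granularity).pvalue(score, strand)


def count_occurrences(hits: Sequence[MotifHit], per: str = "occurrences") -> int:
    """Observed count x: total hits, or number of regions with >= 1 hit."""
    if per == "occurrences":
        return len(hits)
    if per == "regions_with_hit":
        return len({h.region_id for h in hits})
    raise ValueError(f"unknown counting mode {per!r}")


# ---------------------------------------------------------------------------
# random-region null and the Z-score
# ---------------------------------------------------------------------------


def sample_random_regions(
    chrom_sizes: Mapping[str, int],
    lengths: Sequence[int],
    n_draws: int = 100,
    seed: int = 0,
) -> list[list[tuple[str, int, int]]]:
    """N draws of random regions, one per input length (lengths matched
    one-to-one), uniform over the genome weighted by chromosome length and
    fully inside their chromosome.  Regions may overlap each other and the
    observed sites; no exclusion is applied."""
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    if any(l <= 0 for l in lengths):
        raise ValueError("region lengths must be positive")
    if max(lengths, default=0) > sizes.min():
        raise ValueError("a requested length exceeds the shortest chromosome")
    rng = np.random.default_rng(seed)
    weights = sizes / sizes.sum()
    draws: list[list[tuple[str, int, int]]] = []
    for _ in range(n_draws):
        regions: list[tuple[str, int, int]] = []
        for length in lengths:
            ci = int(rng.choice(len(chroms), p=weights))
            start = int(rng.integers(0, chrom_sizes[chroms[ci]] - length + 1))
            regions.append((chroms[ci], start, start + length))
        draws.append(regions)
    return draws


def motif_zscore(
    x: int, null_counts: Sequence[int], motif_id: str = "", ddof: int = 0
) -> MotifZScore:
    """z = (x - mu) / sigma against the resampled null counts.

    sigma uses the population denominator N by default (the draws are taken
    as the null distribution itself); set ``ddof=1`` for the sample
    convention.  sigma == 0 yields an undefined flag, never infinity.
    """
    counts = np.asarray(null_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("at least 2 null counts required")
    mu = float(counts.mean())
    sigma = float(counts.std(ddof=ddof))
    z = (x - mu) / sigma if sigma > 0 else None
    return MotifZScore(motif_id, int(x), mu, sigma, z, counts.size,
                       tuple(int(c) for c in null_counts))


def motif_enrichment(
    sites: IntervalSet,
    genome: Mapping[str, str],
    pwms: Sequence[Pwm],
    window: int = 200,
    n_draws: int = 100,
    p_threshold: float = 1e-4,
    seed: int = 0,
    count_mode: str = "occurrences",
    granularity: float = 1e-3,
    estimate_background: bool = True,
) -> pd.DataFrame:
    """Full pipeline: windows -> scan -> null draws -> Z-score per motif.

    With ``estimate_background`` the PWM backgrounds are replaced by the
    0-order base composition of the supplied genome.  Returns a DataFrame
    sorted by descending z (undefined z last).
    """
    if estimate_background:
        from .io import genome_background

        bg = genome_background(genome)
        pwms = [p.with_background(bg) for p in pwms]
    regions, _ = extract_windows(sites, genome, window)
    lengths = [len(s) for s in regions.values()]
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    draws = sample_random_regions(chrom_sizes, lengths, n_draws, seed)
    null_region_sets = [region_sequences(d, genome) for d in draws]
    rows = []
    for pwm in pwms:
        scorer = PwmScorer(pwm, granularity)
        x = count_occurrences(
            scan_pwm(regions, pwm, p_threshold, scorer=scorer), count_mode
        )
        null_counts = [
            count_occurrences(
                scan_pwm(rs, pwm, p_threshold, scorer=scorer), count_mode
            )
            for rs in null_region_sets
        ]
        zs = motif_zscore(x, null_counts, pwm.motif_id)
        rows.append(
            {
                "motif_id": pwm.motif_id,
                "x": zs.x,
                "mu": zs.mu,
                "sigma": zs.sigma,
                "z": zs.z,
                "n_draws": zs.n_draws,
                "window": window,
                "p_threshold": p_threshold,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("z", ascending=False, na_position="last").reset_index(
        drop=True
    )


class MotifEnrichment:
    """Estimator-style wrapper around :func:`motif_enrichment`.

    ``fit(sites, genome, pwms)`` computes the observed counts, the null and
    the Z-scores; results land in ``results_`` and ``zscores_``.
    """

    def __init__(self, window: int = 200, n_draws: int = 100,
                 p_threshold: float = 1e-4, seed: int = 0,
                 count_mode: str = "occurrences", granularity: float = 1e-3,
                 estimate_background: bool = True):
        self.window = window
        self.n_draws = n_draws
        self.p_threshold = p_threshold
        self.seed = seed
        self.count_mode = count_mode
        self.granularity = granularity
        self.estimate_background = estimate_background

    def get_params(self, deep=True):
        return {
            "window": self.window, "n_draws": self.n_draws,
            "p_threshold": self.p_threshold, "seed": self.seed,
            "count_mode": self.count_mode, "granularity": self.granularity,
            "estimate_background": self.estimate_background,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, sites: IntervalSet, genome: Mapping[str, str],
            pwms: Sequence[Pwm]):
        self.results_ = motif_enrichment(
            sites, genome, pwms, self.window, self.n_draws, self.p_threshold,
            self.seed, self.count_mode, self.granularity,
            self.estimate_background,
        )
        self.zscores_ = dict(zip(self.results_["motif_id"],
                                 self.results_["z"]))
        return self
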