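"""Combinatorial co-occupancy, MARE calling, differential occupancy and
TSS-window gene annotation.

A MARE (MITF-associated regulatory element) is modelled here as a site
where every member transcription-factor summit lies strictly between the
two summits of a flanking remodeller-nucleosome pair, with acetylation
present at the flanks.  Co-occupancy between factor peak sets is defined by
summit-to-summit distance.  Differential occupancy compares mean window
signal between two conditions with a symmetric log2-ratio threshold; it is
a descriptive call, not a significance test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DegTable, IntervalSet, TssRecord
from .matrices import SignalMatrix
from .peaks import PairedPeakCall

__all__ = [
    "CooccupancyRecord",
    "MareRecord",
    "DifferentialCall",
    "intersect_summits",
    "classify_combinations",
    "call_mares",
    "DifferentialOccupancy",
    "differential_occupancy",
    "annotate_genes",
    "overlap_fraction",
    "deg_overlap",
]


@dataclass(frozen=True)
class CooccupancyRecord:
    site_id: str
    flags: tuple[tuple[str, bool], ...]  # factor -> presence
    offsets: tuple[tuple[str, int], ...]  # factor -> summit offset from site
    code: str  # ordered subset of present factors, '+'-joined

    def present(self, factor: str) -> bool:
        return dict(self.flags).get(factor, False)


@dataclass(frozen=True)
class MareRecord:
    site_id: str
    tf_members: tuple[tuple[str, int], ...]  # TF -> summit offset from centre
    p1: float
    p2: float
    acetyl_left: bool
    acetyl_right: bool
    strictly_between: bool
    is_mare: bool
    genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class DifferentialCall:
    site_id: str
    mean1: float
    mean2: float
    log2_ratio: float
    label: str  # loss | gain | unchanged


# ---------------------------------------------------------------------------
# summit intersection
# ---------------------------------------------------------------------------


def _nearest_summit(positions: np.ndarray, query: int) -> tuple[int, int] | None:
    """(position, distance) of the nearest summit; equidistant -> leftmost."""
    if positions.size == 0:
        return None
    j = int(np.searchsorted(positions, query))
    best = None
    for k in (j - 1, j):
        if 0 <= k < positions.size:
            pos = int(positions[k])
            dist = abs(pos - query)
            if best is None or dist < best[1] or (dist == best[1] and pos < best[0]):
                best = (pos, dist)
    return best


def intersect_summits(
    set_a: IntervalSet, set_b: IntervalSet, max_dist: int = 250
) -> pd.DataFrame:
    """Match each A site to the nearest B summit within ``max_dist``.

    Returns one row per A site with the matched B summit position and
    signed offset (B - A); unmatched sites have ``cooccupied`` False.
    Matching is by summit-to-summit distance (<= max_dist, inclusive);
    equidistant flanking summits resolve to the leftmost.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    b_pos = set_b.summit_positions()
    rows = []
    for site_id, iv in zip(set_a.ids(), set_a):
        summit = iv.summit_pos
        near = _nearest_summit(b_pos.get(iv.chrom, np.array([])), summit)
        hit = near is not None and near[1] <= max_dist
        rows.append(
            {
                "site_id": site_id,
                "chrom": iv.chrom,
                "summit": summit,
                "cooccupied": hit,
                "b_summit": near[0] if hit else pd.NA,
                "offset": near[0] - summit if hit else pd.NA,
                "distance": near[1] if hit else pd.NA,
            }
        )
    columns = ["site_id", "chrom", "summit", "cooccupied", "b_summit",
               "offset", "distance"]
    return pd.DataFrame(rows, columns=columns)


def classify_combinations(
    sites: IntervalSet,
    factor_sets: dict[str, IntervalSet],
    max_dist=250,
) -> tuple[list[CooccupancyRecord], pd.DataFrame]:
    """Exact combinatorial class per site over named factor peak sets.

    ``max_dist`` may be a scalar or a per-factor dict.  The combination
    code lists present factors in the order of ``factor_sets``; the class
    table tallies sites per code (the analogue of heatmap cluster sizes).
    """
    if len(factor_sets) != len(set(factor_sets)):
        raise ValueError("duplicated factor names")
    if len(factor_sets) < 1:
        raise ValueError("at least one factor set required")
    dists = (
        max_dist if isinstance(max_dist, dict)
        else {f: max_dist for f in factor_sets}
    )
    per_factor = {
        f: intersect_summits(sites, fs, dists[f]).set_index("site_id")
        for f, fs in factor_sets.items()
    }
    records: list[CooccupancyRecord] = []
    for site_id in sites.ids():
        flags = []
        offsets = []
        for f in factor_sets:
            row = per_factor[f].loc[site_id]
            present = bool(row["cooccupied"])
            flags.append((f, present))
            if present:
                offsets.append((f, int(row["offset"])))
        code = "+".join(f for f, p in flags if p) or "none"
        records.append(
            CooccupancyRecord(site_id, tuple(flags), tuple(offsets), code)
        )
    counts = pd.Series([r.code for r in records]).value_counts()
    table = counts.rename_axis("combination").reset_index(name="n_sites")
    return records, table


# ---------------------------------------------------------------------------
# MARE calling
# ---------------------------------------------------------------------------


def call_mares(
    sites: IntervalSet,
    remodeller_calls: dict[str, PairedPeakCall],
    tf_sets: dict[str, IntervalSet],
    acetyl_sites: IntervalSet,
    max_dist: int = 250,
    acetyl_dist: int = 150,
    acetyl_rule: str = "both",
) -> list[MareRecord]:
    """Call MAREs: TF summit(s) strictly between an acetylated remodeller pair.

    A site qualifies iff (i) its remodeller profile is classified paired,
    (ii) at least one member TF is present (summit within ``max_dist`` of the
    site centre) and every member TF summit lies strictly inside (p1, p2),
    and (iii) an acetylation summit lies within ``acetyl_dist`` of both
    flanking remodeller summits ("both"), or of at least one ("either").
    """
    if acetyl_rule not in ("both", "either"):
        raise ValueError(f"unknown acetyl rule {acetyl_rule!r}")
    tf_tables = {
        f: intersect_summits(sites, fs, max_dist).set_index("site_id")
        for f, fs in tf_sets.items()
    }
    acetyl_pos = acetyl_sites.summit_positions()
    out: list[MareRecord] = []
    for site_id, iv in zip(sites.ids(), sites):
        call = remodeller_calls.get(site_id)
        if call is None or call.klass != "paired":
            continue
        p1, p2 = call.p1, call.p2
        center = iv.summit_pos
        members = []
        for f in tf_sets:
            row = tf_tables[f].loc[site_id]
            if bool(row["cooccupied"]):
                members.append((f, int(row["offset"])))
        if not members:
            continue
        strictly_between = all(p1 < off < p2 for _, off in members)
        flanks = []
        for p in (p1, p2):
            near = _nearest_summit(
                acetyl_pos.get(iv.chrom, np.array([])), int(round(center + p))
            )
            flanks.append(near is not None and near[1] <= acetyl_dist)
        left_ac, right_ac = flanks
        acetyl_ok = (left_ac and right_ac) if acetyl_rule == "both" \
            else (left_ac or right_ac)
        is_mare = strictly_between and acetyl_ok
        out.append(
            MareRecord(site_id, tuple(members), p1, p2, left_ac, right_ac,
                       strictly_between, is_mare)
        )
    return out


# ---------------------------------------------------------------------------
# differential occupancy
# ---------------------------------------------------------------------------


class DifferentialOccupancy:
    """Descriptive loss/gain calls between two row-aligned signal matrices.

    Per site the mean window signal is computed for each condition and the
    log2 ratio ``log2((s2 + eps) / (s1 + eps))`` thresholded symmetrically:
    loss if <= -threshold, gain if >= +threshold, else unchanged.  The
    pseudocount eps defaults to 1% of the reference matrix's mean signal.
    """

    def __init__(self, log2_threshold: float = 1.0,
                 pseudocount: float | None = None):
        self.log2_threshold = log2_threshold
        self.pseudocount = pseudocount

    def get_params(self, deep=True):
        return {"log2_threshold": self.log2_threshold,
                "pseudocount": self.pseudocount}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, reference: SignalMatrix):
        self.reference_ = reference
        eps = self.pseudocount
        if eps is None:
            eps = 0.01 * float(reference.values.mean())
        if eps <= 0:
            raise ValueError("pseudocount must be positive")
        self.eps_ = eps
        return self

    def predict(self, treatment: SignalMatrix) -> list[DifferentialCall]:
        ref = self.reference_
        if (
            treatment.anchor_ids != ref.anchor_ids
            or treatment.values.shape != ref.values.shape
            or treatment.bin_size != ref.bin_size
        ):
            raise ValueError("matrices must share anchors and binning")
        m1 = ref.values.mean(axis=1)
        m2 = treatment.values.mean(axis=1)
        ratio = np.log2((m2 + self.eps_) / (m1 + self.eps_))
        calls = []
        for sid, a, b, r in zip(ref.anchor_ids, m1, m2, ratio):
            if r <= -self.log2_threshold:
                label = "loss"
            elif r >= self.log2_threshold:
                label = "gain"
            else:
                label = "unchanged"
            calls.append(DifferentialCall(sid, float(a), float(b), float(r),
                                          label))
        self.calls_ = calls
        return calls


def differential_occupancy(
    matrix_cond1: SignalMatrix,
    matrix_cond2: SignalMatrix,
    log2_threshold: float = 1.0,
    pseudocount: float | None = None,
) -> list[DifferentialCall]:
    est = DifferentialOccupancy(log2_threshold, pseudocount)
    return est.fit(matrix_cond1).predict(matrix_cond2)


def differential_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"site_id": c.site_id, "mean_cond1": c.mean1,
             "mean_cond2": c.mean2, "log2_ratio": c.log2_ratio,
             "label": c.label}
            for c in calls
        ]
    )


# ---------------------------------------------------------------------------
# gene annotation and expression overlap
# ---------------------------------------------------------------------------


def annotate_genes(
    sites: IntervalSet, tss, window: int = 10_000
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Associate genes with site summits within a TSS window.

    A gene is associated iff at least one site summit s satisfies
    ``tss - window <= s < tss + window`` (half-open, strand-independent).
    Returns (gene -> site ids, site -> gene ids).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    summits = sites.summit_positions()
    ids_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for site_id, iv in zip(sites.ids(), sites):
        ids_by_chrom.setdefault(iv.chrom, []).append((iv.summit_pos, site_id))
    for chrom in ids_by_chrom:
        ids_by_chrom[chrom].sort()
    gene_map: dict[str, list[str]] = {}
    site_map: dict[str, list[str]] = {s: [] for s in sites.ids()}
    for rec in tss:
        if not isinstance(rec, TssRecord):
            raise TypeError("tss must be a sequence of TssRecord")
        entries = ids_by_chrom.get(rec.chrom, [])
        pos_arr = np.array([p for p, _ in entries])
        lo = np.searchsorted(pos_arr, rec.pos - window, side="left")
        hi = np.searchsorted(pos_arr, rec.pos + window, side="left")
        linked = [entries[i][1] for i in range(lo, hi)]
        if linked:
            gene_map[rec.gene_id] = linked
            for s in linked:
                site_map[s].append(rec.gene_id)
    return gene_map, site_map


def overlap_fraction(annotated_genes, deg: DegTable) -> dict[str, dict]:
    """Per-status fraction of DEG genes with an associated site.

    For each regulation status: |annotated genes of that status| / |genes
    of that status|; an empty status class yields fraction None.
    """
    annotated = set(annotated_genes)
    if annotated and len(deg) and not (annotated & set(deg.status)):
        warnings.warn("annotated gene ids are disjoint from the DEG table ids",
                      stacklevel=2)
    out: dict[str, dict] = {}
    for status in ("up", "down", "unchanged"):
        genes = deg.genes(status)
        n = len(genes)
        k = len(genes & annotated)
        out[status] = {
            "n_status": n,
            "n_annotated": k,
            "fraction": (k / n) if n else None,
        }
    return out


def deg_overlap(deg_a: DegTable, deg_b: DegTable) -> pd.DataFrame:
    """Venn-style pairwise overlap of two DEG tables, per status."""
    rows = []
    for status in ("up", "down", "unchanged"):
        a = deg_a.genes(status)
        b = deg_b.genes(status)
        rows.append(
            {
                "status": status,
                "a_only": len(a - b),
                "b_only": len(b - a),
                "both": len(a & b),
            }
        )
    return pd.DataFrame(rows)
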