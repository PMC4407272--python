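"""Synthetic chromatin datasets with planted ground truth.

The generator emulates the statistical structure of MNase ChIP-seq style
occupancy around regulatory elements in a melanoma-like setting: a
transcription factor summit sitting in a nucleosome-depleted region between
two flanking remodeller-bound nucleosomes (separations drawn from a 450-800
bp range), TSS with -1/+1 nucleosomes centred by default at -200 and +72 bp
and promoter-paused Pol II just upstream of the +1 nucleosome, combinatorial
factor-membership classes, embedded sequence motifs, genes linked to
occupied sites at controlled TSS-window fractions, and a knockdown condition
with site-specific multiplicative occupancy loss.

Every draw is fully determined by the config seed, and the planted truth is
recorded so downstream modules can be tested for exact recovery.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    BASES,
    CoverageTrack,
    DegTable,
    GenomicInterval,
    IntervalSet,
    Pwm,
    TssRecord,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_deg_table,
    write_fasta,
    write_tss_table,
)

__all__ = [
    "ARCHITECTURES",
    "ElementClass",
    "SimConfig",
    "PlantedElement",
    "GeneRecord",
    "SyntheticTruth",
    "generate_truth",
    "synthesize_coverage",
    "synthesize_sequence",
    "synthesize_gene_tables",
    "simulate_dataset",
    "ebox_pwm",
    "random_pwm",
]

# Architecture vocabulary:
#   flat             anchor with no planted signal (background only)
#   single           one remodeller-bound nucleosome at the element centre
#   tf_only          TF summit(s) with no remodeller pair
#   paired           two remodeller nucleosomes at centre +/- d/2, no TF
#   tf_between_pair  TF summit(s) strictly between a remodeller pair (MARE-like)
#   tss              -1/+1 remodeller nucleosomes around a stranded TSS + Pol II
ARCHITECTURES = ("flat", "single", "tf_only", "paired", "tf_between_pair", "tss")

REMODELLER = "REMODELLER"
ACETYL = "ACETYL"
POLII = "POLII"


@dataclass(frozen=True)
class ElementClass:
    """One planted element class: an architecture plus factor membership."""

    name: str
    n: int
    architecture: str
    tfs: tuple[str, ...] = ()
    acetyl: str = "none"  # none | both | left | right
    separation: tuple[float, float] | None = None  # overrides config default
    knockdown_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.n < 0:
            raise ValueError("element count must be >= 0")
        if self.acetyl not in ("none", "both", "left", "right"):
            raise ValueError(f"unknown acetyl mode {self.acetyl!r}")
        if self.separation is not None and self.separation[0] > self.separation[1]:
            raise ValueError("separation range inverted")
        if not 0.0 <= self.knockdown_fraction <= 1.0:
            raise ValueError("knockdown_fraction must be in [0, 1]")


def _default_classes() -> tuple[ElementClass, ...]:
    return (
        ElementClass("mare", 40, "tf_between_pair", tfs=("MITF", "SOX10"),
                     acetyl="both", knockdown_fraction=0.5),
        ElementClass("paired", 30, "paired", acetyl="both"),
        ElementClass("single", 20, "single"),
        ElementClass("tf_only", 20, "tf_only", tfs=("MITF",)),
        ElementClass("tss", 40, "tss"),
    )


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; the seed is mandatory.

    Amplitudes are peak heights in arbitrary density units; ``noise_rate``
    is the per-bp Poisson background rate, default 0.05 x the nucleosome
    amplitude.  Signal-to-noise for a fixture is amplitude / noise_rate.
    """

    seed: int
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    classes: tuple[ElementClass, ...] = field(default_factory=_default_classes)
    separation_range: tuple[float, float] = (450.0, 800.0)
    tss_upstream: float = -200.0
    tss_downstream: float = 72.0
    tss_offset_sd: float = 20.0
    polii_gap: float = 40.0
    nuc_sd: float = 40.0
    tf_sd: float = 25.0
    nuc_amplitude: float = 10.0
    tf_amplitude: float = 10.0
    acetyl_amplitude: float = 8.0
    polii_amplitude: float = 8.0
    noise_rate: float = 0.5
    min_spacing: int = 3_000
    margin: int = 3_000
    knockdown_factor: str = REMODELLER
    knockdown_loss: float = 0.1
    motif_embed_prob: float = 0.5
    embed_motif: Pwm | None = None
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    # gene layout (dedicated gene chromosome, one 90-kb slot per gene)
    gene_chrom: str = "chrG"
    gene_slot: int = 90_000
    n_genes: dict[str, int] = field(
        default_factory=lambda: {"down": 12, "up": 12, "unchanged": 12}
    )
    # fraction of each status linked to an occupied site within +/-10 kb and
    # +/-30 kb of the TSS (down defaults follow the 34% / 47% regime, up the
    # 12% / 18% regime)
    linked_fractions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "down": (0.34, 0.47),
            "up": (0.12, 0.18),
            "unchanged": (0.10, 0.15),
        }
    )

    def __post_init__(self) -> None:
        if self.separation_range[0] >= self.separation_range[1]:
            raise ValueError("separation range must satisfy min < max")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")
        if not np.isclose(sum(self.base_composition), 1.0):
            raise ValueError("base_composition must sum to 1")
        for st, (f10, f30) in self.linked_fractions.items():
            if not 0 <= f10 <= f30 <= 1:
                raise ValueError(f"linked fractions for {st!r} must be 0<=f10<=f30<=1")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["classes"] = [dataclasses.asdict(c) for c in self.classes]
        if self.embed_motif is not None:
            d["embed_motif"] = {
                "motif_id": self.embed_motif.motif_id,
                "probs": self.embed_motif.probs.tolist(),
                "background": self.embed_motif.background.tolist(),
                "pseudocount": self.embed_motif.pseudocount,
            }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["classes"] = tuple(
            ElementClass(**{**c, "tfs": tuple(c.get("tfs", ())),
                            "separation": tuple(c["separation"])
                            if c.get("separation") else None})
            for c in d.get("classes", [])
        )
        for key in ("separation_range", "base_composition"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("embed_motif"):
            m = d["embed_motif"]
            d["embed_motif"] = Pwm(
                m["motif_id"], np.asarray(m["probs"]),
                np.asarray(m["background"]), m.get("pseudocount", 0.0),
            )
        d["linked_fractions"] = {
            k: tuple(v) for k, v in d.get("linked_fractions", {}).items()
        }
        return cls(**d)


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedElement:
    element_id: str
    chrom: str
    center: int
    class_name: str
    architecture: str
    factors: frozenset[str]
    strand: str = "."
    separation: float | None = None  # paired / tf_between_pair
    tf_offsets: tuple[tuple[str, int], ...] = ()  # factor -> offset from centre
    tss_offsets: tuple[int, int] | None = None  # (-1, +1) in TSS coordinates
    acetyl: str = "none"
    knockdown_loss: bool = False
    motif_id: str | None = None
    motif_pos: int | None = None  # absolute start of the embedded instance
    motif_strand: str | None = None
    gene_id: str | None = None

    @property
    def flank_offsets(self) -> tuple[int, int] | None:
        """Offsets of the two remodeller bumps from the centre, if paired."""
        if self.separation is None:
            return None
        half = int(round(self.separation / 2.0))
        return (-half, half)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    status: str | None  # None => not in the DEG table (e.g. TSS-element genes)
    linked_10kb: bool
    linked_30kb: bool
    element_id: str | None = None


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated dataset."""

    config: SimConfig
    chrom_sizes: dict[str, int]
    elements: list[PlantedElement]
    genes: list[GeneRecord]

    def elements_frame(self) -> pd.DataFrame:
        rows = []
        for el in self.elements:
            rows.append(
                {
                    "element_id": el.element_id,
                    "chrom": el.chrom,
                    "center": el.center,
                    "class": el.class_name,
                    "architecture": el.architecture,
                    "factors": "+".join(sorted(el.factors)),
                    "strand": el.strand,
                    "separation": el.separation,
                    "acetyl": el.acetyl,
                    "knockdown_loss": el.knockdown_loss,
                    "motif_id": el.motif_id,
                    "motif_pos": el.motif_pos,
                    "motif_strand": el.motif_strand,
                    "gene_id": el.gene_id,
                }
            )
        return pd.DataFrame(rows)

    def genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(g) for g in self.genes])

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.elements_frame().to_csv(outdir / "truth_elements.tsv", sep="\t",
                                     index=False)
        self.genes_frame().to_csv(outdir / "truth_genes.tsv", sep="\t",
                                  index=False)
        write_chrom_sizes(self.chrom_sizes, outdir / "chrom.sizes")

    # -- derived views ------------------------------------------------------

    def factor_names(self) -> list[str]:
        names: set[str] = set()
        for el in self.elements:
            names |= el.factors
        return sorted(names)

    def element_sites(self, classes: list[str] | None = None) -> IntervalSet:
        """One interval per element, summit at the planted centre."""
        ivs = []
        for el in self.elements:
            if classes is not None and el.class_name not in classes:
                continue
            half = max(500, int(el.separation or 0))
            start = max(0, el.center - half)
            ivs.append(
                GenomicInterval(el.chrom, start, el.center + half,
                                name=el.element_id, strand=el.strand
                                if el.strand in "+-" else ".",
                                summit=el.center - start)
            )
        return IntervalSet(tuple(ivs))

    def factor_sites(self, factor: str, split_flanks: bool = False) -> IntervalSet:
        """Called-peak analogue for one factor.

        By default one record per element carrying the factor, summit at the
        factor's focal position (TF summit, pair midpoint, bump centre).
        With ``split_flanks`` the acetyl / remodeller marks of a paired
        element are emitted as one record per flanking nucleosome, as a
        nucleosome-resolution peak caller would see them.
        """
        ivs: list[GenomicInterval] = []
        for el in self.elements:
            if factor not in el.factors:
                continue
            positions: list[int]
            if factor in (REMODELLER, ACETYL) and el.flank_offsets is not None:
                if factor == ACETYL:
                    flags = {
                        "both": (True, True), "left": (True, False),
                        "right": (False, True), "none": (False, False),
                    }[el.acetyl]
                else:
                    flags = (True, True)
                offs = [o for o, keep in zip(el.flank_offsets, flags) if keep]
                if split_flanks:
                    positions = [el.center + o for o in offs]
                else:
                    positions = [el.center]
            elif factor == REMODELLER and el.architecture == "tss":
                sign = -1 if el.strand == "-" else 1
                offs = list(el.tss_offsets or ())
                if split_flanks:
                    positions = [el.center + sign * o for o in offs]
                else:
                    positions = [el.center]
            elif factor == POLII:
                sign = -1 if el.strand == "-" else 1
                up, down = el.tss_offsets or (0, 0)
                positions = [
                    el.center
                    + sign * int(round(down - self.config.polii_gap))
                ]
            else:  # a TF
                tf_off = dict(el.tf_offsets).get(factor, 0)
                positions = [el.center + tf_off]
            for k, pos in enumerate(positions):
                start = max(0, pos - 150)
                suffix = f".{k}" if len(positions) > 1 else ""
                ivs.append(
                    GenomicInterval(el.chrom, start, pos + 150,
                                    name=f"{el.element_id}{suffix}",
                                    summit=pos - start)
                )
        return IntervalSet(tuple(ivs))

    def tss_records(self, include_slot_genes: bool = True) -> list[TssRecord]:
        recs = []
        for g in self.genes:
            if not include_slot_genes and g.status is not None:
                continue
            recs.append(TssRecord(g.gene_id, g.chrom, g.tss, g.strand))
        return recs

    def deg_table(self) -> DegTable:
        return DegTable(
            {g.gene_id: g.status for g in self.genes if g.status is not None}
        )

    def mare_ids(self, acetyl_rule: str = "both") -> set[str]:
        """Element ids that satisfy the planted MARE definition."""
        ok_acetyl = {"both": ("both",), "either": ("both", "left", "right")}[
            acetyl_rule
        ]
        return {
            el.element_id
            for el in self.elements
            if el.architecture == "tf_between_pair" and el.acetyl in ok_acetyl
        }


# ---------------------------------------------------------------------------
# truth generation
# ---------------------------------------------------------------------------


def _spaced_positions(rng, n: int, lo: int, hi: int, gap: int) -> np.ndarray:
    """n sorted positions uniform over [lo, hi) with pairwise gaps >= gap."""
    span = (hi - lo) - (n - 1) * gap
    if n == 0:
        return np.array([], dtype=np.int64)
    if span <= 0:
        raise ValueError(
            "genome too small for requested element count at minimum spacing"
        )
    u = np.sort(rng.uniform(0, span, size=n))
    return (lo + u + gap * np.arange(n)).astype(np.int64)


def _rng_for(seed: int, label: str) -> np.random.Generator:
    """A child generator keyed deterministically by seed and label."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    )


def generate_truth(config: SimConfig) -> SyntheticTruth:
    """Place all element classes and genes; deterministic under the seed."""
    rng = _rng_for(config.seed, "truth")
    total = sum(c.n for c in config.classes)
    chroms = list(config.chrom_sizes)
    usable = np.array(
        [max(0, config.chrom_sizes[c] - 2 * config.margin) for c in chroms],
        dtype=float,
    )
    if total > 0 and usable.sum() <= 0:
        raise ValueError(
            "genome too small for requested element count at minimum spacing"
        )

    # elements per chromosome, proportional to usable length
    if total > 0:
        per_chrom = rng.multinomial(total, usable / usable.sum())
    else:
        per_chrom = np.zeros(len(chroms), dtype=int)

    positions: list[tuple[str, int]] = []
    for chrom, n_c in zip(chroms, per_chrom):
        pos = _spaced_positions(
            rng, int(n_c), config.margin,
            config.chrom_sizes[chrom] - config.margin, config.min_spacing,
        )
        positions.extend((chrom, int(p)) for p in pos)

    # shuffle class labels over placements
    labels = np.concatenate(
        [np.full(c.n, i, dtype=int) for i, c in enumerate(config.classes)]
    ) if total else np.array([], dtype=int)
    rng.shuffle(labels)

    elements: list[PlantedElement] = []
    genes: list[GeneRecord] = []
    per_class_members: dict[str, list[int]] = {c.name: [] for c in config.classes}

    for idx, ((chrom, center), lab) in enumerate(zip(positions, labels)):
        cls = config.classes[lab]
        arch = cls.architecture
        element_id = f"el{idx:05d}"
        separation = None
        tss_offsets = None
        strand = "."
        tf_offsets: tuple[tuple[str, int], ...] = ()
        factors: set[str] = set()
        gene_id = None

        if arch in ("paired", "tf_between_pair"):
            lo, hi = cls.separation or config.separation_range
            separation = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            factors.add(REMODELLER)
            if cls.acetyl != "none":
                factors.add(ACETYL)
        if arch == "single":
            factors.add(REMODELLER)
        if arch in ("tf_only", "tf_between_pair"):
            factors.update(cls.tfs)
            k = len(cls.tfs)
            # distinct small offsets inside the NDR for multiple member TFs
            if k == 1:
                offs = [0]
            else:
                offs = [int(round(-60 + 120 * j / (k - 1))) for j in range(k)]
            tf_offsets = tuple(zip(cls.tfs, offs))
        if arch == "tss":
            factors.update({REMODELLER, POLII})
            strand = "+" if rng.random() < 0.5 else "-"
            up = int(round(config.tss_upstream
                           + rng.normal(0, config.tss_offset_sd)))
            down = int(round(config.tss_downstream
                             + rng.normal(0, config.tss_offset_sd)))
            up = min(up, -50)  # keep -1 upstream and +1 downstream
            down = max(down, 20)
            tss_offsets = (up, down)
            gene_id = f"tssgene{idx:05d}"
            genes.append(
                GeneRecord(gene_id, chrom, center, strand, None, True, True,
                           element_id)
            )

        elements.append(
            PlantedElement(
                element_id, chrom, center, cls.name, arch,
                frozenset(factors), strand, separation, tf_offsets,
                tss_offsets, cls.acetyl if arch in ("paired", "tf_between_pair")
                else "none",
                False, gene_id=gene_id,
            )
        )
        per_class_members[cls.name].append(len(elements) - 1)

    # knockdown flags: exactly round(fraction * n) members per class
    for cls in config.classes:
        members = per_class_members[cls.name]
        n_loss = int(round(cls.knockdown_fraction * len(members)))
        if n_loss:
            chosen = rng.choice(len(members), size=n_loss, replace=False)
            for j in chosen:
                i = members[j]
                elements[i] = dataclasses.replace(elements[i],
                                                  knockdown_loss=True)

    # motif embedding: exactly round(prob * n_eligible) elements
    if config.embed_motif is not None:
        eligible = [i for i, el in enumerate(elements)
                    if el.architecture != "flat"]
        n_embed = int(round(config.motif_embed_prob * len(eligible)))
        chosen = rng.choice(len(eligible), size=n_embed, replace=False) \
            if n_embed else []
        motif = config.embed_motif
        for j in sorted(chosen):
            i = eligible[j]
            el = elements[i]
            pos = el.center - len(motif) // 2
            strand = "+" if rng.random() < 0.5 else "-"
            elements[i] = dataclasses.replace(
                el, motif_id=motif.motif_id, motif_pos=pos, motif_strand=strand
            )

    # gene chromosome: one slot per DEG gene, linked elements planted inside
    chrom_sizes = dict(config.chrom_sizes)
    n_slot_genes = sum(config.n_genes.values())
    if n_slot_genes > 0:
        gsize = n_slot_genes * config.gene_slot + 2 * config.margin
        if config.gene_chrom in chrom_sizes:
            raise ValueError(
                f"gene chromosome {config.gene_chrom!r} collides with genome"
            )
        chrom_sizes[config.gene_chrom] = gsize
        slot_ids = list(range(n_slot_genes))
        rng.shuffle(slot_ids)
        cursor = 0
        for status in sorted(config.n_genes):
            n = config.n_genes[status]
            f10, f30 = config.linked_fractions.get(status, (0.0, 0.0))
            n10 = int(round(f10 * n))
            n30 = int(round(f30 * n)) - n10
            kinds = ["near"] * n10 + ["band"] * n30 + ["decoy"] * (n - n10 - n30)
            for k, kind in enumerate(kinds):
                slot = slot_ids[cursor]
                cursor += 1
                tss = config.margin + slot * config.gene_slot \
                    + config.gene_slot // 2
                strand = "+" if rng.random() < 0.5 else "-"
                gid = f"{status}gene{k:04d}"
                el_id = None
                if kind != "decoy":
                    if kind == "near":
                        off = int(rng.integers(-9_500, 9_501))
                        l10, l30 = True, True
                    else:  # 10-30 kb band
                        off = int(rng.integers(10_500, 29_501))
                        if rng.random() < 0.5:
                            off = -off
                        l10, l30 = False, True
                    el_id = f"gel_{gid}"
                    elements.append(
                        PlantedElement(
                            el_id, config.gene_chrom, tss + off,
                            "gene_linked", "single",
                            frozenset({REMODELLER}), ".",
                        )
                    )
                else:
                    l10 = l30 = False
                genes.append(
                    GeneRecord(gid, config.gene_chrom, tss, strand, status,
                               l10, l30, el_id)
                )

    return SyntheticTruth(config, chrom_sizes, elements, genes)


# ---------------------------------------------------------------------------
# coverage synthesis
# ---------------------------------------------------------------------------


def _add_bump(vec: np.ndarray, center: int, amplitude: float, sd: float) -> None:
    """Add a Gaussian-shaped bump, truncated at +/- 5 sd."""
    half = int(np.ceil(5 * sd))
    lo = max(0, center - half)
    hi = min(len(vec), center + half + 1)
    if lo >= hi:
        return
    x = np.arange(lo, hi) - center
    vec[lo:hi] += amplitude * np.exp(-0.5 * (x / sd) ** 2)


def _factor_bumps(
    el: PlantedElement, factor: str, config: SimConfig
) -> list[tuple[int, float, float]]:
    """(center, amplitude, sd) triples a factor contributes at one element."""
    if factor not in el.factors:
        return []
    bumps: list[tuple[int, float, float]] = []
    sign = -1 if el.strand == "-" else 1
    if factor == REMODELLER:
        if el.flank_offsets is not None:
            for off in el.flank_offsets:
                bumps.append((el.center + off, config.nuc_amplitude,
                              config.nuc_sd))
        elif el.architecture == "tss":
            for off in el.tss_offsets or ():
                bumps.append((el.center + sign * off, config.nuc_amplitude,
                              config.nuc_sd))
        else:  # single
            bumps.append((el.center, config.nuc_amplitude, config.nuc_sd))
    elif factor == ACETYL:
        flags = {"both": (True, True), "left": (True, False),
                 "right": (False, True), "none": (False, False)}[el.acetyl]
        for off, keep in zip(el.flank_offsets or (), flags):
            if keep:
                bumps.append((el.center + off, config.acetyl_amplitude,
                              config.nuc_sd))
    elif factor == POLII:
        up, down = el.tss_offsets or (0, 0)
        pos = el.center + sign * int(round(down - config.polii_gap))
        bumps.append((pos, config.polii_amplitude, config.tf_sd))
    else:  # TF
        tf_off = dict(el.tf_offsets).get(factor, 0)
        bumps.append((el.center + tf_off, config.tf_amplitude, config.tf_sd))
    return bumps


def synthesize_coverage(
    truth: SyntheticTruth,
    factor: str,
    condition: str = "control",
    chroms: list[str] | None = None,
) -> CoverageTrack:
    """Dense coverage for one factor in one condition.

    In the ``knockdown`` condition, bumps of the configured knockdown factor
    at loss-flagged elements are multiplied by the configured loss factor;
    Poisson background noise is independent per (factor, condition).
    """
    config = truth.config
    if factor not in truth.factor_names():
        raise ValueError(f"unknown factor {factor!r}")
    if condition not in ("control", "knockdown"):
        raise ValueError(f"unknown condition {condition!r}")
    sizes = (
        truth.chrom_sizes
        if chroms is None
        else {c: truth.chrom_sizes[c] for c in chroms}
    )
    data = {c: np.zeros(n, dtype=float) for c, n in sizes.items()}
    for el in truth.elements:
        if el.chrom not in data:
            continue
        scale = 1.0
        if (
            condition == "knockdown"
            and el.knockdown_loss
            and factor == config.knockdown_factor
        ):
            scale = config.knockdown_loss
        for center, amp, sd in _factor_bumps(el, factor, config):
            _add_bump(data[el.chrom], center, amp * scale, sd)
    if config.noise_rate > 0:
        rng = _rng_for(config.seed, f"noise:{factor}:{condition}")
        for chrom in sorted(data):
            data[chrom] += rng.poisson(config.noise_rate,
                                       size=len(data[chrom]))
    return CoverageTrack(data, dict(sizes))


# ---------------------------------------------------------------------------
# sequence synthesis
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def synthesize_sequence(truth: SyntheticTruth) -> dict[str, str]:
    """I.i.d. background sequence with consensus motif instances planted."""
    config = truth.config
    rng = _rng_for(config.seed, "sequence")
    genome: dict[str, np.ndarray] = {}
    base_arr = np.frombuffer("ACGT".encode(), dtype="S1")
    for chrom in sorted(truth.chrom_sizes):
        n = truth.chrom_sizes[chrom]
        genome[chrom] = rng.choice(base_arr, size=n,
                                   p=list(config.base_composition))
    for el in truth.elements:
        if el.motif_id is None or config.embed_motif is None:
            continue
        motif = config.embed_motif
        inst = motif.consensus
        if el.motif_strand == "-":
            inst = reverse_complement(inst)
        pos = el.motif_pos
        if pos is None or pos < 0 or pos + len(inst) > truth.chrom_sizes[el.chrom]:
            raise ValueError(
                f"motif instance outside chromosome at element {el.element_id}"
            )
        genome[el.chrom][pos : pos + len(inst)] = np.frombuffer(
            inst.encode(), dtype="S1"
        )
    return {c: arr.tobytes().decode() for c, arr in genome.items()}


def synthesize_gene_tables(truth: SyntheticTruth) -> tuple[list[TssRecord], DegTable]:
    """Materialise the TSS table and DEG status table from the truth."""
    return truth.tss_records(), truth.deg_table()


# ---------------------------------------------------------------------------
# convenience PWMs for simulations
# ---------------------------------------------------------------------------


def ebox_pwm(background=(0.25, 0.25, 0.25, 0.25)) -> Pwm:
    """A synthetic E-box-style PWM (consensus TCACGTGA), built in code.

    Stand-in motif for an MITF-like bHLH factor; not taken from any motif
    database.
    """
    consensus = "TCACGTGA"
    probs = np.full((len(consensus), 4), 0.04)
    for i, base in enumerate(consensus):
        probs[i, BASES.index(base)] = 0.88
    return Pwm("EBOX_SYN", probs, np.asarray(background, float))


def random_pwm(
    rng: np.random.Generator,
    motif_id: str,
    length: int = 8,
    concentration: float = 0.5,
    background=(0.25, 0.25, 0.25, 0.25),
) -> Pwm:
    """A random Dirichlet PWM; lower concentration gives sharper columns."""
    probs = rng.dirichlet([concentration] * 4, size=length)
    probs = np.clip(probs, 1e-4, None)
    probs /= probs.sum(axis=1, keepdims=True)
    return Pwm(motif_id, probs, np.asarray(background, float))


# ---------------------------------------------------------------------------
# full dataset emission
# ---------------------------------------------------------------------------


def simulate_dataset(
    config: SimConfig,
    outdir,
    factors: list[str] | None = None,
    conditions: tuple[str, ...] = ("control",),
    sequence: bool = False,
) -> SyntheticTruth:
    """Generate a dataset and write every format the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(config)
    truth.write(outdir)
    write_bed(truth.element_sites(), outdir / "sites.bed")
    for factor in factors if factors is not None else truth.factor_names():
        write_bed(truth.factor_sites(factor),
                  outdir / f"{factor.lower()}_sites.bed")
        for condition in conditions:
            track = synthesize_coverage(truth, factor, condition)
            write_bedgraph(track,
                           outdir / f"{factor.lower()}_{condition}.bedgraph")
    tss, deg = synthesize_gene_tables(truth)
    write_tss_table(tss, outdir / "tss.tsv")
    write_deg_table(deg, outdir / "deg.tsv")
    if sequence:
        write_fasta(synthesize_sequence(truth), outdir / "genome.fa")
    return truth
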