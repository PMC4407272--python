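# chromare

Integrative chromatin analysis of remodeller/transcription-factor
co-occupancy at regulatory elements, at desk scale and with planted ground
truth.

In melanoma cells, MNase ChIP-seq of the SWI/SNF ATPase BRG1 shows a
characteristic architecture at active regulatory elements: two
remodeller-bound nucleosomes separated by roughly 450–800 bp flank a
nucleosome-depleted region in which lineage transcription factors such as
MITF and SOX10 bind, with H3K27ac marking the flanking nucleosomes. At
transcription start sites the same factor occupies the −1 and +1
nucleosomes (meta-profile maxima near −200 bp and +72 bp), with paused
Pol II immediately upstream of the +1 nucleosome. `chromare`
re-implements the computations that characterise this architecture as a
tested, reusable Python library plus CLI:

- **core IO** (`chromare.io`): BED, bedGraph, FASTA, JASPAR count
  matrices, TSS and differential-expression tables, with a dense
  1-bp `CoverageTrack` and 0-based half-open coordinates throughout.
- **synthetic data** (`chromare.simulate`): genomes, coverage tracks,
  peak sets, motif-bearing sequence, gene tables and knockdown conditions
  with fully recorded planted truth (`SyntheticTruth`).
- **signal matrices** (`chromare.matrices`): anchor-centred binned
  read-density matrices and meta-profiles (heatmap substrate).
- **profile clustering** (`chromare.cluster`): `ProfileKMeans`, a
  scikit-learn-style estimator over profile rows, plus re-clustering and
  Hungarian label matching.
- **paired peaks** (`chromare.peaks`): `SummitDetector` finds summits in
  smoothed profiles, classifies none/single/paired architectures,
  measures inter-peak separations d, and classifies TSS −1/+1 occupancy.
- **co-occupancy & MAREs** (`chromare.cooccupancy`): summit-distance
  intersection, exact combinatorial class tables, MARE calling (TF
  summits strictly between an acetylated remodeller pair), knockdown
  differential occupancy, ±window TSS gene annotation and
  expression-overlap fractions.
- **motif Z-scores** (`chromare.motifs`): PWM log-odds scanning with
  exact DP p-values in summit windows, a matched-length random-region
  null (default 100 draws), and the enrichment statistic

  ```
  z = (x − µ) / σ
  ```

  where x is the observed motif occurrence count and µ, σ are the mean
  and (population) standard deviation of the count over the random
  draws.

## Worked example

```python
import numpy as np
from chromare import (
    SimConfig, ElementClass, generate_truth, synthesize_coverage,
    AnchorSet, compute_matrix, call_pairs, separation_summary,
)

config = SimConfig(
    seed=1,
    classes=(ElementClass("mare", 40, "tf_between_pair",
                          tfs=("MITF", "SOX10"), acetyl="both"),),
    n_genes={"down": 0, "up": 0, "unchanged": 0},
)
truth = generate_truth(config)
track = synthesize_coverage(truth, "REMODELLER")
matrix = compute_matrix(track, AnchorSet.from_intervals(truth.element_sites()),
                        flank=1000, bin_size=10)
calls = call_pairs(matrix)
s = separation_summary(calls)
print(f"{s['n_paired']} paired sites, median d = {s['median']:.0f} bp, "
      f"range {s['min']:.0f}-{s['max']:.0f} bp")
```

prints

```
40 paired sites, median d = 660 bp, range 470-790 bp
```

i.e. all 40 planted elements are recognised as paired remodeller
nucleosomes and the recovered inter-peak separations span the planted
450–800 bp range. The same objects feed clustering
(`kmeans_profiles(matrix, k=4, seed=1)`), MARE calling and the motif
Z-score (`motif_enrichment(sites, genome, pwms, seed=1)`).

The CLI mirrors the library:

```bash
chromare simulate --seed 1 --out data/ --sequence
chromare matrix --track data/remodeller_control.bedgraph \
    --anchors data/sites.bed --chrom-sizes data/chrom.sizes \
    --summit-col 6 --out matrix.tsv
chromare pairs --matrix matrix.tsv --out pairs.tsv
```

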