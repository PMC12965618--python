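# viradiel

Sub-daily time-series analysis for marine virome abundance tables.

High-frequency viromic sampling — every 4 hours at the surface and every
12 hours at the deep chlorophyll maximum over ~5 days — makes it possible
to ask whether individual viral populations (vOTUs, ~species-rank contig
clusters) track the day/night cycle even when aggregate community metrics
stay flat. `viradiel` implements that analysis end to end for
population-by-sample normalized coverage tables:

* **Community diversity.** Inverse Simpson alpha diversity
  (1 / Σ pᵢ²), Bray–Curtis beta diversity on log₂(x+1) abundances, classical
  PCoA, and MRPP / ANOSIM / Wilcoxon rank-sum contrasts between depth
  layers or day and night samples.
* **Diel rhythm detection.** Each series is detrended (OLS on elapsed
  time over included samples) and pooled into time-of-day classes. For
  every circular *umbrella alternative* — abundance rising monotonically
  from a trough class to a peak class around one arc of the 24-h clock and
  falling back around the other — a Jonckheere–Terpstra-type statistic
  counts concordant cross-class pairs,

      A = Σ_arcs Σ_{i<j on the trough→peak walk} [ #{x∈i, y∈j : x < y} + ½·ties ].

  The per-population p-value is the best alternative's upper-tail p
  (exact, from a dynamic program over rank placements, whenever the series
  is tie-free) times the effective number of distinct alternatives, capped
  at 1; Benjamini–Hochberg step-up control across populations declares
  diel populations at FDR ≤ 0.05.
* **Peak timing and archetypes.** Peak clock time is the time-of-day
  class with the highest mean within-series abundance rank (exact ties →
  circular midpoint); peaks inside 18:00–06:00 are "night". Scaled,
  detrended diel series are checked for clusterability (Hopkins statistic)
  and clustered by a 1-D batch self-organizing map, with PAM and
  complete-linkage hierarchical clustering as comparators; the archetype
  count sits at the elbow of the mean-silhouette profile, with
  Calinski–Harabasz as a companion metric.
* **AMG curation and host summaries.** A conservative rule chain for
  auxiliary metabolic genes (auxiliary score 1–3; metabolic module or
  M/K/E flag; viral-region or contig-score ≥ 0.95 evidence; no
  mobile-genetic-element keywords on the contig; no tRNA/repeat overlap at
  phage ends; optional KEGG KO requirement), plus genus-level
  host-prediction summaries with ≤ 1 % pooling into "Others" and per-genus
  log₂ fold changes between depths.
* **Synthetic data.** A generator reproducing the sampling design (29
  surface samples at 4-h spacing starting 16:00, two masked; 10
  deep-chlorophyll-maximum samples at 12-h spacing, two masked) with known
  per-population ground truth: diel rows are log-normal series modulated
  by a periodic umbrella (or cosine) waveform with chosen peak phase,
  rise time, and amplitude.

## Worked example

```python
import numpy as np
from viradiel.syndata import SyntheticConfig, simulate_abundance
from viradiel.rhythm import rain_scan
from viradiel.archetypes import scale_series, select_archetypes, peak_rank_time

cfg = SyntheticConfig(n_populations=300, fraction_diel=0.5, seed=7)
matrix, truth = simulate_abundance(cfg)

results = rain_scan(matrix, period=24.0, alpha=0.05)
diel = [r for r in results if r.is_diel]
print(f"{len(diel)} of {len(results)} populations diel "
      f"({100*len(diel)/len(results):.2f}%)")

scaled, kept = scale_series(matrix, [r.population_id for r in diel])
report, detail = select_archetypes(scaled, k_range=range(2, 7), seed=7)
print(f"hopkins = {report.hopkins:.2f}")
print(f"chosen: {report.method} with k = {report.k} "
      f"(mean silhouette {report.mean_silhouette:.2f})")

clock = np.array([s.clock_hours for s in matrix.samples])
classes = np.round((clock % 24) / 4).astype(int) % 6
mask = matrix.included_mask()
idx = {p: i for i, p in enumerate(matrix.population_ids)}
peaks = [peak_rank_time(matrix.values[idx[p]], classes, mask, deltat=4.0,
                        population_id=p) for p in kept]
night = sum(pt.day_night == "night" for pt in peaks)
print(f"{100*night/len(peaks):.2f}% of diel populations peak at night")
```

prints

```
152 of 300 populations diel (50.67%)
hopkins = 0.74
chosen: pam with k = 3 (mean silhouette 0.46)
76.32% of diel populations peak at night
```

Half the simulated populations carry a planted 24-h rhythm and the scan
recovers almost exactly those (150 planted, 152 flagged at FDR 0.05); the
Hopkins statistic well above 0.5 says the diel series are genuinely
clusterable, the silhouette elbow lands on the three planted waveform
archetypes, and the night-peaking share reflects the 80/20 night/day
archetype weights of the generator.

The same stages are available from the shell:

```sh
viradiel simulate --seed 7 --out-prefix sim
viradiel validate sim_abundance.tsv sim_metadata.csv
viradiel rhythm sim_abundance.tsv sim_metadata.csv --layer SUR --out rhythm.tsv
viradiel archetypes sim_abundance.tsv sim_metadata.csv --diel-results rhythm.tsv
viradiel amg-filter sim_annotations.tsv --require-ko
viradiel hosts sim_abundance.tsv sim_metadata.csv sim_hosts.csv
```

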