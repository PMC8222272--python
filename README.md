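# replistress

Quantitative analysis toolkit for replication stress and telomere dynamics
in progerin-expressing (HGPS) cells, with matched synthetic-data
generators. It covers the four measurement tracks such studies combine:

1. **Replication timing (RT) profiling.** Two-channel array probes
   (log2 early/late ratio *M*, mean intensity *A*, one probe per 13 kb)
   are normalized (within-array MA loess, between-array quantile), smoothed
   per chromosome by a local-linear tricube regression with a 3 Mb window,
   and compared between conditions through 95% confidence bands
   (fit ± 1.96·SE): maximal runs of probes where the two bands are disjoint
   become *earlier*/*later* differential-RT regions, summarized as genome
   fractions.
2. **SMARD fiber statistics.** From run-length-encoded labeled DNA fibers
   (EdU first pulse, IdU second, 20 min each; 2 kb/µm stretch): replication
   track lengths (maximal IdU tracts), fork rates (track/20 min),
   inter-origin distances, stalled-fork percentage (EdU with no adjacent
   IdU), and replicating vs non-replicating telomere classification with
   FISH-tract length estimates.
3. **QIBC cell-cycle gating.** Per-nucleus DAPI/EdU intensities gated
   flow-cytometry-style into G1/S/G2M (automatic KDE-valley thresholds),
   with per-phase summaries of damage markers (γH2AX intensity, 53BP1
   foci).
4. **Telomere and growth assays.** Population doublings
   (PD = log2(C2/C1)), TRF Southern quantification (ladder calibration,
   OD-weighted mean length ΣOD/Σ(OD/L), shortening rate in bp/PD), qPCR
   fold enrichment (E^ΔCt), MadID telomere-normalized m6A ratios, and ChIP
   enrichment vs input/H3.

Every input the pipeline consumes can be generated synthetically with the
statistical structure the analyses assume (domain-structured RT with dye
bias and injected shifts; pulse-labeled fibers with fork speeds and
stalls; 2N/4N DAPI mixtures; TRF smears shortening with PD), so each
method is exercisable end-to-end from a single seed. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
import replistress as rs
from replistress.synth import RTSimConfig, simulate_rt_truth, simulate_arrays

layout = rs.make_genome(n_chrom=10, chrom_length=20_000_000, spacing=13_000)
cfg = RTSimConfig()           # noise 0.3, dRT 1.5, 3% earlier shifts, 2 replicates
truth = simulate_rt_truth(layout, cfg, seed=1)
arrays = simulate_arrays(truth, cfg, seed=1)

for a in arrays:              # within-array dye-bias removal
    a.M = rs.loess_normalize_within(a.M, a.A)
for a, m in zip(arrays, rs.quantile_normalize_between([a.M for a in arrays])):
    a.M = m

bands = {}
for cond in ("ref", "cond"):
    avg = np.mean([a.M for a in arrays if a.condition == cond], axis=0)
    bands[cond] = rs.profile_ci(avg, bandwidth=3e6, level=0.95, layout=layout)

regions = rs.call_differential(bands["cond"], bands["ref"], min_probes=8)
print(rs.genome_fraction(regions, layout))
```

prints

```
    scope direction   percent
0  genome   earlier  4.421326
1  genome     later  0.000000
```

i.e. with 3.13% of this simulated genome truly shifted to earlier
replication (ΔRT = +1.5), the confidence-band caller recovers earlier
regions covering 4.42% and calls no spurious later regions. The ~1-point
overshoot is the documented boundary blur of CI-band calling at a 3 Mb
smoothing window (region edges extend ~0.5 Mb beyond each true shift
boundary); with no injected shifts the called fraction is 0.0%.

The same workflow is available from the shell:

```bash
replistress simulate rt --seed 1 --out sim/
replistress rt-call --in sim/probes_raw.tsv --out calls/
replistress run --seed 1 --out full/      # all four tracks + metrics.json
```

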