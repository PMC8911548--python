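# phasorseg

Unsupervised segmentation of time-resolved fluorescence (FLIM/TCSPC) decay
maps by phasor-plot analysis and Gaussian-mixture clustering.

The package targets fibre-based time-resolved fluorescence imaging of
heterogeneous fluorescent materials — the motivating application is
discriminating painting materials (pigments bound in rabbit-skin glue, egg
yolk, acrylic PVA or linseed oil) whose emission spectra overlap but whose
fluorescence lifetimes differ. It is equally applicable to any TCSPC decay
map in which two or more populations with distinct decay kinetics share a
field of view.

## Method

Each pixel of a decay map is a TCSPC histogram `c_k` (default: 256 bins of
195 ps under 20 MHz pulsed excitation, i.e. a 49.92 ns window inside the
50 ns period). The phasor transform projects every decay onto the first
harmonic of the repetition frequency *f*:

```
g = Σ_k c_k cos(ω t_k) / Σ_k c_k        ω = 2πf
s = Σ_k c_k sin(ω t_k) / Σ_k c_k        t_k = (k + ½)·Δt
```

Mono-exponential decays fall on the universal semicircle
`(g − ½)² + s² = ¼`; mixtures fall inside it. The fit-free phase lifetime

```
τ_phase = s / (2πf·g)
```

equals the true lifetime for a mono-exponential decay. Low-signal pixels
are discarded by a quality filter that keeps only decays with peak counts
strictly greater than 100.

The retained (g, s) cloud is modelled as a K-component bivariate Gaussian
mixture `p(x) = Σ_i f_i N(x; µ_i, Σ_i)` (default K = 2, one component per
known population at a measured interface) fitted by expectation–
maximization. Each phasor is hard-assigned to its most probable component,
and — because every phasor traces back to exactly one pixel — the cluster
labels become a spatial segmentation. Each cluster is reported as mean ± SD
τ-phase, reproducing a per-population lifetime table, and rendered as
false-colour τ maps, red/green cluster maps and responsibility-blended
probability images.

A synthetic-data module generates mono/bi-exponential decays under periodic
excitation with Poisson counting noise and two-population interface maps
with known ground truth, so the whole pipeline is testable end to end
without instrument data.

## Worked example

Simulate a 50×60 interface map (3000 decays) between two mono-exponential
populations with lifetimes 3.7 ns and 1.7 ns — the measured mean τ-phases
of cerulean blue in rabbit-skin glue and in linseed oil — at an expected
peak of 500 counts with Poisson noise, then segment it:

```
$ phasorseg simulate --tau-a 3.7 --tau-b 1.7 --shape 50x60 --peak 500 \
      --seed 0 --out interface.csv
seed=0
$ phasorseg segment interface.csv --out seg_out
INFO retained 3000 / 3000 pixels
INFO GMM converged=True after 4 iterations, log-likelihood 27177.037
INFO cluster 1: n=1500 mean tau=3.70 ns sd=0.04 ns
INFO cluster 2: n=1500 mean tau=1.70 ns sd=0.02 ns
retained=3000 k=2 out=seg_out
```

All 3000 decays pass the 100-count filter; the mixture fit converges and
the two clusters recover the ground-truth lifetimes (3.70 ± 0.04 ns and
1.70 ± 0.02 ns) with each cluster holding exactly the 1500 pixels of its
population. `seg_out/` contains the τ-phase map (CSV, float TIFF, and a
blue-to-red PNG over 2.0–4.5 ns), the phasor coordinates with cluster
labels, the fit report, the cluster summary table and the rendered
cluster/probability maps. `phasorseg report` concatenates summary tables
from several runs.

The same workflow is available as a library:

```python
from phasorseg import (AcquisitionConfig, PopulationSpec, RunConfig,
                       run_segmentation, simulate_interface_map)

cfg = AcquisitionConfig()                      # 20 MHz, 256 × 195 ps
glue = PopulationSpec(lifetimes=(3.7,), target_peak=500, label=1)
oil = PopulationSpec(lifetimes=(1.7,), target_peak=500, label=2)
dmap = simulate_interface_map(glue, oil, (50, 60), 30, cfg, seed=0)
result = run_segmentation(dmap, RunConfig(acquisition=cfg, seed=0))
for s in result.summaries:
    print(s.cluster_id, round(s.mean_tau_ns, 2), round(s.sd_tau_ns, 2))
# 1 3.7 0.04
# 2 1.7 0.02
```

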