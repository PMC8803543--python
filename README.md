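# statecomp

Transient, sub-second bursts of 4–30 Hz oscillatory power are a basic
feature of resting-state MEG/EEG. Two very different data-driven models are
used to carve such recordings into discrete, recurring brain states:

* **EEG microstates** — periods of quasi-stable sensor topography, found by
  clustering instantaneous maps (typically restricted to peaks of global
  field power) and assigning every sample to the best-matching template;
* **power-envelope hidden Markov models (HMM)** — a K-state Markov chain
  with Gaussian emissions fit to band-limited Hilbert power envelopes,
  decoded into exclusive, complete binary state time courses by the Viterbi
  algorithm.

`statecomp` implements both arms end to end, together with the state
statistics (mean lifetimes, fractional occupancies, thresholded
partial-correlation power maps) and the spatial/temporal cross-state
correlation framework needed to ask whether the two kinds of states
describe the same neural events. Because resting-state MEG/EEG corpora are
rarely shareable, the package ships a first-class synthetic-data module
that plants a hidden Markov chain of oscillatory bursts behind a known toy
leadfield, so every stage can be validated against ground truth.

## Models

**Global field power and microstates.** For a sensor map
$v_t \in \mathbb{R}^C$, $\mathrm{GFP}(v_t)$ is its spatial standard
deviation. Atomize–agglomerate hierarchical clustering (AAHC) starts from
singleton clusters of (GFP-peak) maps and repeatedly dissolves the cluster
with least explained GFP — $\sum_{i \in c}(\mathrm{gfp}_i\,
|r(v_i, u_c)|)^2$, with $u_c$ the cluster's principal-component topography
— reassigning each freed map to the cluster of maximal absolute spatial
correlation, until $K$ clusters remain. Backfitting labels sample $t$ with
$\arg\max_k |r(v_t, u_k)|$; the labelling is exclusive and complete. A
smoothed variant labels GFP peaks only and extends labels by
nearest-neighbour interpolation. Fit quality is the global explained
variance $\mathrm{GEV} = \sum_t (\mathrm{gfp}_t\, r_t)^2 / \sum_t
\mathrm{gfp}_t^2$.

**Envelope HMM.** Per subject, band-passed signals are Hilbert-transformed
to power envelopes, window-averaged down to 40 Hz, demeaned, scaled by the
subject's pooled SD, concatenated across subjects, and reduced to the first
$N$ principal components. A $K$-state Gaussian HMM is then fit by
variational Bayes with conjugate priors (Dirichlet transitions,
Gaussian–Wishart emissions; an EM route is available), run with multiple
restarts keeping the lowest free energy, and decoded with Viterbi.

**State statistics.** Lifetimes are the durations of maximal constant-label
runs; occupancies are per-state time fractions. Power maps are partial
correlations between a state's activation series and each location's power
envelope, controlling for the other states, thresholded against the Fisher
null $z \sim \mathcal{N}(0, 1/\sqrt{\nu - 3})$ with
$\nu = \lfloor T/4 \rfloor - (K - 1)$ and Bonferroni correction over
$(K-1) \times$ spatial degrees of freedom. Cross-model comparisons use
within-subject Pearson correlations of power maps (spatial) and Spearman
correlations of binary activations (temporal), with one-sided group
t-tests.

## Worked example

```python
import numpy as np
import statecomp as sc

cfg = sc.SimConfig(n_subjects=3, duration_s=60.0, K_true=4, seed=2)
recordings, truth = sc.generate_dataset(cfg)
micro = [sc.moving_window_downsample(
            sc.bandpass(sc.rereference_average(r), 4.0, 30.0), 40.0)
         for r in recordings]
maps = np.concatenate(
    [m.data[sc.find_gfp_peaks(sc.gfp_series(m))] for m in micro])
model = sc.aahc_cluster(maps, K=4)
```

Running `python examples/02_microstates.py` (the script above plus scoring)
prints:

```
clustered 2396 GFP-peak maps into K=4 microstates
explained GFP fraction (clustering): 0.66
template recovery |corr| vs planted maps: [0.999 0.999 0.999 0.999]
subject sub01: GEV 57%, raw lifetime 44 ms, smoothed 168 ms
```

i.e. the four planted topographies are recovered essentially exactly, the
classification explains 57% of global variance, and — the package's central
contrast — raw per-sample microstate labels flicker on a ~40 ms timescale
while peak-interpolated labels (and, see `examples/03_envelope_hmm.py`,
Viterbi-decoded HMM states at ~257 ms) persist several times longer on the
very same data. `examples/` contains one short script per capability:
simulation and containers, microstates, the envelope HMM, thresholded power
maps, and the cross-model comparison; `statecomp run --config cfg.yaml
--out dir` drives the whole pipeline from a YAML file.

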