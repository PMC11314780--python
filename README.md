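# eegfc — EEG functional connectivity and MST topology pipeline

`eegfc` quantifies how the functional organisation of the infant brain changes
across the first year of life from baseline (task-free) EEG. It is aimed at
developmental-neuroscience groups who record multichannel EEG at successive
ages (e.g. 6 and 12 months), want band-wise functional connectivity and graph
summaries per subject, and need longitudinal statistics that respect repeated
measures and missing follow-up.

## What it computes

For every 2-s epoch, every channel pair and each of six frequency bands
(delta 2–4, theta 4–6, low alpha 6–9, high alpha 9–13, beta 13–30,
gamma 30–45 Hz):

- **Magnitude-squared coherence** from Welch-averaged cross-spectra,

  MSC(f) = |⟨Sxy(f)⟩|² / (|⟨Sxx(f)⟩| |⟨Syy(f)⟩|) ∈ [0, 1],

  averaged over the band's frequency bins; the mean over all channel pairs is
  the whole-brain **Mean MSC**.
- **Phase lag index** from Hilbert instantaneous phases,

  PLI = |⟨sign Δφ(t_k)⟩| ∈ [0, 1],

  which discounts zero-lag (volume-conducted) coupling; the pairwise mean is
  **Mean PLI**.
- The **minimum spanning tree** of the PLI matrix (Kruskal on weights
  1 − PLI, i.e. the backbone of strongest couplings) and its topology:
  leaf fraction Lf, diameter, eccentricity, betweenness centrality Bc,
  tree hierarchy Th = L/(2·m·B_max), degree correlation, and degree
  divergence κ = ⟨k²⟩/⟨k⟩. Together these locate the network on the
  line-like (less integrated) … star-like (hub-integrated) continuum.

Epoch values are averaged per subject and compared across timepoints and sex
with a linear mixed model (subject random intercept), Benjamini–Hochberg FDR
across bands, and associated with later cognitive/language outcome scores via
bootstrap Spearman correlations whose percentile CI must exclude zero.

A synthetic cohort generator produces multichannel surrogate recordings with
known coupling ground truth (two timepoints, optional sex effect, outcomes
linearly tied to true coupling, missing-completely-at-random follow-up), so
the entire pipeline can be validated end to end without any raw EEG.

## Worked example

```python
import numpy as np
from eegfc import (CouplingSpec, FrequencyBand, generate_coupled_pair,
                   bandpass_filter, pli_matrix, msc_matrix, mean_offdiag,
                   build_mst, mst_features)

band = FrequencyBand("high_alpha", 9.0, 13.0)

# two 10 Hz channels, pi/4 apart, moderately noisy
rec = generate_coupled_pair(fs=250.0, duration=2.0,
                            spec=CouplingSpec(10.0, np.pi / 4, 1.0, 0.5), seed=42)
pli = pli_matrix(bandpass_filter(rec, band).data)
msc = msc_matrix(rec.data, rec.fs, band)
print(f"PLI  = {pli.values[0, 1]:.3f}")
print(f"MSC  = {msc.values[0, 1]:.3f}")

# MST topology of a hub-dominated PLI matrix
rng = np.random.default_rng(0)
v = rng.uniform(0.0, 0.2, size=(8, 8))
v = (v + v.T) / 2
v[0, 1:] = v[1:, 0] = 0.9        # strong hub couplings
np.fill_diagonal(v, 0.0)
feats = mst_features(build_mst(v))
print(f"leaf fraction  = {feats.leaf_fraction:.3f}")
print(f"diameter       = {feats.diameter}")
print(f"tree hierarchy = {feats.tree_hierarchy:.3f}")
print(f"kappa          = {feats.kappa:.3f}")
```

prints

```
PLI  = 1.000
MSC  = 0.805
leaf fraction  = 0.875
diameter       = 2
tree hierarchy = 0.500
kappa          = 4.000
```

The constant π/4 lag is perfect phase locking, so PLI is 1; sensor noise is
uncorrelated between the channels, so coherence sits below 1. The
hub-dominated matrix yields a star tree: 7 of 8 nodes are leaves, every node
is within 2 edges of every other, and Th reaches its star-limit 0.5.

Full runs go through the CLI:

```bash
eegfc simulate --out data --n-t6 20 --n-t12 20 --n-overlap 10 --seed 1
eegfc run-all --config config.toml     # features.csv, stats.csv, correlations.csv
```

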