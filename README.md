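# fontanflow

Automated flow analysis for the Fontan circulation: joint deep
classification + segmentation of multi-vessel phase-contrast MR (PCMR)
cines, flow quantification, deep temporal clustering of flow-curve
phenotypes, and time-varying survival analysis of the resulting clusters.

Patients with a functionally single ventricle and Fontan palliation have
highly abnormal blood-flow patterns in the aorta (Ao), the branch pulmonary
arteries (LPA/RPA) and the caval veins (SVC/IVC). Velocity-encoded PCMR
measures these flows over the cardiac cycle, but registries store only
time-averaged summaries; recovering the time-varying signal at scale
requires automatic vessel identification and segmentation, followed by a
temporal dimensionality reduction that preserves waveform shape. This
package implements that full pipeline and, because registry data is
access-restricted, ships a first-class synthetic-data module (pulsatile
vessel phantoms with analytic ground-truth flow, cluster-structured flow
cohorts, and cluster-dependent event times) so every stage is testable
end to end.

## Models

**DCS — joint Deep Classification + Segmentation.** A five-scale
encoder/decoder in the UNet3+ style operating on 2-channel 2D+time input
(contrast-equalized magnitude and the "imaginary" image `M sin(phi)`):
3D convolutions with spatial-only pooling, full-scale skip connections,
deep supervision with head weights (0.25, 0.25, 0.25, 0.25, 1.00), a
classification-guided module (CGM) from the bottleneck, and a tunable side
input that one-hot encodes the DICOM series description (6 slots), maps it
through an MLP to a 64-element vector, reshapes it 8x8, tiles it over the
32 frames and concatenates it to the bottleneck (255 + 1 = 256 channels at
8x8x32 for the default 128x128x32 input). Training minimizes, at every
head, `1.00 * FocalTversky(seg) + 0.25 * CE(CGM)` with Adam. Predicted
masks are projected back to the source grid; the largest space-time
connected component is kept for LPA/RPA/IVC and the two largest for Ao/SVC.
Flow is `sum_mask VENC * phi / pi * pixel_area` per frame; the net forward
volume is its integral over one RR interval.

**DTC — Deep Temporal Clustering.** BSA-indexed, 30-frame, globally
z-scored two-channel flow curves are compressed by a temporal autoencoder
(1D conv, 50 filters, kernel 10; max-pool 3; BiLSTMs of 50 and 1 units)
into latent vectors `z_i`. A clustering layer with centroids `mu_j` assigns

    q_ij = (1 + ||z_i - mu_j||^2)^-1 / sum_j' (1 + ||z_i - mu_j'||^2)^-1

and self-trains against the sharpened target

    p_ij = (q_ij^2 / sum_i q_ij) / sum_j' (q_ij'^2 / sum_i q_ij')

by minimizing reconstruction MSE + KL(P || Q) (equal weights, Adam,
lr 1e-3), updating assignments every 100 epochs until fewer than 0.1% of
samples change cluster. A PCA + k-means baseline (60-dimensional
concatenated curves, mean-centered) is included for comparison, and
cluster-outcome association uses a time-varying Cox model on
counting-process intervals plus Simon-Makuch curves (Kaplan-Meier extended
to time-varying group membership, truncated below 10 at risk).

Both networks run on a small numpy reverse-mode autodiff engine inside the
package (`fontanflow.nn`) — no deep-learning framework is required.

## Worked example

Ground-truth flow quantification on a synthetic five-vessel exam, then
phenomapping a synthetic caval-flow cohort:

```python
import numpy as np
from fontanflow import phantom as ph, dtc
from fontanflow.flowquant import compute_flow_curve, derived_indices

exam = ph.generate_phantom_exam(ph.default_phantom_spec(seed=0))
rates = {v: compute_flow_curve(exam.truth_masks[v], exam.series[v],
                               bsa=exam.demographics["BSA"]).indexed_flow_rate
         for v in exam.series}
print(rates, derived_indices(rates))
```

prints indexed flow rates (L/min/m^2) and derived hemodynamic indices:

```
LPA: 0.64  RPA: 0.69  SVC: 0.89  IVC: 1.25  Ao: 2.41
total_pa_flow: 1.330   lpa_fraction: 0.484
total_vc_flow: 2.137   svc_fraction: 0.415   collateral_pct: 11.310
```

(`collateral_pct` is the aortic-minus-caval fraction of aortic flow, the
aortopulmonary collateral estimate; `lpa_fraction` is LPA / total PA flow.)

```python
from fontanflow.baseline_pca import pca_kmeans
from sklearn.metrics import adjusted_rand_score

spec = ph.CohortSpec(archetypes=ph.VC_ARCHETYPES, n_per_cluster=50,
                     seed=7, scan_probs=(1.0,))
curves, labels, demo = ph.generate_flow_cohort(spec)
data = dtc.prep_curves(curves, demo["BSA"].to_numpy(), ("SVC", "IVC"))
res = dtc.train_dtc(data, k=4, config=dtc.TAEConfig(
    pretrain_epochs=30, update_interval=25, max_epochs=300, seed=1))
print(res.summary())
print("ARI vs simulated truth:", adjusted_rand_score(labels, res.labels_))
```

```
Deep temporal clustering (k=4, n=200)
  converged: True after 50 epochs
  final fraction changed: 0.0000%
  cluster sizes: [50, 50, 50, 50]
  silhouette (latent space): 0.779
ARI vs simulated truth: 1.0
```

The four recovered clusters are exactly the four simulated hemodynamic
archetypes (IVC-dominant, SVC-dominant/high-flow, normal/high-flow,
normal/normal-flow), and the self-trained latent space separates them more
cleanly than the PCA + k-means baseline on the same data (silhouette 0.78
vs 0.61).

A command-line interface mirrors the library:
`fontanflow simulate | train-dcs | segment | flows | train-dtc |
cluster-pca | outcomes | report` (see `fontanflow --help`).

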