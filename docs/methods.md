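# Methods

## Model

Patients form an undirected weighted population graph. Node features are
image-derived vectors; edge weights are clinical similarity scores. The
risk model is a two-layer GraphSAGE with edge-weight-normalized mean
aggregation:

    agg_v = Σ_{u∈N(v)} w_uv h_u / Σ_{u∈N(v)} w_uv        (zero vector if N(v)=∅)
    h'_v  = ReLU(W [h_v ; agg_v] + b)

followed by a linear head mapping the second-layer embedding to a scalar
risk s_v. Normalizing by the weighted degree makes the layer invariant to
a global rescaling of edge weights; only relative weights matter. An
optional "mean-augment" pooling mode concatenates the graph-wide mean
embedding to every node before the head; it is off by default because a
graph-constant channel cannot help rank nodes within one graph, and the
shift-invariance of the Cox partial likelihood makes a constant offset
irrelevant.

Training is transductive: the whole graph (all features and edges,
including validation and test nodes) is visible to the forward pass, and
only the loss is masked to training nodes. The loss is the negative mean
Cox partial log-likelihood with risk sets formed inside the mask
(inclusive t_j ≥ t_i); ties are handled by Breslow by default, Efron
optionally. Both the loss and its analytic gradient are implemented
directly in NumPy and verified against brute-force risk-set enumeration
and finite differences. Optimization is full-batch Adam with inverted
dropout on both hidden layers, optional L2 weight decay, and early
stopping on the validation Cox loss (parameters of the best validation
epoch are restored). Features are standardized to zero mean / unit
variance over all nodes before training (transductive scaling); the
fitted scaler is stored with the model.

Defaults: hidden widths 128/64, dropout 0.1, lr 1e-3, 300 epochs,
patience 30, Glorot-uniform initialization. These are generic, deliberately
conservative settings; the cohort-scale experiments below use a compact
variant (16/8, lr 3e-3, weight decay 3e-3) sized to an 800-patient cohort
with 32-dimensional features, where the wider default network gains
nothing and trains more noisily.

## Similarity graph

Four component scores per pair: demographics = 1[same sex]·w_sex +
age-kernel·w_age with a piecewise kernel (full credit ≤ 5 y gap, half
credit ≤ 10 y, else 0); location, histology and stage are category
indicators. All component weights default to 1, so the demographics
component peaks at 2 and the others at 1. The combination rule is the
**sum** (range [0, 5]) with connection threshold 2.0 by default; the
product rule (range [0, 2]) is retained as a config option. The sum was
chosen as the default because observed neighbour edge-weight medians in
this design sit in the 2–3 range, which a product of sub-unit components
cannot reach; the threshold 2.0 means "at least two full component
agreements (or equivalents)". The stage component compares the IA/IB/IIA/IIB
sub-stage for equality rather than T/N/M triplets, since sub-stage is the
granularity available in the clinical table. Nodes are ordered
canonically by patient id, making graph construction invariant to record
order; an all-pairs vectorized scorer is tested against a per-pair
brute-force oracle.

## Synthetic cohorts

The generator emulates a large early stage surgical NSCLC cohort:
59.2% male, age ~ N(60.6, 8.7²) truncated to [18, 95], histology
72.4/22.9/4.7% (adeno/squamous/other), lobe 25.7/14.1/33.8/9.8/16.6%
(LUL/LLL/RUL/RML/RLL), sub-stage 46.4/35.6/7.8/10.2% (IA/IB/IIA/IIB).
Covariates are drawn independently — real cohorts correlate them (e.g.
histology with sex and smoking), which this generator does not attempt.

Survival follows a Weibull proportional-hazards model with log relative
hazard β_stage·stage_ordinal + β_image·z, where z ~ N(0,1) is a latent
image score (independent of the clinical covariates by default; an
`image_stage_dependence` knob can couple it to stage). Defaults
β = (0.4, 0.5), shape 1.3, OS scale 253 months were calibrated once by
simulation so that marginal 5-year OS is ≈ 78.2%; an independent Weibull
recurrence channel (scale 785.9 months) defines RFS = min(recurrence,
death) with ≈ 74.2% 5-year RFS. Administrative censoring at 84 months
(~7-year accrual-plus-follow-up horizon) yields ≈ 31% observed OS events.
Node features are standard Gaussian noise with the first `n_informative`
coordinates mean-shifted by z, so the image signal is recoverable by
averaging but no single column is decisive. Phantom tumour volumes (noisy
bright ellipsoids on a lung-attenuation background, mild per-axis radius
jitter) exercise the preprocessing path; they make no attempt at CT
texture realism. Consequently, passing tests demonstrate the correctness
of the machinery under a proportional-hazards world with independent
covariates — not performance on real CT features, real censoring
patterns, or correlated clinical data.

## Preprocessing path

CT windowing defaults to (−1000, 400) HU with voxels above 400 HU
(bone-bright) removed, i.e. mapped to the output floor — the rescaled
volume lies in [0, 1]. Volumes are standardized to 128×128×64 (centre
zero-padding for small tumours, centre-crop for oversized ones — the
padding convention extended symmetrically), trilinearly resampled to
64×64×36, and tiled into a 384×384 montage: 36 axial slices in ascending
order, six per row, slice k at grid position (k÷6, k mod 6). The montage
is "divided into 36 ordered patches" in exactly this tile sense, and
`split_montage` inverts the tiling exactly. The default featurizer
computes per-tile summary statistics (mean, sd, quartiles → 180 values)
padded to a configurable dimension (default 768); learned feature
extractors can be registered behind the same deterministic contract.

## Evaluation stack

* **AUC**: outcome binarized at a fixed horizon (default 60 months —
  5-year framing): positive if the event occurred by the horizon,
  negative if followed beyond it, subjects censored earlier excluded.
  Point estimate is Mann–Whitney concordance; CI is a percentile
  bootstrap (1000 resamples, stratified within outcome classes so every
  resample retains both, seeded).
* **Stratification**: high/low at the training-set median risk
  (strictly-greater rule, so constant risks give all-low); Kaplan–Meier
  and log-rank are delegated to lifelines and verified against
  product-limit and O−E/V oracles.
* **NRI** is the continuous (category-free) version, range [−2, 2].
* **IDI** is the difference in discrimination slopes and requires
  probabilities; raw risk scores are mapped by within-cohort rank scaling
  (rank − 0.5)/n, a monotone convention that fixes the scale without
  asserting calibration. The same mapping feeds DCA.
* **DCA**: net benefit TP/n − (FP/n)·p_t/(1−p_t) over thresholds
  0.05…0.95, with treat-all and treat-none references.

## Parameter-recovery experiment

The recovery study (also run by `scripts/acceptance.py`) uses n = 800,
effects (0.5, 1.0) — an image-dominant hazard — with 16 of 32 feature
coordinates informative, and the compact training configuration above.
These conditions are chosen so that failure indicates an implementation
defect rather than an information limit: with the image and stage
channels independent, the stage contribution to the hazard is not
recoverable from features plus normalized aggregation, so the achievable
test c-index is bounded by the feature-only ceiling (≈ 0.70–0.75 here,
with occasional test-set draws near 0.65 at 100 test patients / ~40
events). The trained model reaches > 0.65 in 18–19 of 20 seeds, matches
chance (mean within [0.45, 0.55]) when features are shuffled off their
patients, and yields positive NRI/IDI against the stage-ordinal baseline.

## Numerical and degenerate-case choices

* Cox loss errors when the mask holds no events (undefined likelihood);
  a single event with itself as risk set gives loss 0.
* Log-sum-exp shifts by the max risk; loss/gradient match enumeration to
  1e-10 at n ≤ 8 and finite differences to 1e-7.
* Isolated nodes aggregate a zero vector and never error.
* An empty graph (no pair above threshold) is valid; training degrades to
  a per-node MLP.
* Edge weights equal at the threshold are included (≥).
* Splits: test and validation sizes round down, training takes the
  remainder — the only convention consistent with a 1492/213 partition
  of 1705 at 75/12.5/12.5.
* Bootstrap and training randomness always derive from explicit seeds;
  the pipeline log records the seed of every stage.

## Known limitations

No pretrained image featurizer ships with the package (the adapter hook
exists; the default featurizer is summary statistics). Clinical
covariates are generated independently. The similarity formula's exact
component definitions in the source design are unpublished; the scheme
here is an explicit, configurable stand-in. Evaluation AUC is
fixed-horizon, not incident/dynamic time-dependent AUC. Training is
dense full-batch and sized for cohorts of order 10³–10⁴ nodes, not
GPU-scale graphs.
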