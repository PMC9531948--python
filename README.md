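# graphsurv

Population-graph survival modelling for early stage (IA–IIB) non-small
cell lung cancer.

Surgical resection is the standard of care in early stage NSCLC, yet
roughly 40–55% of patients relapse; pTNM staging alone predicts this
coarsely. `graphsurv` implements a prognostic model that combines the two
information channels a thoracic clinic actually has — tumour imaging and
non-imaging clinical data — in a single graph: each patient is a node
carrying an image-derived feature vector, and two patients are linked when
a clinical similarity score over demographics (sex + age), tumour lobe,
histology and pTNM sub-stage reaches a connection threshold, with the
score as the edge weight. A two-layer edge-weighted GraphSAGE network is
trained transductively on the whole graph with a Cox
proportional-hazards partial-likelihood loss

```
L(θ) = −(1/D) Σ_{i: δ_i=1} [ s_i − log Σ_{j: t_j ≥ t_i} exp(s_j) ]
```

(s = per-node risk score, D = number of events, risk sets restricted to
training nodes; Breslow ties by default, Efron optional) and emits one
risk score per patient, for overall survival (OS) or recurrence-free
survival (RFS).

The package is aimed at methods researchers in clinical survival
prediction: everything runs end-to-end on synthetic cohorts with known
ground truth, so the machinery — graph construction, the GraphSAGE/Cox
training loop (NumPy, analytic gradients), and the full evaluation stack
(bootstrap AUC at a fixed horizon, training-median risk stratification,
Kaplan–Meier curves with log-rank tests, continuous NRI, IDI, decision
curve analysis) — is testable without patient data. A CT preprocessing
path (windowing, 128×128×64 standardization, 64×64×36 resampling, 384×384
six-per-row slice montage, pluggable featurizer) handles real NIfTI
tumour ROIs when you have them.

## Worked example

```bash
graphsurv run-all --config demo_cfg.json --out demo_run
graphsurv report --run-dir demo_run
```

where `demo_cfg.json` asks for an 800-patient synthetic cohort with an
image-dominant hazard (log-hazard = 0.5·stage + 1.0·latent image score,
half of 32 feature coordinates informative) and a compact network
(hidden widths 16/8, lr 3e-3). The report prints:

```
    graph_model  OS: AUC 0.726 (0.613-0.827), log-rank p 1.10e-03, NRI 0.100, IDI 0.107
    graph_model RFS: AUC 0.740 (0.630-0.837), log-rank p 2.42e-04, NRI 0.087, IDI 0.103
 stage_baseline  OS: AUC 0.622 (0.499-0.734), log-rank p 7.87e-03
 stage_baseline RFS: AUC 0.642 (0.535-0.761), log-rank p 3.35e-03
  test c-index OS: 0.710
  test c-index RFS: 0.721
```

Reading this: on the 100 held-out test patients the graph model separates
5-year survivors from non-survivors with AUC 0.73 (OS), clearly above the
stage-ordinal baseline (0.62); stratifying the test set at the training
median risk gives significantly separated Kaplan–Meier arms (log-rank
p ≈ 1e-3); and positive NRI/IDI say the model reclassifies patients in
the right direction relative to staging alone. The run directory also
holds the graph edge list, model archive, per-patient risks, training
log, KM/DCA plots and a JSON-lines stage log.

The same pipeline is available as library calls (`generate_cohort`,
`build_graph`, `train`, `evaluate_model`, …); the CLI verbs `simulate`,
`preprocess`, `build-graph`, `train`, `evaluate`, `run-all`, `report`
are thin wrappers.

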