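# Methods

This note documents the models and procedures implemented in `crownprof`,
the choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Crown profiles

A crown profile is the radius `CR` of the crown envelope as a function of
relative crown height `RCH ∈ [0, 1]` — depth below the treetop divided by
the largest crown length `LCL = TH − HCB`.  Field measurements give four
radii per cardinal direction at RCH = 0.25, 0.5, 0.75, 1.0; together with
the structural anchor `CR = 0` at the treetop these five knots are
interpolated onto the uniform grid RCH = 0.0, 0.1, …, 1.0 with PCHIP
(monotone piecewise-cubic Hermite).  PCHIP reproduces the knots exactly,
is monotone on monotone data and cannot overshoot local extrema —
properties that matter for envelope curves, where spline or polynomial
oscillation would create phantom bulges.  Interpolated radii are clipped
at zero as a numerical guard; with PCHIP this should never trigger, and a
warning is logged if it does.  Crown heights from the treetop follow as
`CH_k = 0.1·k·LCL`.  The mean profile is the layerwise arithmetic mean of
the four directional profiles.

Data filters: DBH ≥ 5 cm, 0 < HCB < TH, all measured RCH ≤ 1.0, exactly
four valid radii per direction.  Rejections carry machine-readable reason
codes and filtering is idempotent.

## The competition index

**Competitor units.**  Competitors of a subject tree are the trees whose
Voronoi cells share an edge of positive length with the subject's cell.
Cells are clipped to the circular plot boundary before adjacency is read
off; boundary trees therefore keep finite cells and edge artefacts from the
unbounded hull are avoided.  Candidate pairs come from the Delaunay dual
(SciPy), cell polygons from Shapely's Voronoi construction, and a pair is
adjacent when its clipped cells share boundary longer than 1 nm.  Fewer
than three stems, or collinear stems, have no Voronoi diagram; the
implementation falls back to "all other trees are neighbours" with a
warning.  The test suite validates adjacency against an independent
brute-force oracle (nearest-stem labelling of a dense grid); the only
permitted disagreements are shared edges shorter than the grid resolution,
which the oracle cannot see.

**Layer gate.**  Crown discs at layers k (subject) and t (competitor)
compete only when `|CH_ik − CH_jt| ≤ 2 m`.  CH is depth from each tree's
own top (the convention of the measurement protocol), not height above
ground, and the 2 m threshold is fixed rather than size-dependent.  A
competitor layer may gate into several subject layers; each subject layer
is computed independently.

**Overlap geometry.**  Crowns at a layer are discs centred on the stem.
With radii r₁, r₂ and stem distance d the overlap is: 0 when d ≥ r₁+r₂;
the area of the smaller disc when d ≤ |r₁−r₂|; otherwise the circular lens
`r₁² arccos((r₁²+d²−r₂²)/2dr₁) + r₂² arccos((r₂²+d²−r₁²)/2dr₁r₂) − 2·Heron(r₁,r₂,d)`.
The three regimes agree at their boundaries to well below 1e-6 m² (tested on
1,000 random pairs) and the closed form matches 10⁷-sample Monte-Carlo
estimates within 1% relative error.  Regime classification uses a 1e-12 m
tolerance; at exact boundaries the formulas coincide, so ties are harmless.
Near-degenerate lenses (one radius ≈ 0) can lose ~1e-9 m² to cancellation,
so the lens value is clamped to [0, π·min(r₁,r₂)²].

**CPCI.**  For subject layer k,

    CPCI_k = (1 / Z_ik) Σ_j Σ_t AO_ij(k,t) · (CH_jt · CR_jt) / (CH_ik · CR_ik)

over gated pairs, with `Z_ik = π CR_ik²` the subject's disc area.  Two
points were open and are resolved as follows: the size-ratio weight is
applied per pair inside the double sum (the alternative — a single ratio
outside an already-summed overlap — is ill-defined for more than one
competitor), and the undefined "projection area" is taken as the subject's
own disc area at that layer, consistent with the disc simplification.
Layers with `CR_ik = 0` have CPCI 0 by definition.  Geometry always uses
the directional-mean profiles; the directional variant does not recompute
overlaps but allocates each layer's CPCI across E/W/S/N as

    CPCI_dir(k) = CPCI_k · (1 − CR_dir / Σ_dir CR_dir),

an exact identity `Σ_dir CPCI_dir(k) = 3 CPCI_k` that the tests enforce at
1e-12.  Directions where the subject's own crown is large receive a smaller
share: an expanded radius is read as evidence of *less* suppression from
that side.

## Feature sequences and models

Each tree (or tree × direction) becomes a 10-step sequence over layers
k = 1…10, ordered top → base so the lagged radius CR_(k−1) is naturally
seeded by the known treetop zero.  (A base → top ordering is available as a
configuration switch; its first lag is seeded with 0 for want of a
below-base radius.)  Per step the 14 predictors are AGE, DBH, TH, CW, HCW,
HCB, CH_k, LCL, TSC, CLR, BA, SDI, CR_(k−1), CPCI_k; dropping CPCI gives
the 13-feature ablation condition.  TSC is slenderness TH(m)/DBH(cm); BA
and SDI are conventional per-hectare basal area and Reineke density
(exponent 1.605, reference 25 cm), entering only as stand-context features.
Missing HCW is imputed with the plot mean; HCW does not enter the CPCI.

Inputs and targets are min-max scaled to [0, 1] with statistics from the
training partition only; test values outside the training range map outside
[0, 1] and are deliberately not clipped (logged instead).  The 8:1:1
train/validation/test split operates at the tree level, so the lag feature
cannot leak information across partitions through shared trees.

Architectures (NumPy, hand-written backpropagation, finite-difference
verified):

* **vanilla_lstm** — one LSTM layer over the raw features, per-step linear
  head.
* **cnn_lstm** — residual convolution block (two 1-D convolutions with
  kernel 3 and same-padding, the second with twice the filters; a linear
  projection of the input added elementwise; ReLU) feeding the LSTM.
* **cnn_lstm_attention** — additionally, the LSTM output sequence is
  permuted so time is innermost, a fully connected 10→10 layer plus softmax
  produces, per hidden unit, an attention distribution over the 10 layers,
  and the original sequence is reweighted elementwise (length preserved) —
  the sequence must survive because the head is per-step.  Alternative
  readings (a single distribution shared across units; a residual
  "add-the-weighted-sequence" form) were considered; the per-unit
  multiplicative form follows the described permute→dense→softmax structure
  most directly.

Training minimises MSE on normalised targets with Adam (default learning
rate 3e-3, batch 32, max 200 epochs, early stopping patience 20, best
validation weights restored, all RNGs seeded; the implementation is exactly
reproducible, with no framework nondeterminism).  The optimiser, epoch
budget and loss are not externally prescribed; these are conventional
choices, exposed in `ModelConfig`.  Hyperparameter search uses canonical
particle swarm optimisation (inertia 0.7, cognitive = social = 1.5, swarm
10, 20 iterations by default; integer dimensions rounded at evaluation)
over filters 32–256, LSTM units 32–128, learning rate 1e-5–1e-2, batch
16–64, scoring validation MSE of a shortened (50-epoch) training run.

At prediction time the lag feature uses **teacher forcing** by default (the
observed previous-layer radius); an **autoregressive** mode feeds back the
model's own previous prediction.  Teacher forcing measures one-step-ahead
accuracy and is the default reporting mode; autoregressive prediction is
what a deployment without measured radii would use, compounds errors, and
separates model quality much more sharply.  Metrics are reported for
whichever mode is configured.

## Evaluation

MSE (m²), RMSE, MAE, ME (m, mean of observed − predicted) and
R² = 1 − SSE/SST with the test-set mean in SST, computed over pooled
tree × layer records in metres after inverse normalisation.  Zero observed
variance makes R² undefined; it is reported as NaN with a warning.  Feature
attribution uses permutation importance (increase in test MSE when one
feature is shuffled across sequences, step-varying features shuffled within
each step slot, averaged over repeats).  Permutation importance was chosen
over SHAP-style explainers because it is assertable against
generator-controlled ground truth and needs no extra dependencies.

## Synthetic stands

The generator emulates a middle-aged pine stand: hard-core sequential
inhibition stem placement (default 125 stems, 25 m plot radius, 1.5 m
minimum spacing); lognormal DBH (mean 19.5 cm, sd 6.8 cm); height allometry
`TH = 2.3321·DBH^0.55·exp(ε)`; crown ratio ~ N(0.42, 0.10) truncated to
(0.15, 0.80) with `HCB = TH(1 − CLR)`; crown-width allometry
`CW = 0.26487·DBH^0.70`; age tied to relative diameter.  The allometric
coefficients include the lognormal Jensen correction so that large-sample
generated means hit the calibration targets (DBH 19.5 cm, TH 11.8 m,
HCB ≈ 6.8 m, CW 2.1 m, AGE 27.3 yr), which the tests check to within two
standard errors at n = 5,000.

Directional radius curves are power functions
`r_dir(u) = mult_dir · (CW/2) · u^β · (1 − γ·crowd_dir)` with β ~ N(0.6,
0.08) per tree, cardinal multipliers (E 0.97, W 0.95, S 1.18, N 0.90)
giving the south-largest asymmetry expected under northern-hemisphere
insolation, and `crowd_dir ∈ [0, 1]` a cosine-windowed, proximity-weighted
count of neighbours within 8 m of the stem in that compass sector.  The
competition sensitivity γ (default 0.5) scales how strongly crowding
compresses the crown.  Recorded radii at RCH 0.25/0.5/0.75/1.0 carry 5%
multiplicative lognormal noise (mean-one).  `CW` is recorded as the
*allometric* (pre-competition) width: the competition signal must be
carried by stem geometry and CPCI, not leaked through a static feature —
this is what makes the ±CPCI ablation informative.

Two subtleties the generator exposed:

* With γ > 0 the crowding→CPCI association is confounded: crowded crowns
  shrink, which reduces their overlaps, and the net rank correlation can
  even turn negative.  The invariant "CPCI recovers injected crowding" is
  therefore tested at γ = 0, where crown size is independent of crowding
  and the correlation is strongly positive.
* Under teacher-forced evaluation with 5% measurement noise the prediction
  task saturates near R² ≈ 0.999; under-trained models all sit at that
  ceiling and architecture differences drown in seed noise.  With the full
  training budget (200 epochs, patience 20) the capacity ordering
  (attention ≥ CNN-LSTM > vanilla) emerges consistently.

## What the synthetic experiments show — and what they do not

The analogue experiment (four 125-tree plots, γ = 0.5, three seeds, both
±CPCI conditions, all three architectures; roughly three minutes on one
CPU) demonstrates that the pipeline is internally consistent: the index
detects the competition the generator injected, richer architectures fit
better, and the qualitative ordering matches what one expects from model
capacity.  It does not validate the biology: real crowns are not power
functions, real asymmetry is not four fixed multipliers, real measurement
error is not i.i.d. lognormal, and real stands mix species and ages.
Numeric values obtained on synthetic stands (R² ≈ 0.99 at the noise
ceiling) are properties of the generator, not of any field population, and
are deliberately not comparable to results on measured data.

## Known limitations

* The layer gate compares depths below each tree's own top; two crowns at
  very different absolute heights can still be gated together if their
  depths match.  This follows the field-measurement convention (CH recorded
  from the treetop) but is worth revisiting
  with height-above-ground data.
* Voronoi adjacency after clipping can include hairline edges (sub-mm);
  these are kept (threshold 1e-9 m) and are irrelevant to CPCI because the
  corresponding crowns rarely overlap.
* PSO searches the learning rate on a linear scale across three decades;
  a log-scale search would cover the low decades more evenly.
* The CLI's dataset container is NumPy `.npz`; models are not serialised to
  disk (experiments re-train, which at these sizes takes seconds).
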