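# crownprof

Directional crown-profile prediction for *Pinus yunnanensis* stands: a
layered, direction-aware **Crown Profile Competition Index (CPCI)** built
from Voronoi competitor units and circle-overlap geometry, feeding compact
sequence models (Vanilla LSTM, CNN-LSTM, CNN-LSTM-Attention) that predict
the crown radius at every relative crown height.

## The problem

The crown profile — crown radius `CR` as a function of relative crown height
`RCH` (depth below the treetop divided by the largest crown length `LCL`) —
drives light capture, growth and competition modelling for individual trees.
Crowns are neither symmetric nor free of neighbours: competition compresses
them layer by layer and direction by direction.  `crownprof` implements a
full pipeline for foresters and quantitative ecologists working with
stem-mapped plots:

1. **Data model and filters** (`stand_io`) — per-tree records (position,
   DBH, TH, HCB, HCW, CW, AGE) plus crown radii measured in the four
   cardinal directions at RCH = 0.25, 0.5, 0.75, 1.0; trees with radii
   recorded above RCH 1.0 or with fewer than four valid radii per direction
   are excluded.  Derived variables: `LCL = TH − HCB`, crown-length ratio
   `CLR = LCL/TH`, slenderness `TSC = TH/DBH`, stand basal area `BA` and
   Reineke's stand density index `SDI = N_ha (Dg/25)^1.605`.
2. **Profile interpolation** (`profile_interp`) — shape-preserving PCHIP
   interpolation of each direction's four measurements (plus the zero-radius
   treetop anchor) onto the uniform grid RCH = 0.0, 0.1, …, 1.0, giving
   radii `CR_0 … CR_10`.
3. **Competition** (`competition`) — competitors are trees whose Voronoi
   cells share an edge with the subject's cell (cells clipped to the plot
   circle).  Crowns at each layer are discs; two layers compete when their
   crown heights from the treetop differ by at most 2 m.  With `AO_i(k)` the
   gated overlap area summed over competitors and layers,

       CPCI_k = (1 / π CR_ik²) · Σ_j Σ_t AO_ij(k,t) · (CH_jt CR_jt) / (CH_ik CR_ik)

   and the directional allocation
   `CPCI_dir(k) = CPCI_k (1 − CR_dir / Σ_dir CR_dir)`, which hands larger
   shares of the competitive pressure to the directions where the subject's
   own crown is smaller (the four shares always sum to `3·CPCI_k`).
4. **Features and models** (`features`, `models`, `nn`) — per tree a
   10-step sequence (layers k = 1…10, top to base) of 14 predictors (AGE,
   DBH, TH, CW, HCW, HCB, CH_k, LCL, TSC, CLR, BA, SDI, the lagged radius
   CR_(k−1), CPCI_k), min-max normalised on the training split (8:1:1 by
   tree).  Three architectures with per-step output heads, trained with
   Adam + early stopping; hyperparameters (filters 32–256, LSTM units
   32–128, learning rate 1e-5–1e-2, batch size 16–64) tunable by particle
   swarm optimisation (`pso`).
5. **Evaluation** (`evaluate`) — MSE, RMSE, MAE, ME and R² in metres over
   pooled tree×layer records, condition/direction report tables, and
   permutation feature importance.
6. **Synthetic stands** (`synthetic`) — a calibrated generator (hard-core
   stem placement, lognormal DBH, power-function profiles, south-largest
   directional asymmetry, crowding-dependent crown reduction) so the whole
   pipeline is testable without field data.

## Worked example

```bash
crownprof --seed 4 run-all --n-plots 4 --n-trees 125 --max-epochs 200 --out demo/
```

simulates four 125-tree plots, computes profiles and CPCI, trains the three
architectures with and without the CPCI feature (about a minute on one CPU),
and prints (numbers from this exact command):

```
arch                 dir   CPCI   MSE(m²)    RMSE(m)    MAE(m)     ME(m)      R²
cnn_lstm             mean  no     0.00010    0.00991    0.00702     0.00078   0.99854
cnn_lstm             mean  yes    0.00015    0.01223    0.00737     0.00122   0.99777
cnn_lstm_attention   mean  no     *0.00005*  *0.00689*  *0.00431*  * 0.00035* *0.99929*
cnn_lstm_attention   mean  yes    0.00008    0.00904    0.00568     0.00119   0.99878
vanilla_lstm         mean  no     0.00017    0.01286    0.00878    -0.00196   0.99754
vanilla_lstm         mean  yes    0.00025    0.01573    0.01148    -0.00134   0.99632
```

Each row is one condition cell evaluated on the held-out test trees: e.g.
the first row says the CNN-LSTM without CPCI predicts layer radii with a
root-mean-square error of 9.9 mm and explains 99.85% of the radius
variance; stars mark the best value per column.  The attention model leads
every error column and both hybrid models beat the plain LSTM.  Single runs
at this scale sit near the generator's 5% measurement-noise ceiling, so the
effect of the CPCI feature is within seed noise here; the multi-seed
analogue experiment run by the acceptance script (below) is the right place
to read it.

The same stages are scriptable individually (`simulate`, `cpci`,
`features`, `train`, `tune`, `evaluate`) or callable as a library
(`crownprof.pipeline.prepare_stand`, `run_experiment`, `recovery_suite`).

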