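# Methods

## Model

`gridrisk` fits a two-dimensional LSTM over a raster of city cells. The
recurrence is a single raster scan (row by row, west to east): cell (t, s)
sees the outputs h and states C of its north (t−1, s) and west (t, s−1)
neighbours; out-of-grid neighbours contribute zero vectors. One forget gate
per incoming direction (f1 north, f2 west) weights how much accident
potential is inherited from each neighbour, the input gate i weights the
locally generated candidate state S = tanh(W_C·I + b_C), and the output
gate o converts the accumulated potential C into the observed
characteristics h = o ⊙ tanh(C). All five weight matrices act on the
concatenation I = (x, h_north, h_west) ∈ R^16 and are shared by every
cell, which is what makes the weight-matrix summaries interpretable as
area-wide rules.

Assumptions worth stating explicitly:

* **One scan direction.** Information flows south-east only. This is a
  modelling choice, not a physical one; it keeps the recurrence acyclic and
  trainable in one pass. Influence from the south/east neighbours is not
  modelled.
* **Hidden width = output width (5).** h is read *directly* as the five
  scaled accident characteristics, with no read-out layer. This identifies
  each latent channel of C with one characteristic (the basis of the
  interpretation machinery) at the cost of model capacity.
* **Range mismatch, kept deliberately.** Targets are min–max scaled to
  [0, 1] while h = o·tanh(C) lives in (−1, 1). No output rescaling is
  applied; the fit resolves the mismatch by occupying the positive part of
  the range. Potential maps report C on this internal scale by default; the
  inverse-scaled view is a labelled convenience, since C is a latent sum
  that need not stay inside the target range.
* **State growth.** C is not clipped or normalized. When f1 + f2 < 1
  elementwise the recursion is contractive (‖C‖∞ ≤ max‖i⊙S‖∞ / (1 −
  max(f1+f2)), asserted numerically in the tests); with wide-open forget
  gates C can grow along a scan, which tanh in the output absorbs.

## Data pipeline

Accident records are encoded before aggregation: dates become the day
distance to the nearest winter solstice (22 December; 0–183 on real
calendars, computed with leap years), times the same-day second distance to
15:00 (0–54 000), and the two road-layout labels ordinal levels (isolation
1–4, cross-section 1–5, closed vocabularies). Each cell receives the count
of events within 3000 m of its centre and the *unweighted mean* of each
encoded characteristic over those events; the mean is the least-structured
aggregator and is the package's choice where no rule is prescribed. Cells
with no event in radius are masked missing.

Windows of 9 × 9 cells are cut at stride 1. A window is unusable when its
missing fraction is ≥ 0.80 (the boundary is deliberately strict-at-the-
threshold). The test split (default 100 windows) is drawn uniformly without
replacement. Min–max scaling statistics are fitted only on observed cells
covered by at least one training window and then applied everywhere, so
the held-out windows leak nothing into preprocessing; missing cells inside
usable windows are imputed as 0 after scaling and excluded from the loss by
the mask. Loss is computed on the central 3 × 3 block only, which insulates
the fit from the zero boundary of each window.

## Spatial statistics

Global Moran's I and Geary's C are computed on rook (default) or queen
contiguity, binary (default) or row-standardized, restricted to observed
cells. Inference uses the closed-form normality-assumption variances;
one- and two-sided p-values are both reported, and a Monte-Carlo
permutation null is available. The checkerboard identities (I = −1,
C = 2(n−1)/n on a ±1 board with binary rook weights) and the permutation
mean E[I] = −1/(n−1) serve as exact oracles in the tests.

## Training

Adam on the masked central-block MSE, default minibatches of 128 at
learning rate 5·10⁻³ for 200 epochs, all configurable. Backpropagation
through the 2-D recurrence is implemented explicitly (reverse raster
order, accumulating gradients through both the h-concatenation and the
C-transfer paths) and validated against central finite differences; the
comparison floors the per-component denominator at 10⁻⁴ because central
differences at step 10⁻⁵ resolve derivatives only to ~10⁻¹¹.

Two defaults were chosen against the obvious textbook settings, after both
failed visibly:

* **Minibatch rather than full batch.** Full-batch Adam takes one step per
  epoch; at 200 epochs it stalls an order of magnitude above the achievable
  recovery error. Minibatching reaches the noise floor in the same number
  of epochs.
* **Small uniform init (±0.1), forget biases 0.** Glorot-scaled init, and
  a +1 forget-bias init, both occasionally start the recurrence saturated
  on strongly coupled data (the output feeds back into the next cell's
  input, so large weights compound along the scan); some seeds then
  plateau at ~30× the achievable error. The small init removed every such
  failure in a 10-seed probe. Teachers (below) keep Glorot scale and ±1
  forget biases — generators should be expressive, students robust.

Baselines share the loss protocol and hidden width 5: a per-cell
feedforward net with one tanh hidden layer (BPNN — purely local), and 1-D
tanh-RNN / LSTM recurrences along each row independently (spatial coupling
in one direction only). They are minimal members of their families, with
parameter budgets of the same order as the grid model, and each baseline's
backward pass is finite-difference checked.

## Synthetic city (what it does and does not emulate)

Land-use channels are white noise convolved with a Gaussian kernel
(`correlation_length`, default 2000 m ≈ 5 cells) and affinely rescaled to
the published per-channel ranges (e.g. plot ratio exactly [0, 6.62]), so
each channel is positively spatially autocorrelated by construction — the
property the real rasters exhibit and the one the autocorrelation stage
must detect. Events are a point process with intensity exp(z̄/2) of the
standardized channels; dates mix a point mass on the winter solstice
(weight 0.6) with a uniform background; times mix a uniform 13:00–17:00
block (weight 0.55) with a uniform day; labels are categorical with
urban-plausible frequencies.

Not emulated: real street geometry and networks, the actual seasonal
*spread* around the solstice (the point-mass winter component is a
deliberate degenerate simplification), label–location dependence, and any
particular city's layout. Passing tests therefore demonstrate pipeline and
estimator correctness under controlled spatial structure, not predictive
validity on any real city.

Teacher experiments generate targets by running a known random parameter
set forward over scaled land-use windows (independently per window, zero
boundaries — exactly the student's conditions) plus Gaussian noise
(sd 0.02), clipped to [0, 1]. The teacher's candidate-state bias is +0.5
so its outputs occupy the clip-free part of the range; `coupled=True`
teachers use +1 forget biases, making neighbour transfer the dominant
term. Recovery is measured as held-out central-block MSE relative to
target variance; the noise floor is sd² = 4·10⁻⁴.

## Problem sizes

The shipped experiments use a 53 × 53 city (2 000 windows, 100 held out)
for recovery and 31 × 31 cities (529 windows) across 5 seeds for the
model comparison at 80 epochs — sizes at which every effect tested is
comfortably resolved on a single CPU in minutes. The acceptance script
uses a 48 × 48 city with 4 000 events for the autocorrelation stage.

## Known limitations

* Interpretations of gates as "proportions of influence" are heuristic
  reads of a nonlinear model, not causal estimands.
* The single scan direction induces an asymmetry (north/west vs
  south/east) that is an artifact of cell ordering.
* The aggregation of characteristics within 3000 m smooths sharply
  localized effects; radius and aggregator are configurable but fixed per
  run.
* Published reference weight tables are used only to verify summary
  arithmetic (Sum rows within print rounding of ±0.01); the underlying
  study data are not public, so fitted values cannot be compared beyond
  layout and arithmetic.
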