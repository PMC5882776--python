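# Methods

## Logistic reduction kinetics

Cumulative anaerobic reduction processes are modelled with the
three-parameter logistic

C(t) = a / (1 + b·e^(−kt))

where *a* (series unit) is the maximum capacity of the process — Fe(II)
accumulation, or sulfate/PCP decrement — *b* (dimensionless) locates the
curve in time, and *k* (d⁻¹) is the rate constant.  The instantaneous
rate dC/dt is maximal at the inflection point, giving the two derived
statistics reported per fit:

* V_max = 0.25·a·k (series unit per day),
* t_Vmax = ln(b)/k (days), where C(t_Vmax) = a/2.

Both identities are exercised as properties (dense numerical
differentiation agrees with 0.25·a·k to 1e−9 relative; the curve passes
through a/2 at t_Vmax).

**Decrement transform.** The logistic applies to *cumulative* quantities,
so decreasing analytes (nitrate, sulfate, PCP) are first transformed to
`baseline − value`.  The baseline defaults to the value at the earliest
time point; when the initial pool is known from the design it should be
passed explicitly, otherwise the fitted capacity is biased low by the
amount already consumed at t = 0.  Values exceeding the baseline by up to
2% of the baseline (measurement jitter) are clipped to zero decrement;
larger excursions raise an error rather than being silently absorbed.

**Fitting.** Bounded trust-region nonlinear least squares (scipy's TRF)
with positivity constraints on all three parameters, relative tolerances
1e−10, at most 10 000 evaluations per start.  Initialisation matters:
curves that sit at zero through an onset lag admit a spurious
step-function local minimum (k → large, b → huge) that a naive start
from b₀ = a₀/C(0) − 1 falls into.  The fitter therefore derives its
primary start from the half-maximum crossing time t₅₀ — k₀ from the
slope of the logit-linearised interior, b₀ = e^(k₀·t₅₀) so the candidate
passes through a₀/2 at t₅₀ — and polishes a small deterministic set of
alternative starts (±2× on k₀, plus the C(0)-based guess), keeping the
lowest sum of squares.  Fits report R² = 1 − SS_res/SS_tot and an honest
convergence flag; series with fewer than 4 distinct times or constant
values are rejected up front.

**Replicates** are averaged pointwise before fitting by default; pooled
fitting of raw replicate points is available as an option.

## Electron-equivalent balance

Per mole of acceptor reduced the half-reactions transfer Fe(III): 1,
NO₃⁻ (to N₂): 5, SO₄²⁻ (to sulfide): 8 electron equivalents; reductive
dechlorination transfers 2 eeq per C–Cl bond reduced.  Complete oxidation
of lactate to CO₂ donates 12 eeq/mol, so the standard microcosm design —
20 mM lactate in the 0.015 L aqueous phase of a 15 g soil, 1:1 (w/v)
slurry — adds 20 × 0.015 × 12 = 3.60 mmol eeq.

Dechlorination accounting offers two modes.  The default,
`per_chlorine`, charges 2 eeq for every chlorine removed across the whole
congener distribution (150 µM PCP fully converted to 3-CP in 0.015 L:
2.25e−3 mmol × 4 Cl × 2 = 0.018 mmol eeq), and is the mode consistent
with observed ledger magnitudes (~0.02 mmol).  The alternative,
`per_molecule`, reads "2 eeq per mol acceptor" literally (0.0045 mmol for
the same conversion).  Both are implemented; neither is asserted to be
the uniquely correct bookkeeping, and the dechlorination profile check
enforces phenol-skeleton conservation before any eeq is computed.

Ledger totals are exact sums of their pathway components.  A consumed
total *can* exceed the donor eeq in strongly amended systems — indigenous
soil organic carbon also donates — so the budget-sanity property
(consumed ≤ added) is asserted only for the unamended configuration,
where the donor dominates.

Background soil sulfate defaults to 6.67 mM in the slurry, obtained from
a soil content of 640.9 mg SO₄²⁻ per kg dry soil at 15 g soil per
0.015 L water.

## Congener model and pathway inference

A chlorophenol congener is the set of ring positions bearing chlorine,
with the hydroxyl fixed at position 1; positions 2/6 are *ortho*, 3/5
*meta*, 4 *para*.  Names follow lowest-locant convention
("3,4,5-TCP", "PCP" for the full set, "phenol" for the empty set) and
name/position-set conversion is a verified bijection over all 32 sets.
Mirror-symmetric sets (e.g. {2,3,4,5} vs {2,3,4,6}) are deliberately not
merged: analytical standards distinguish them, so the package does too.

A dechlorination step is valid iff the child's positions are a strict
subset of the parent's with exactly one element removed (checked
exhaustively against a brute-force subset oracle over all 32×32 pairs).
Observed chains are ordered by first-detection time above a configurable
threshold (default 1 µM); ties on the coarse sampling grid are broken by
descending chlorine count, since a parent is detectable no later than its
product.  The package only books observed chains — it does not predict
regioselectivity.

## Chain kinetics

Metabolite cascades are modelled as an irreversible linear chain of
first-order reactions with an optional hard onset lag (default 3 d,
matching the 3–7 d acclimation commonly seen before dechlorination
starts; the state is frozen at the initial condition for t < lag).  With
all decay constants distinct (terminus decay constant 0) the closed-form
Bateman solution is used; rate collisions within 1e−8 relative fall back
to adaptive numerical integration (LSODA, rtol 1e−9).  Equivalence of the
two routes on random rate vectors in [0.05, 1.0] d⁻¹, total-mass
conservation to 1e−9 relative, and unimodality of intermediate
trajectories are property-tested.  Rate fitting optimises log-rates
(guaranteeing positivity) by Levenberg–Marquardt against any subset of
≥ 2 observed species with ≥ 5 time points.

## Synthetic microcosm generator

The generator emulates one treatment of a lactate-amended PCP microcosm
and records its ground truth.  Defaults define the reference study
conditions:

| parameter | default | rationale |
|---|---|---|
| soil, water, lactate, PCP | 15 g, 0.015 L, 20 mM, 150 µM | standard slurry design |
| sampling | days 0, 3, 7, 12, 17, 22, 40; triplicate | typical 40-day incubation schedule |
| noise | multiplicative Gaussian, CV 3%, truncated at 0 | analytical recoveries of 92–106% imply a few-percent error scale |
| nitrate | zero-order depletion, gone by day 3 | denitrification outcompetes all other pathways |
| sulfate truth | logistic, a = 0.9 × pool, b = 9.03, k = 0.21 d⁻¹ | ~90% reduction of the available pool over 40 d |
| Fe(II) truth | logistic, a = 119.74 mM, b = 179.09, k = 0.76 d⁻¹ | HCl-extractable Fe(II) scale of iron-rich paddy soils |
| chain rates | 0.20, 0.55, 0.25, 0.40 d⁻¹, lag 3 d | head rate from ~75% PCP loss by day 12 and <10% residual by day 17; fast TeCP/DCP steps keep them transient so TCP and 3-CP dominate, as observed |
| inhibition | rate factor 1/(1 + 0.02·SO₄ + 0.01·NO₃) (mM) | 0.02/mM lengthens the fitted PCP t_Vmax by ~20% at 20 mM sulfate; nitrate weaker per mM |
| molybdate | caps sulfate decrement at 25% of the pool | ATP-sulfurylase inhibition plateau |

Randomness uses a single `numpy` Generator stream seeded from the
mandatory config seed; replicates consume the stream in fixed order, so a
config is byte-reproducible.  The inhibition factor is phenomenological:
the generator encodes the *direction and magnitude* of competitive
suppression, not its community-level mechanism, and applies one constant
factor to all chain steps.

What the generator does **not** emulate: time-varying inhibition (real
suppression fades as sulfate is consumed), non-Gaussian or
heteroscedastic analytical error, sorption/desorption kinetics, branching
dechlorination pathways, methanogenesis, and any microbial community
dynamics.  Passing recovery tests therefore demonstrates that the
estimators are consistent under the stated generative model — not that
real microcosms satisfy that model.

**Validation harness.** `truth_recovery_report` fits the logistic to the
replicate-mean sulfate decrement (against the known initial pool) and
Fe(II) accumulation, infers the congener chain, and tabulates relative
errors against truth.  Under the default conditions (CV 3%, 7 time
points, triplicate) the capacity *a* is recovered within 5% and *k*
within 10% at the frozen validation seeds, and the inferred class
sequence is exactly ortho, ortho, para, meta.  A 100-pair Monte-Carlo
check confirms the fitted PCP t_Vmax of a 20 mM sulfate arm exceeds the
control's in ≥ 95% of seeded dataset pairs.

## Numerical and interface choices

* Reported kinetics round to 2 d.p. and ledgers to 3 d.p.; all internal
  computation is double precision.
* Tidy CSV (treatment_id, analyte, replicate, time_d, concentration,
  unit) is the single interchange schema; the unit column is mandatory
  and mixed units within one series are an error, never a guess.
* Outputs refuse to overwrite existing files without an explicit force
  flag; validation failures raise typed errors naming the offending
  field, row or pair.
* The problem sizes used throughout (7-point grids, triplicates, 100
  Monte-Carlo pairs) are the reference study conditions; estimator
  behaviour at other scales is covered by the grid-density property test.

## Known limitations

* The logistic capacity of a decrement series is only identifiable up to
  the assumed baseline; supply the designed initial pool where known.
* Nitrate's 3-day depletion leaves ≤ 2 points on the ramp, so logistic
  fits of nitrate decrement are possible but weakly constrained; the
  generator treats denitrification as zero-order instead.
* 3-CP is modelled as the chain terminus because nothing beyond it is
  observed; the package does not assert that further dechlorination is
  impossible.
* The constant inhibition factor cannot reproduce both early suppression
  and late convergence of amended treatments; it targets the
  inflection-time shift only.
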