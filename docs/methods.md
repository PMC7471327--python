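# Methods

## Problem and data model

The unit of observation is an administrative booking record: patient id,
gender, age at prescription, prescription date, appointment date, status,
facility id and health-service provision id.  The prediction task is
multi-label: given a patient's bookings over 52 consecutive weeks, predict
for each of a fixed set of 10 facilities whether the patient has at least
one appointment there in the following 9 weeks.  An 11th label aggregates
all remaining facilities; it exists because the pairwise ranking loss
(below) is undefined for all-zero label vectors, and the window-extraction
rule (at least one forecast-period booking) then guarantees every kept
window has a non-zero label.

## Cleaning

Five rules are applied in a fixed order, each removed record attributed to
the first rule that fires: (1) blank/unknown patient, provision or
facility identifiers (the sentinel set `{"", "UNKNOWN", "NA"}` is
configurable — real databases mark encoding errors in idiosyncratic
ways); (2) only `Valid` status kept; (3) patients with fewer than five
remaining records dropped; (4) records with no appointment date dropped;
(5) records with appointment before prescription (negative waiting time)
dropped.  Cleaning is idempotent and fully audited (`CleaningReport`).

## Featurization

**Calendar.** Weeks are consecutive 7-day blocks anchored at the
configured period start, 1-based; `T = ceil(days/7)`.  The week count is
always computed from the period, never hard-coded.

**Weekly matrices.** Per patient, sparse `T × n_provisions` and
`T × n_facilities` count matrices (scipy CSR).

**Windows.** Every start week `w` (stride 1) yields a candidate
52-week window plus 9-week forecast slice.  Kept iff the window has
bookings in ≥ 4 distinct weeks and the forecast slice has ≥ 1 booking.
The implementation uses cumulative sums; a brute-force per-start-week
checker serves as its test oracle.

**Provision clustering.** Provisions are described by seven statistical
features (relative frequency, distinct patients, mean/sd of patient age,
mean weekly count, week coverage, mean waiting days), standardized, and
k-means-clustered (k-means++ init, 10 restarts, seeded) into k = 8
clusters.  k is adopted as a fixed upstream result; a silhouette-based
selection utility is included for synthetic-data sanity checks only.

**Facility columns.** Facilities are ranked by total appointments in the
extracted windows' forecast slices (ties broken by lexicographic id).  The
top 10 become columns 1–10; other facilities in one of the top-10's
districts map to that district's group column; the remainder map to a
rest-of-universe column.  With real-world-like data the top 10 span 8
districts giving 19 columns, but the layout adapts: if the synthetic top
10 span fewer or more districts, downstream shapes follow the catalog
(nothing assumes 19).

**Scaling.** Counts pass through `φ(x) = 1 − λ^{−x}`, `λ = e/2 ≈ 1.3591`.
φ(0) = 0, φ is strictly increasing with strictly decreasing increments,
so differences among small counts dominate.  φ is applied to the model
inputs `P` and `F` only; the forecast matrix stays in raw counts because
it exists solely to produce labels (φ preserves zero/positive, so labels
would be unchanged anyway).  Age is `clip(age, 0, 120)/120`, with age
taken as the window's first calendar year minus the estimated birth year
(minimum over records of prescription year − age at prescription).

**Rebalancing.** Windows whose only positive label is the 11th (no top-10
visit) dominate realistic data; before each run they are down-sampled
uniformly to 1/7 of their number, raising every top-facility label's
relative frequency.

## Network

Four temporal blocks: `P` (52×8) and `F` (52×19) each through a
max-pooling and an average-pooling block.  Per kernel size
`s ∈ S = {6, 9, …, 51}` a block applies 64 filters spanning `s` weeks and
all columns with "same" zero padding (for even `s` the extra pad element
is placed at the sequence end — a convention pinned by a test), tanh
activation, 2×1 pooling with stride 2, elementwise summation of the 64
pooled vectors, and concatenation across `S`.  Block output length
`n_S · t/2 = 16·26 = 416`; dense-head input `4·416 + 2 = 1666`; head
layers 128 → 32 → 11, all tanh.

Choices the architecture description leaves open, fixed here: tanh for
convolutional, hidden and output activations (the convention of the
original pairwise multi-label backpropagation scheme, whose exponential
pairwise loss needs no ±1 label recoding because only the index sets
`Y`/`Ȳ` enter); pooling stride equal to pool size 2 (forced by the stated
t → t/2 reduction); Glorot-uniform initialization.  Adam with learning
rate 1e-3, batch size 64, early-stopping patience 5 (restoring
best-validation weights) — defaults chosen as standard practice since no
values are prescribed; all configurable.  Samples with all-ones label
vectors are excluded from the loss (counted in the training log) but kept
for evaluation.  Divergence (non-finite loss) aborts with diagnostics.

The BP-MLL gradient is computed analytically and verified against central
finite differences.  Forward/backward passes are vectorized NumPy
(im2col convolution via `sliding_window_view` + matmul); weights are
float32, loss/gradient accumulation float64.

**Thresholds.** After training, per label j independently,
`θ_j = argmin FP(θ) + FN(θ)` on the validation set, candidates being
midpoints between consecutive sorted unique scores plus below-min /
above-max sentinels, ties resolved to the smallest candidate; prediction
is `score > θ_j`.  Labels constant in validation get a sentinel threshold
(all-negative or all-positive) and are logged.

**Baselines.** A single multi-output random forest (not 11 independent
forests — one model per method) and a dense MLP, both on the flattened
`52·8 + 52·19 + 2 = 1406` vector; the MLP shares the BP-MLL loss, early
stopping and threshold-calibration code path with the network.  The
forest thresholds per-label probabilities at 0.5 (threshold calibration
belongs to the ranking-loss networks).

## Evaluation

Mean Hamming distance `d_H(y, ŷ) = |{j : y_j ≠ ŷ_j}|` averaged over
windows; exact accuracy (whole 11-label vector correct) and top-10 exact
accuracy (last label ignored); per-label accuracy, precision, recall, F1
from confusion counts; AUC as the Mann–Whitney rank statistic (ties
counted half), which equals trapezoidal ROC integration — pinned by a
property test against an independent implementation.  "Overall" metrics
are micro-averaged (pooled counts / pooled score–label pairs) because the
labels are strongly unbalanced; macro variants are emitted alongside so
the averaging choice stays visible.  Undefined quantities (empty
precision denominator, constant-label AUC, empty first-access subset) are
flagged, never silently zeroed.

First-access accuracy for facility j restricts to test windows with an
all-zero 52-week column j but `y_j = 1` and reports the fraction predicted
positive — recall on that subset, the only metric the subset definition
supports (every member is a true positive candidate).  The attendance
lower bound compares, per facility, the predicted-positive count with the
actual positive count; their ratio is the conservative coverage of true
demand.

Experiments repeat over n seeded runs (window-level shuffling, rebalance,
split, train, calibrate, evaluate) and report mean ± sd.  Splits are
0.72/0.18/0.10 (train/validation/test) for the networks and 0.90/0.10 for
the forest.  Window-level splitting can place overlapping windows of one
patient in train and test; this is the faithful default, and a
`split_by_patient` option removes the leakage for sensitivity analyses.

## Synthetic data generator

The generator emulates an administrative booking database, not clinical
reality: power-law facility popularity and provision frequencies
(exponents calibratable — `calibrate_provision_exponent` matches a target
top-50 cumulative frequency such as 0.59), gamma-distributed per-patient
weekly Poisson rates (defaults shape 1.5, scale 0.12 → ≈ 0.18
bookings/week, ≈ 28 over three years — a plausible outpatient intensity),
geometric prescription-to-appointment waits (mean 10 days), Bernoulli(0.5)
gender, uniform birth years 1930–2010.  Two mechanisms create learnable
temporal signal: *facility loyalty* (each booking is at the patient's home
facility with probability 0.8 by default) and *revisit bursts* (with
configurable probability a booking spawns a follow-up at the same facility
4–12 weeks later).  Contamination rates inject invalid statuses, negative
waits and blank facility ids to exercise cleaning.  Everything derives
from one seed; output files are byte-identical across runs.

What it does **not** model: diagnoses or outcomes, seasonality,
practitioner effects, facility capacity limits, correlated provision
sequences, patient relocation.  Passing tests therefore demonstrate that
the pipeline recovers planted booking-pattern signal, not that the model
attains any particular accuracy on real administrative data.

## Problem sizes and numerical choices

The default generator preset (2,000 patients, 3 years) runs in seconds; a
larger five-year preset exists for bigger experiments.  The
signal-recovery setting used by the verification suite and the acceptance
script uses 80 patients with loyalty 0.9 and burst 0.6, yielding ≈ 5,000–
6,000 windows, and a reduced network (kernel sizes {6, 12, 18, 24}, 8
filters, patience 3, ≤ 40 epochs) — sizes chosen so a single-CPU run
completes in minutes while leaving the architecture's structure (four
blocks, multi-size kernels, dual pooling, shared head) intact.  The full
default architecture (64 filters, 16 kernel sizes) is exercised
shape-exactly; training it is a matter of compute, not of different code
paths.

Tie-breaks and degenerate inputs are all deterministic and documented in
code: facility ranking ties by id, gender-mode ties to 0, threshold ties
to the smallest candidate, k-means determinism via seed + 10 restarts.

## Known limitations

- No GPU path and no hyperparameter search — both out of scope by design.
- The provision-cluster count (8) and the statistical feature set for
  clustering are adopted conventions, not re-derived.
- Real-data headline numbers cannot be reproduced without the proprietary
  source database; the package substitutes oracle equivalences and
  synthetic-signal recovery, and the generator makes no claim to match
  the real distributions beyond their qualitative shapes.
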