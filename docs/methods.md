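# Methods

## Data model and ingestion

A proximity logger row carries (focal, partner, start, end, duration).
Timestamps have 1 s resolution and day-first dates; the duration column is
redundant and is cross-checked against the timestamp span at parse time —
a mismatch is a validation error naming the row, because it indicates
clock drift or truncation that no downstream step could repair. Rows
naming animals outside the triad manifest are rejected with a per-row
report rather than an error (neighbouring collars occasionally appear in
real streams).

Time zero is the introduction of the unfamiliar animal (code 3) to the
resident pair (codes 1 and 2). Records ending at or before time zero are
dropped; records straddling it are clipped to start at 0.

**Reciprocal compression.** Both collars of a dyad can report the same
encounter with slightly different boundaries. We take, per dyad, the union
of all reported spans, merging overlapping or abutting half-open intervals
[onset, offset) into maximal disjoint intervals. The union is the most
permissive contact definition — the dyad is in contact during every second
at least one collar says so — and is idempotent, which the property tests
exploit. Whether discrepant reciprocal reports should instead be resolved
by, say, keeping the longer report is an open choice; the union was chosen
once and is not configurable.

**Onset tie-breaking.** Downstream, event order must be total. Coinciding
onset seconds are resolved by shifting the 2nd..k-th onset forward by
+1..+(k−1) s, ordering coinciding onsets by dyad code (1,2) < (1,3) <
(2,3); a shift cascades past seconds that are already occupied. The dyad
ordering is arbitrary but deterministic — any fixed order reproduces the
same event stream on re-runs. An offset is moved along only when the shift
would otherwise empty its interval. Because intervals are processed in
(onset, dyad) order, assigned onsets are strictly increasing, so per-dyad
ordering is preserved and onsets end up globally distinct.

## Event classification

The triad state is the set of currently active dyads. Onsets from the
empty state are *pair* events; from a one-tie state *group* events (the
lone animal necessarily joins one member of the standing pair); from a
two-tie state the closing onset is a *triangle* event. Offsets are
classified by the number of ties they dissolve out of. At the same second
offsets are processed before onsets, so "group" always means joining ties
that are genuinely contemporaneous.

Triangle onsets are counted in summaries but never modelled: from a
two-tie state the closing onset is the only onset possible, so it carries
no information about which event was chosen over which alternatives.

**Day boundaries.** Fits are stratified by day. The default `calendar`
grid uses local calendar days, day 1 being the (partial) day of the
introduction; a `fixed` grid of 24 h blocks from time zero is available.

## History statistics and risk sets

Each candidate onset at time t gets five statistics:

| statistic    | meaning                                                          |
|--------------|------------------------------------------------------------------|
| `unfam`      | 1 if the candidate dyad involves the unfamiliar animal           |
| `pair_hour`  | candidate dyad's pair onsets in (t−3600, t)                      |
| `pair_day`   | candidate dyad's pair onsets in [day_start, t)                   |
| `group_hour` | group onsets in (t−3600, t) whose resulting two-tie configuration included the candidate dyad |
| `group_day`  | the same over [day_start, t)                                     |

Conventions that needed fixing once: windows never cross a day boundary
(history restarts each day; on the introduction day, "the day so far" is
everything since time zero); the hour window is open at its lower end, so
an event aged exactly one hour has just expired, making hourly counts
strictly nested within daily counts; and a group event credits exactly the
two dyads of the configuration it produced — the co-present but untied
third dyad gets no credit, since the statistic is meant to capture "these
two animals were together as part of a group".

Pair strata have three rows (all dyads are candidates from the empty
state); group strata have two (the two ways the lone animal can join).
Each stratum has exactly one realized row.

**Normalization.** Within one fitted dataset the four count columns are
centred and scaled to unit sample standard deviation (constant columns
become zeros); `unfam` stays on its natural 0/1 scale so its coefficient
remains a familiar-vs-unfamiliar contrast. Centring is cosmetic — any
per-dataset column shift is constant within every stratum and cancels in
the conditional likelihood — but the scaling makes effect sizes comparable
across days and between the two timescales.

## Estimation

The conditional-logit log-likelihood
ℓ(θ) = Σ_s [θ·s_realized − log Σ_rows exp(θ·s_row)] is concave and is
maximised by Newton–Raphson with the analytic gradient and observed
information, a step-halving safeguard, and convergence at gradient
max-norm < 1e−8 or step < 1e−10. Probabilities are computed with
max-subtraction so extreme linear predictors cannot overflow. The null
log-likelihood has the closed form −Σ_k n_k log k (k = stratum size) and
is computed that way. Standard errors are the square roots of the inverse
information diagonal; Wald z-tests use the normal reference, starred at
0.05 and 0.01 two-sided.

Degenerate inputs are reported, not papered over: a singular information
matrix raises an error naming the collinear or constant columns (a
zero-variance normalized column is the common cause on sparse days), and
separation — an estimate running away past |θ| = 15 with the gradient
still pushing outward — is returned as a non-converged fit whose message
names the offending effect. The per-day command-line driver records such
day × model cells as skipped/failed in its results file.

## Generative simulator

The simulator runs the triad in continuous time over the same state
space. From the empty state each dyad d starts a contact at rate
exp(β0_pair + θ_pair·s_d(t)); from a one-tie state each of the two joining
dyads at rate exp(β0_group + θ_group·s_d(t)); from a two-tie state the
closing triangle onset occurs at the bare group baseline (it is generated,
never modelled). Active ties dissolve independently at a constant hazard —
onset formation is the modelled process, so dissolution is deliberately
covariate-free. The statistics s_d are the unnormalised history counts
defined above, recomputed from the realized history with the same day
resets and hour-window expiries; rates are therefore piecewise constant
and sampling uses competing exponentials with re-sampling at every rate
breakpoint (event, window expiry, day boundary), which is exact for
piecewise-constant intensities.

Event times are recorded on the integer-second logger clock, strictly
increasing, and every recorded contact lasts at least the 2 s the
ingestion filter keeps. This makes the round-trip contract exact:
re-ingesting the emitted logger files reproduces the true event stream
event for event. The costs are negligible at the default rates: a recorded
time can be bumped by ≤1 s when two events would share a second, and a
dissolution can be held to the 2 s minimum. An optional reciprocal-noise
mode adds the partner collar's duplicate report with up to 2 s of *inward*
boundary jitter — duplicates are subsets of the primary report, so
compression recovers the primary intervals exactly while still exercising
the merge logic.

The baseline log-rates exist only in the generator; the conditional
likelihood is invariant to them, which the recovery tests exploit.

**Default parameters.** Defaults emulate the motivating cattle
experiment's design and observed volumes: 36 triads, introduction at
mid-day followed by monitoring to the end of day 5 (day 1 is a half day),
β0_pair = −8.7 and β0_group = −6.9 (≈35 pair and ≈12 group onsets per
triad-day, group ≈ a third of pair volume, triangles a few percent of
group events), dissolution hazard 0.01 s⁻¹ (mean bout ≈ 100 s),
θ_pair = (−0.5, 0.05, 0.02, 0.03, 0.01) and
θ_group = (0.5, −0.05, 0.02, 0.04, 0.01) on the raw count scale —
a familiarity advantage in pair formation, the unfamiliar animal
over-involved in group formation, and mild positive history dependence.
History coefficients are kept small because daily counts feed back into
rates within a day; large positive values make the process self-exciting
to the point of blow-up, which the simulator guards against by refusing
log-rates beyond ±30.

What the simulator does *not* emulate about real loggers: detection
dropouts and range asymmetries beyond boundary jitter, spatial movement,
diurnal activity rhythms, or battery effects. Passing recovery tests
therefore demonstrate that the estimator inverts the model's own
generative process at realistic scale — not that the model is correctly
specified for any particular field data set.

## Parameter recovery and calibration

The generator uses raw counts, the fit z-scaled ones, so the recovery
target for each count effect is θ_raw × (realized sample SD of its
column); `unfam` is compared directly. For recovery experiments the
strata of a study are pooled over days and triads into one dataset per
model type (the per-day stratification exists for substantive, not
statistical, reasons; pooling gives the cleanest large-sample check), and
a nominal 95% Wald interval per effect is compared with the rescaled
truth. The replicated-coverage experiment (120 studies × 200 triads ×
5 days, both models) checks that empirical coverage lies in [0.90, 0.99]
per effect. The band is a band, not a point, and the replication count is
chosen so that the Monte-Carlo error of each coverage proportion
(≈ ±0.02 at 120 replicates) is small against the band's width.

## Problem sizes

The test suite and the acceptance script regenerate everything they
measure. Sizes were chosen as the smallest that make each check
informative: micro-streams (≤5 events) for exact likelihood enumeration,
6-triad studies for the algebraic contracts, 20 single-triad seeds for the
round-trip, 36 triads for the worked recovery example (the design scale of
the motivating study), and 120 × 200 triads for coverage.
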