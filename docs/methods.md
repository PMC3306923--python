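# Methods

## The problem

Biomonitoring studies often have good urinary biomarker data and poor
environmental exposure data. For a pesticide like chlorpyrifos (CPF), whose
specific metabolite 3,5,6-trichloro-2-pyridinol (TCPy) is routinely measured
in spot urine samples, a *reverse dosimetry* approach turns the logic of
pharmacokinetic modelling around: instead of predicting urinary excretion
from measured exposures, it reconstructs the absorbed dose from the measured
urinary excretion. Because a spot urine sample alone cannot identify a dose
profile, the inversion is constrained to a single oral bolus at a known
anchor time — here, dinner at 19:00 of day 1, the dominant dietary intake of
the emulated study design (13 children ages 3–6, two seasons, four spot
voids per 24-h period: before bedtime on day 1; first-morning, lunch and
dinner on day 2).

## Kinetic model

`spkdose.pk` uses the minimal model consistent with an oral bolus and a
stated 16-h biological half-life: one body compartment with first-order
absorption and elimination,

    dG/dt = −k_a G,   dB/dt = k_a G − k_e B,   dU/dt = f_u k_e B,

whose cumulative urinary excretion per unit parent dose is the closed form

    M(τ) = f_u [1 − (k_a e^{−k_e τ} − k_e e^{−k_a τ}) / (k_a − k_e)].

Parameters (units, default, why):

| parameter | default | meaning |
|---|---|---|
| `t_half_elim` | 16 h | elimination half-life of orally ingested CPF; k_e = ln 2 / 16 |
| `k_a` | 1.386 /h | absorption rate constant (30-min absorption half-time, typical of a dietary bolus) |
| `f_u` | 0.7 | fraction of the absorbed parent dose excreted in urine as TCPy; the conventional literature value — it cancels from every ratio-based check |
| `mw_parent` | 350.59 g/mol | CPF; reported doses are parent-equivalents |
| `mw_metabolite` | 198.42 g/mol | TCPy; carried for unit conversions of raw data |

Metabolite moles map 1:1 to parent moles, so the inversion of an observed
window-averaged excretion rate `UER_avg` over the void window `(t_p, t_c)` is

    dose = UER_avg / [ (M(t_c−t0) − M(t_p−t0)) / (t_c−t_p) ] × MW_parent / BW,

linear in the observation and exact (to float tolerance) on noiseless
forward-simulated data. The reconstructed dose is the full bolus attributed
to the anchor exposure, reported per day; no additional 24-h truncation is
applied, since under linearity truncating and rescaling are equivalent and
full-bolus attribution is the only convention that makes the round trip
exact. The removable `k_a = k_e` singularity is lifted by a 1e-9 relative
perturbation of `k_a` rather than a second code path.

## Input records, units and clock

A record holds the nine study variables: subject-period identifier
(`114.1` = subject 114, summer), agricultural-residence flag, average
urinary excretion rate, body weight, route/scenario code (1 inhalation,
2 dermal — recognised and rejected, the oral pathway is the model's
constraint; 3–7 oral bolus slots, with 3 = first-morning, 4 = lunch,
5 = bedtime, 6 = dinner, 7 = unassigned), exposure start/end times, and the
previous/current void times.

Times use a continuous study clock — hours since midnight of day 1, so
day-2 07:00 is 31.0 — which removes the wrap-around ambiguity of a 24-h
clock spanning two days. Canonical internal units are µmol/L, L, hours and
kg; the file stores the excretion-rate column in mmol/hr as a display unit,
converted by an exact decimal exponent shift so table round-trips are
bit-exact. Concentrations reported below detection enter as 0 and yield
dose 0, matching the structural zeros of the reference dose table.

## Missing-data cascade

`resolve_defaults` fills gaps from the most to the least representative
tier and logs every substitution: measured values are never touched;
subject-derived values come next (the void interval from the void volume via
`(V_u / V_avg24)·24`, clamped to (0, 24] with a warning since a spot void
cannot accumulate longer than the daily cycle the formula assumes; the
excretion rate recomputed from concentration × volume / interval);
reference defaults come last (age/sex-graded body weights and 24-h urine
volumes, the scheduled void times 21/31/36/43 h and the 19-h exposure
anchor). The shipped reference tables are editable placeholders (24-h
volumes 500–700 mL, weights 14–23 kg bracketing the study's printed
weights); the original reference sources are external and not reproduced, so
the YAML is config, not ground truth. Age and sex are not part of the
9-variable record (they belonged to the study roster), so the pipeline takes
an optional demographics mapping and otherwise a documented default
(age 5, sex f).

## Composites

Each void yields its own dose estimate for the same day-1 dinner bolus
(lunch and dinner voids of day 2 are anchored at day-1 dinner as a composite
meal exposure). Three daily composites are built per subject-period:

* **SPK I** — the first-morning estimate alone;
* **SPK II** — bedtime + first-morning, volume-weighted mean
  (w_i = V_i/ΣV_i). "Normalised by the volume of each void" is read as
  volume weighting: it is the only reading that uses the volumes and reduces
  to the plain average when volumes are equal. When both doses are present
  but a volume is missing, the fallback is an unweighted mean with a logged
  warning;
* **SPK III** — the unweighted mean of all four voids.

Composites use whatever constituents are available rather than failing —
forced by the reference table's printed pattern, where SPK II/III values
exist for subject-periods whose SPK I is missing. Zero-dose constituents
count as observations. Dinner voids may include day-2 exposure; no
correction is specified for this and none is applied.

## Reporting

`summary_table` gives per-group n, mean, sample SD (n−1), median
(average-of-middle-two), 95% CI (mean ± t_{0.975,n−1}·sd/√n — the source
tables' CI method is unstated and their printed CIs are not exactly
recoverable from the printed means/SDs, so CI cells are not validated), and
min–max; rounding to 2 decimals happens only at presentation. The paired
t-test of each composite against externally supplied PBPK doses and the
one-way ANOVA across composites are computed and logged; the printed
significance levels of the original analysis are not asserted because its
pairing/transform is under-specified and does not reproduce from the
printed per-subject doses.

Known internal inconsistencies of the reference tables, documented and
excluded from validation: the overall SPK II/III means recompute to
1.07/0.93 (printed 0.97/0.87), the overall SPK III median to 0.93 (printed
0.92), the per-season SPK I n's to 9/12 (printed 10/11), and the
community-block labels appear swapped relative to the per-subject table's
R/S legend (the recomputation agrees with the accompanying prose, not the
block labels).

## Synthetic studies

`generate_study` emulates the design so every stage is testable without any
external data: per child, residence is Bernoulli(6/13) (the observed R/S
split), age uniform on 3–6, weight = age/sex reference × lognormal jitter
(CV 8%); per season, a true dose is drawn lognormal with meanlog ln(0.5)
and sdlog 1.17, putting the median at 0.5 and the upper 2.5% tail near
5 µg/kg/day — bracketing the printed dose range (0–9.13) without claiming
the study's distribution. Void times are the schedule ± 0.5 h uniform
jitter; void metabolite amounts are cumulative-excretion increments between
consecutive voids (perfect bladder emptying — the same assumption the
excretion-rate formula makes); volumes scale with the collection interval ×
lognormal jitter (CV 25%); observed concentration = amount/volume ×
mean-one lognormal error (default CV 30%); voids drop out independently
(default 10%, about the n.a. density of the reference table). All
randomness flows from one seed; the same seed reproduces the table
byte-identically.

What the generator does **not** emulate: preformed TCPy intake (so real
urinary TCPy overstates CPF dose), multi-route and repeated daily
exposures (real dinner voids carry day-2 intake; the generator's single
bolus makes the noiseless round-trip exact by construction), incomplete
bladder emptying, and within-day variation of urine production. Passing
recovery tests therefore demonstrate the correctness of the inversion and
plumbing under the model's own assumptions, not the accuracy of the
assumptions for field data.

## Numerical choices and problem sizes

The ODE cross-check integrates the three-state system with `solve_ivp`
(rtol 1e-11) and agrees with the closed form to ≤1e-6 relative on
τ ∈ [0, 96] h. Test problem sizes: noiseless recovery at the design size
(13 × 2), sampling-noise checks at 200 children × 1 season, invariant
sweeps over 1,000 randomized parameter/composite draws — sizes chosen to
make Monte-Carlo tolerances meaningful while the whole suite stays fast.
`scripts/acceptance.py` measures the terminal half-life of the simulated
excretion curve with near-instant absorption (k_a = 1e6/h) by a log-linear
fit over 24–72 h post dose, on a 97-point grid.

## Limitations

The kinetic form is a reconstruction: the original analysis deferred its
equations to unpublished scripts, and this one-compartment model is the
minimal form consistent with its stated constraints. Whether the original
reported absorbed or ingested (pre-bioavailability) dose is unstated; doses
here are absorbed. `f_u` and `k_a` defaults are conventional rather than
study-specific, and `f_u` scales every reported dose linearly — ratio and
recovery properties are invariant to it, absolute doses are not. Slot 7
records are estimated but never enter composites, as their void identity is
unknown.
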