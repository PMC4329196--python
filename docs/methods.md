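# Methods

## Compartmental mechanics

The lung is a set of N = 100 parallel compartments behind one series dead
space. Each compartment carries a polynomial pressure-volume law
`P_alv = P_ext + k V + k2 V^2 + k3 V^3`. `P_ext` (cm H2O) lumps
superimposed gravitational pressure and surface-tension effects into a
single offset; `k` (cm H2O/ml) is the linear stiffness; the quadratic term
dominates the progressive stiffening, so elastance grows roughly with the
square root of distending pressure — the shape implied by clinical
compliance trajectories under PEEP staircases, where dynamic compliance
falls steeply over the first few cm H2O of PEEP but only gently between
PEEP 10 and 45; a small cubic term guards the extreme high-volume end. A
purely cubic stiffening term was rejected during development: any cubic
stiff enough to bound tidal volumes at moderate PEEP extinguishes
ventilation entirely at the staircase top. The exact compartment-level
equations of the lineage of simulators this package follows are published
only in supplementary material that is not publicly archived; this law is
the package's own reconstruction, and everything downstream treats it as
such.

Open compartments fill through an airway resistance `R_aw`
(`dV/dt = (P_aw − P_alv)/R_aw`), integrated with a fixed-step explicit
scheme (dt = 10 ms; the mechanical time constants R_aw/k are ~0.3–1 s, so
the scheme is comfortably stable, and a single-compartment run matches the
closed-form RC exponential to <0.5%). Breath events align to the dt grid.

Recruitment is time-dependent: a collapsed compartment opens once airway
pressure has exceeded its threshold opening pressure (TOP) continuously for
τ_c seconds; any dip to or below TOP resets the timer. Opening starts from
zero volume and the unit fills through its resistance. Derecruitment is the
discrete cliff-edge event evaluated once per breath at end-expiration: an
open unit collapses when its end-expiratory alveolar pressure is below its
closing pressure. Closing pressures sit strictly below TOPs, giving the
open/close hysteresis responsible for the "recruit high, keep with moderate
PEEP" behaviour.

### Population structure

Per-compartment parameters are sampled from population distributions, not
fitted individually (four static blood-gas targets cannot identify hundreds
of free parameters). Two sub-populations are used:

* healthy units — TOP ≈ 0.3–3 cm H2O, closing pressure well below any
  clinical PEEP: normal alveoli that never collapse under the protocols;
* diseased units — a fraction `collapsed_frac` (the calibrated "% of
  compartments collapsed") with TOP from a Gaussian (mean 18, SD 9 cm H2O)
  clipped to [6, 60] — placing ~97% of opening pressures below a sustained
  35 cm H2O, the clinically reported recruitment-pressure spectrum —
  closing pressures from their own Gaussian (mean 7.5, SD 1.5 cm H2O,
  clipped below each unit's TOP), and log-normal τ_c (fitted; defaults:
  log-mean ln 90 s, log-SD 0.8). The TOP hyper-parameters are structural
  defaults, not fit dials: diseased units are closed at the recording
  conditions, so the static targets carry no information about them.

A single truncated Gaussian for TOP cannot simultaneously put ~three
quarters of the mass below PEEP 5 (the open fraction at the recording
conditions) and spread the remainder over 6–45 cm H2O (the gradual
staircase recruitment); the two-population form is the minimal structure
that does both. Likewise, closing pressures are sampled directly rather
than as one global `TOP − Δ_close` offset: a single offset tied to a wide
TOP spread would scatter closing pressures far above the 5–16 cm H2O band
that the post-maneuver maintenance behaviour (PEEP 10 holds, PEEP 5 loses,
PEEP 16 retains ≥95%) requires. The per-compartment `d_close = TOP − P_close`
is stored so the hysteresis invariant `0 < d_close ≤ TOP` is explicit.

Raw standard-normal draws are frozen per seed and transformed by the
hyper-parameters, so calibration moves smoothly through parameter space
while the population realisation stays fixed; identical seed and
hyper-parameters give bit-identical patients and trajectories.

## Gas exchange

Alveolar gas is quasi-steady once per breath. Fresh alveolar ventilation of
compartment *i* is its inspired volume minus its share of the series dead
space; the series dead space is 140 ml plus 4 ml per cm H2O of mean airway
pressure, saturating at 16 cm H2O (conducting-airway distension). Per-compartment alveolar PO2 and
PCO2 solve the two V/Q mass balances (gas-side flux = blood-side flux) by
bisection, with end-capillary blood fully equilibrated to alveolar gas.
Compartments without ventilation carry venous blood unchanged (true shunt);
ventilated-but-unperfused compartments approach inspired gas (alveolar dead
space).

Blood chemistry uses the standard adult correlations: Kelman's rational
polynomial for oxyhaemoglobin saturation with the virtual-PO2 Bohr and
temperature corrections (cross-checked in the tests against the independent
Severinghaus fit), O2 content `1.34·Hb·SO2 + 0.003·PO2`, and the Douglas
whole-blood CO2 content with its saturation-dependent Haldane term. pH
follows Henderson–Hasselbalch along the whole-blood buffer line:
bicarbonate rises 0.15 mmol/l per mmHg PCO2 above 40 (non-bicarbonate
buffering, chiefly haemoglobin). This slope matters: with fixed bicarbonate
the whole-blood CO2 content slope collapses to ~0.09 ml/dl/mmHg and the
venous-arterial PCO2 difference and shunt→PaCO2 coupling become several-fold
too large; with the buffer line the slope is ~0.4 ml/dl/mmHg near the
arterial point and the a-v PCO2 difference lands in the physiological
~4 mmHg range.

Perfusion distributes over compartments in proportion to vascular
conductance `1/R_vasc`, scaled by (a) hypoxic pulmonary vasoconstriction — a
sigmoid reduction of conductance, half-effect at alveolar PO2 40 mmHg, Hill
exponent 3, maximal reduction 50%, switchable off for the shunt-oracle
tests — and (b) a distension factor `1/(1 + (P_alv/25)^3)` representing
capillary compression in highly pressurised units (West-zone behaviour).
The distension coupling and the pressure-dependent dead space together
reproduce the initial PaCO2 rise when ventilator pressure increases.
Diseased units carry a calibrated relative conductance (bounded 0.85–1.35),
allowing the measured venous admixture to differ from the anatomical
collapsed fraction, as the clinical records require.

Arterial blood is the perfusion-weighted mixture of end-capillary
*contents*; tensions are recovered by inverting the content relations
(alternating O2/CO2 inversion, converged to <0.1 mmHg). Mixed venous blood
follows the Fick principle at fixed cardiac output —
`CvO2 = CaO2 − VO2/(10·CO)`, `CvCO2 = CaCO2 + RQ·VO2/(10·CO)` — with a
first-order venous-pool mixing delay (τ = 30 s) so oxygenation transients
over minutes are resolved. Venous admixture (Qs/Qt) is measured with the
Berggren equation against flow-weighted ideal end-capillary blood, exactly
as a clinician would compute it; with HPV and distension disabled it
recovers an imposed shunt fraction to <0.5% absolute.

During the breath-free sustained-inflation hold, alveolar tensions are
frozen rather than re-solved with zero ventilation: the alveolar oxygen
store at high FiO2 far outlasts a 40-s apnoea, whereas a quasi-steady solve
with VA = 0 would snap alveolar gas to venous tensions instantly. Perfusion,
arterial mixing and the venous pool keep evolving during the hold.

## Protocols

Square pressure waveforms (instant rise/fall): PEEP + ΔP for the
inspiratory fraction IE of each cycle, PEEP for the rest; CPAP segments are
constant. Stage durations not fixed by the protocol definitions default to
5 min pre-maneuver (PEEP 10, ΔP 15) and 20 min post-maneuver, both
configurable. The MRS builder accepts off-grid end-PEEPs (e.g. 16 cm H2O)
as an exact final titration step. Patient-specific VR, IE and FiO2 are held
at their calibrated values through every maneuver.

## Calibration

Stage 1 (static): free parameters VR (within ±3 breaths/min of the recorded
rate — it is a ventilator setting, not a disease property), RQ ∈ [0.5, 1.1],
VO2 ∈ [150, 400] ml/min, collapsed fraction ∈ [0.02, 0.60], and the diseased
vascular-conductance weight ∈ [0.85, 1.35]. The objective is the equally
weighted mean squared relative error over {PvO2, PvCO2, Qs/Qt, PaO2}
simulated to steady state at the recording conditions (inspiratory pressure
15, PEEP 5 cm H2O), plus a 1e-3-weighted quadratic pull toward the bound
mid-points. The pull is an identifiability device, not a prior: collapsed
fraction and conductance weight trade off along a ridge that the four
targets cannot break, and the regulariser selects the ridge centre so that
parameter recovery on simulator-generated records is well defined (recovery
to ±5 points on collapsed fraction and ±10% on VO2 is part of the test
suite). Search: bounded differential evolution (seeded, population 8×dim)
followed by a Powell polish; a failed simulation inside the objective
penalises the candidate rather than aborting. The steady state itself is
computed by a short mechanical settling phase and a damped fixed-point
iteration of the per-breath gas exchange with the Fick venous balance —
orders of magnitude faster than time-marching the venous pool.

Stage 2 (dynamic): the τ_c log-mean and log-SD are fitted (Nelder–Mead,
bounded) to a PaO2-versus-time series under PEEP steps 5 → 15 → 5 cm H2O.
The clinical reference series is not published numerically, so a synthetic
generator stands in: piecewise-exponential PaO2 toward PEEP-dependent
plateaus with configurable rise (default 120 s) and fall (60 s) time
constants and optional Gaussian noise, deterministic under seed. The
defaults encode a minutes-scale oxygenation response to PEEP changes, which
is what the opening-timer distribution must reproduce; the committed presets
generate each patient's reference from that patient's own simulated PEEP-5
and PEEP-15 steady states so only the *shape* is imposed. After the dynamic
fit the static targets are re-checked and the relative degradation reported.

The committed presets (`src/alveosim/presets/`) are the product of the full
two-stage pipeline (`scripts/make_presets.py`, budget 2500 evaluations,
seeds recorded in the files, checksums verified at load). They decouple the
maneuver experiments and the test suite from optimizer stochasticity.

## Evaluation metrics

Per breath: PaO2/FiO2, PaCO2, tidal volume, dynamic compliance
Vt/(P_insp − PEEP) reported per mbar with 1 mbar ≡ 1 cm H2O (a ~2%
convention error, accepted), percent of compartments open (sampled after
the end-expiratory derecruitment event), and venous admixture. Maneuver
level: P_peak, the mean of per-compartment maximum alveolar pressures over
the most pressurised 20% of compartments across the whole run; and ΔPO2,
the maximum PaO2/FiO2 minus the pre-maneuver baseline (mean over the last
minute of the pre-maneuver stage). ΔPO2 is deliberately computed on the
PaO2/FiO2 scale in mmHg: the published comparison table describes it as a
PaO2 difference and prints a pressure unit, but its magnitudes only close
on the FiO2-normalised scale, so the header is treated as a typographical
slip. "Percent recruited at the end of the recruitment phase" is sampled at
the final breath of the peak-PEEP staircase step.

## Problem sizes and determinism

Default runs use 100 compartments at dt = 10 ms; a 60-minute protocol
(~1000 breaths, ~360k mechanics steps) completes in roughly one second with
the compiled kernels, and a full five-patient static calibration at the
default budget in a few minutes. The acceptance script re-fits at a reduced
budget of 1500 evaluations per patient for the pooled-correlation figure;
the in-suite calibration check uses 700. The engine draws no random numbers:
all stochasticity lives in the seeded population draws and the seeded
optimizers, so identical seeds reproduce results bit-for-bit.

## What the synthetic data do and do not show

The virtual patients reproduce printed static blood-gas records, and the
dynamic reference generator emulates only the exponential shape of
oxygenation responses to PEEP steps. Neither encodes real per-breath
waveform data, spontaneous breathing effort, secretions/airway closure, or
measurement noise in blood-gas sampling; passing tests therefore show that
the model reproduces the published steady states, orderings and thresholds,
not that it predicts an individual patient's breath-by-breath trajectory.

## Known limitations

* Cardiac output is fixed; right-ventricular impairment and the
  venous-return effects of intrathoracic pressure are out of scope, so
  hemodynamic consequences of high PEEP are not represented.
* Overdistension injury and inflammatory responses are not modelled; P_peak
  is a surrogate for barotrauma exposure, not an injury model.
* During the high-PEEP staircase steps tidal volumes shrink onto the stiff
  part of the PV curve and simulated PaCO2 can transiently overshoot the
  modest rises reported clinically; the post-titration values recover.
* The PRM's peak compartment pressures are only slightly below its 40 cm
  H2O peak airway pressure because, at the calibrated mechanics, open units
  nearly equilibrate within an inspiration; the published table shows a
  larger gap, so maneuver *orderings* rather than P_peak point values are
  the asserted behaviour for PRM.
* Baseline PaCO2 at the pre-maneuver settings (PEEP 10, dP 15) is
  under-predicted by several mmHg relative to published virtual-patient
  values. At steady state arterial PCO2 cannot exceed mixed venous PCO2,
  and the venous calibration targets (measured at PEEP 5, dP 10) pin the
  fit-condition arterial values ~4 mmHg below them; reproducing a further
  5-12 mmHg rise at the higher driving pressure would require effective
  alveolar ventilation to fall substantially as pressure increases, which
  no monotone compartmental PV law plus bounded dead-space growth produces
  without extinguishing ventilation at the staircase top. The implemented
  dead-space and perfusion couplings recover the direction and part of the
  magnitude of the rise; CO2 retention is reproduced qualitatively
  (hypercapnic ordering across patients, rise during the staircase), not
  to the printed baseline values.
* Acid-base is the acute respiratory buffer line only (no metabolic
  compensation); blood temperature is fixed at 37 °C.
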