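# Methods

`finblock` simulates how a continuous sinusoidal current applied at the
optic nerve (frequency-induced neuromodulation, FIN) suppresses, partially
suppresses, or paradoxically excites action-potential conduction in
retinal-ganglion-cell (RGC) optic-nerve fibres of different diameters and
functional types (ON vs OFF). The pipeline has three stages: a quasi-static
volume-conductor solve for the electrode field, a compartmental cable
simulation of combined RGC + myelinated-fibre models driven intracellularly
while the extracellular sinusoid is applied, and sweep/statistics layers
(outcome classes, suppression probability, suppression thresholds).

## Volume conductor

The optic nerve is a 10 mm cylinder of concentric resistive layers.  The
default profile (`default_profile`) uses

| layer             | thickness (um) | conductivity (S/m) |
|-------------------|---------------:|-------------------:|
| nerve fibre space | 230 (radius)   | 0.57               |
| pia               | 10             | 0.17               |
| CSF               | 20             | 1.70               |
| dura              | 15             | 0.06               |
| fat               | 8.47           | 0.04               |

The thicknesses sum to the 283.47 um electrode penetration depth (outer fat
surface to the nerve midline); conductivities are standard murine/mammalian
tissue values with the fibre space treated as isotropic white matter.  An
optional surround layer represents a bone-filled exterior.

Two 200 um discs sit on the nerve's longitudinal axis: the interference
electrode 5 mm from the soma (ideal current source, uniform current density,
1 uA total) and the reference electrode at 6 mm (grounded).  Disc normals
are perpendicular to the nerve axis (a documented convention - the sources
describing this geometry do not fix the face orientation).  The field obeys
`div(sigma grad V) = 0`, discretised with a 7-point finite-difference
stencil (harmonic-mean face conductivities, symmetric positive definite
system) and solved directly below ~50k unknowns, by preconditioned
conjugate gradients above.  Maps are stored in mV per uA and scaled
linearly at run time: tissue is purely resistive under the quasi-static
assumption, so the field follows the electrode current instantaneously.

Boundary conditions: the lateral box faces are insulating (zero normal
current), matching a nerve surrounded by non-conducting tissue.  The two
longitudinal end faces are *grounded* by default.  A fully sealed cylinder
would force every injected microampere to return only through the 200 um
reference disc, stacking volt-scale plateau potentials along the whole
nerve; in reality the nerve continues rostrally into the conductive eye
globe - which is exactly the current-return context of the modelled
preparation - and caudally towards the chiasm.  `end_faces="insulate"`
restores the sealed variant for sensitivity checks.

An analytic point source + sink in an infinite homogeneous medium
(`analytic_bipolar_field`, `V = I/(4 pi sigma) (1/r_src - 1/r_snk)`) serves
as the independent oracle: with one uniform conductivity and the box walls
pushed far out, the finite-difference solution matches it within 5% at
probes at least three disc diameters from either electrode (after removing
the sealed-box reference offset).

## Fibre morphology

Each model is one unbranched chain: dendrites - soma - axon hillock (AH) -
axon initial segment (AIS) - unmyelinated distal axon (DA) - myelinated
axon fibre (MAF).  The dendritic arbour is a surrogate: a symmetric tree
(branch counts 4/2/1 from terminals to primaries, 400 um field diameter)
folded into an equivalent chain whose compartments carry branch-multiplicity
factors on membrane area and axial conductance.  This folding is exact for
a symmetric tree in a locally uniform field, which holds because the
dendrites sit ~5 mm from the nerve electrodes where the field is both tiny
and flat.  ON and OFF cells differ in one number only: the AH height is
40 um larger in the OFF model (40 vs 80 um); the DA absorbs the difference
so that the first node of Ranvier (node A) is 0.8 mm from the soma for both.

The MAF follows the McIntyre-Richardson-Grill (MRG) segmentation: each
node-to-node unit is node + 2 paranodes (PN) + 2 juxtaparanodes (JN) + 6
internodes (IN).  Per-diameter dimensions come from a three-row table
(1.4 / 2.8 / 4.3 um - the modal diameters of the rat optic-nerve fibre-size
groups, abundance-weighted 0.903 / 0.094 / 0.003) linearly interpolated in
fibre diameter and never extrapolated:

| d_f (um) | internodal distance | node diam | axon diam | lamellae |
|---------:|--------------------:|----------:|----------:|---------:|
| 1.4      | 140 um              | 0.50      | 0.98      | 12       |
| 2.8      | 280 um              | 1.00      | 1.96      | 24       |
| 4.3      | 430 um              | 1.50      | 3.01      | 37       |

The table is a synthetic stand-in built from standard small-fibre scalings
(internodal distance ~ 100 x d_f; g-ratio ~ 0.7; ~17 wraps per um of fibre
diameter); the tabulated values the original study interpolated were not
redistributable.  Node length is 1 um and PN length 3 um at all diameters;
JN length scales as 5 x d_f and the 6 IN segments fill the remainder, so
the 2PN+2JN+6IN unit structure is preserved exactly.  A 10 mm nerve gives
floor(10000/INL)+1 nodes (72 / 36 / 24).

Placement: fibres run parallel to the nerve axis through one of 36 cell
centres of a 6x6 grid of 40x40 um cells in the first quadrant (centres at
20, 60, ..., 220 um; one quadrant suffices by symmetry).  The z-shift
in {0, 0.25, 0.5} expresses the longitudinal offset between the
interference electrode and the nearest node as a fraction of the internodal
distance; the whole chain is translated rigidly, so one shift value maps to
different absolute offsets per diameter.  The published grid description is
internally inconsistent (a 200 um quadrant divided into 36 cells of 40 um);
we honour the more specific statement - 6x6 cells of 40x40 um - and expose
cell size and count as parameters.

## Membrane dynamics

All kinetics live in `data/channels.yml` as declarative rate laws (linoid /
exponential / sigmoid forms with singularity removal), so every constant is
auditable data.  The front end (dendrite, soma, AH, AIS, DA) carries
Fohlmeister-Miller-style RGC channels: fast Na (m3h), delayed-rectifier K
(n4) and A-type K (a3h), cm = 1 uF/cm2.  Nodes of Ranvier carry MRG-style
mammalian axon channels at body temperature: fast Na (m3h), persistent Na
(p3) and slow K (s), cm = 2 uF/cm2, rest near -80 mV.  Myelinated PN/JN/IN
compartments are passive - ion exchange in mammalian optic-nerve fibre
models is confined to the nodes - and carry the MRG double-cable passive
elements: per-lamella myelin capacitance 0.1 uF/cm2 and conductance
1e-3 S/cm2 (halved per membrane pair and divided by wrap count), a
periaxonal space 2-4 nm wide, and 70 ohm cm axial resistivity for both
axoplasm and periaxonal pathway.  No temperature scaling is applied beyond
the tabulated rates.

Maximal conductances were calibrated the way the original study fitted its
conductances to target electrophysiology, with the published baseline as
the target: under the standard 0.13 nA x 40 ms soma step the ON 1.4 um
model must fire a stable ~120 Hz train (6 spikes reaching the most distal
node in 50 ms) and every model must be quiescent with no input.  The
calibrated set (relative to the initial literature values: Na x 1.5, A-type
K x 0.6, leak reversal -58 mV, and the compact dendritic tree above) is
baked into `channels.yml`; the OFF and larger-diameter models fire 5
spikes under the same drive, preserving the published ordering in which ON
cells are at least as excitable as OFF cells.

Gating uses the implicit update `x' = (x + dt a) / (1 + dt (a + b))`,
which keeps states in [0, 1] for any dt.

One consequence of the calibrated conductance distribution: spike
initiation is perisomatic but not confined to the AIS - silencing the AIS
sodium conductance alone leaves the soma and hillock able to initiate,
while silencing sodium across the whole front end abolishes spiking.  The
AIS conductance still shapes excitability (the basis of the
threshold-perturbation experiment), it is just not a single point of
failure.

## Cable solver

Two potentials per compartment: intracellular, and the periaxonal potential
between axolemma and myelin.  Unknowns are interleaved, so the whole system
is pentadiagonal and solved by LAPACK banded LU each step; at nodes and
unmyelinated compartments the periaxonal unknown is shorted to the local
extracellular potential through a large conductance (1e5 uS), recovering
the single-cable equations there without breaking the uniform band
structure (the MRG treatment of the nodal gap).  Ionic currents are
linearised about the current gate states inside each backward-Euler voltage
solve; gates then advance implicitly at the new voltage.  dt = 0.01 ms
(one tenth of the shortest FIN period at 10 kHz), T = 50 ms.

Extracellular coupling follows the standard interpolated-potential
approach: the unit-current field map is sampled by trilinear interpolation
at every compartment midpoint once, then scaled each step by the electrode
current `I_int sin(2 pi f_int (t - onset) + phase)`.  FIN is on for the
whole window with phase 0 by default; onset and phase are exposed for
temporal-shift studies.  Positive current means the interference electrode
sources current during the positive half-cycle.  The soma current step
starts at t = 0 (the source material states duration but not onset).

Before t = 0 each system relaxes for up to 60 ms (or until
max |dV/dt| < 1e-5 mV/ms) with all stimuli off; settled states are cached
per (model class, mechanism parameters) and reused across sweep conditions,
which also guarantees the zero-amplitude identity: FIN amplitude 0, or a
zero field map, reproduces the baseline solution bit for bit.

A spike is any upward crossing of 0 mV (with the trace below 0 mV since the
previous crossing), which filters the subthreshold oscillations the
sinusoid induces.  `n_spike` is the count at the most distal node (node B,
5 mm beyond the interference electrode); node A is the most proximal node,
4.2 mm before it.

Numerical guards: rates are evaluated with clipped exponents; the run
aborts if |Vm| exceeds 5000 mV.  That guard is deliberately far above the
physiological range because the extracellular drive near the disc reaches
volt scale at the top of the amplitude grid and the ohmic polarisation of
the axolemma directly under the disc can legitimately pass 500 mV while
remaining perfectly stable.

Accuracy: against an adaptive high-accuracy integrator (LSODA at rtol
1e-10) on a single nodal compartment, the backward-Euler scheme converges
at first order; at dt = 2e-4 ms spike times agree within 0.05 ms and counts
exactly, and at the production dt = 0.01 ms distal spike counts are
unchanged when dt is halved for the conditions sampled in the tests.

## Experiments and statistics

Outcome classes from distal spike counts: *maximal suppression* when
n_spike <= 1 (the single remaining spike is the onset spike the sinusoid
itself evokes - it is counted, by definition), *excitation* when n_spike
exceeds baseline, *partial suppression* in between, *unaffected* when
equal.

Suppression probability at one cross-section position and frequency is the
abundance-weighted fraction of (diameter, z-shift, amplitude) conditions
that are maximally suppressed:

    SP(x, y, f) = sum_{d,z,a} p(d) [n_spike <= 1] / sum_{d,z,a} p(d)

with the amplitude grid {0, 40, ..., 400} uA.  The denominator includes the
0 uA baseline, exactly as the published worked example divides by all 11
amplitudes (7/11 suppressive for 1.4 um and 9/11 for 2.8 and 4.3 um across
three z-shifts gives SP = 0.654); since a spiking baseline is never
"suppressed", this convention caps SP at 10/11 - a documented quirk -
and `include_zero_amplitude=False` provides the FIN-only denominator that
can reach 1.

The suppression threshold `th_sup(f)` is the smallest tested amplitude
above which maximal suppression holds for every higher tested amplitude;
series in which spikes reappear at the top of the grid have no threshold.
Fine sweeps refine the amplitude step to 5 uA around a coarse threshold
(and the frequency step to 10 Hz where the transition zone is examined).

Sweeps are deterministic, cached by condition key (hence resumable) and
write one long-form row per condition; the 0 uA baseline is simulated once
per (cell type, diameter) since without electrode current the field does
not enter the equations.

With the default field and model, the reduced single-position sweep
reproduces the qualitative frequency structure of kilohertz nerve block:
near-complete suppression at 10 Hz (one long anodal half-cycle spans most
of the window), a mid-band trough - at 100-250 Hz no fibre is maximally
suppressed at any amplitude, because each hyperpolarising phase is too
short to hold a block while the depolarising phase re-excites the distal
nodes (spike counts up to ~2x baseline) - and robust amplitude-thresholded
block in the kilohertz regime with exactly one onset spike.  Because the
finite-difference field replaces the original finite-element solution, the
absolute microampere thresholds are not comparable quantities, and the
band edges shift with them: this field couples several-fold more strongly
than the replaced one, so the 40-400 uA grid reaches block-scale drive
already at 350-450 Hz for the smaller fibres, where blocks intrude on the
upper mid-band.  The largest fibre (4.3 um), for which the grid is closest
to threshold scale, shows the full published phenomenology: an empty
50-450 Hz band, strong mid-band excitation, spike reappearance above
threshold at 750-1000 Hz (no stable threshold there) and clean block from
2 kHz up.

## Calibration module

A generic random-walk Metropolis-Hastings sampler over positive bounded
parameters (conductance scale factors addressed as `region/channel`):
log-space Gaussian proposals, uniform box prior, Gaussian likelihood over a
normalised spike-feature vector (count, first-spike latency, peak
potential; the exact loss of the original fitting procedure was not
available, so this declared default is recorded in the output metadata).
A strictly better proposal is always accepted; chains are reproducible
under their seed; on an analytically tractable quadratic loss the chain
marginal matches the corresponding truncated Gaussian.

## Synthetic fixtures

`fixtures` generates every input the statistics and I/O layers need without
the slow biophysical path: zero/homogeneous/layered potential maps, traces
with prescribed 0 mV crossings, and sweep tables with embedded ground-truth
thresholds (including the published worked-example table).  They exercise
file formats and statistics quickly; they do not validate the biophysics,
which the simulation tests cover separately.

## Problem sizes in the test suite

The test and acceptance runs use reduced problem sizes chosen to exercise
every code path at full fidelity: single-position sweeps with the full
3-diameter x 3-z-shift x 11-amplitude block at a handful of frequencies
(the full 36-position, 21-frequency study is available through
`SweepConfig.full_study()` / the CLI); a 20 um near-electrode grid for the
production field; and a soma-only model for the 2000-iteration fit-recovery
check.

## Known limitations

* The myelinated-fibre membrane is passive outside the nodes; juxtaparanodal
  K channels and internodal leak pathways are absent, as in the modelled
  source material.
* The front-end channel set and the per-diameter geometry table are
  literature-grounded reconstructions, not transcriptions; absolute
  thresholds inherit that uncertainty on top of the field-model caveat.
* The dendritic surrogate reproduces field diameter and a plausible load,
  not a reconstructed arbour; results that depend on dendritic morphology
  fine structure are out of scope.
* A single 50 ms window bounds the attainable spike counts; at 10 Hz only
  half a FIN cycle is seen (phase shifts expose the other half).
* Tissue is isotropic and purely resistive; electrode polarisation and
  capacitive tissue effects are not modelled.
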