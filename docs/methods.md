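# Methods

`tmjload` is a desk-scale, muscle-driven rigid-body model of mandibular
open–close movement with reduced-order deformable contact in both
temporomandibular joints (TMJs), plus the analysis pipeline that turns the
simulated contact-force traces into window means, baseline-relative
percentage tables and cut-off detection across a unilateral
ramus-shortening sweep. This note documents the model, its assumptions,
the parameters that matter, and what the synthetic set-up can and cannot
say about real jaws.

## The mechanical model

**Bodies and frames.** The skull is the fixed inertial frame; the mandible
is a single rigid body (mass 0.44 kg, principal inertia ~(800, 1200, 900)
kg·mm²) with six degrees of freedom, integrated with fixed-step
semi-implicit (symplectic) Euler and body-frame Euler equations for the
rotation. Coordinates: midsagittal plane x = 0, +x right, +y anterior, +z
superior; mm / N / s units. The closed-jaw pose is the reference; all
simulations are deterministic (no random numbers anywhere in the solver).

**Joint geometry.** Each TMJ is idealized as a spherical bony condyle
(radius 10 mm) under a concentric spherical bony fossa (radius 16 mm); the
6 mm radial gap is filled by the deformable stack of fossa cartilage
(1.5 mm), articular disc (3 mm) and condylar cartilage (1.5 mm). The
articular cap of the fossa is tilted 30° anteriorly and spans 60° of polar
angle, so its anterior portion plays the role of the eminence slope that
is loaded when the condyle is pulled forward at wide opening, while the
cap never extends below the equator — an inferiorly displaced (fractured,
shortened-ramus) condylar fragment therefore drops clear of the socket
instead of wedging into a sub-equatorial lip. The fossa sphere centre is
offset 0.8 mm along the cap axis (`occlusal_precompression`), so the
seated condyle is pre-compressed into the stack at occlusion and the joint
carries a nonzero closed-mouth load.

**Contact.** Contact is elastic-foundation (per-element through-thickness
compression of the stack), evaluated on the triangulated fossa patch
(superior, fossa–disc compartment) and condyle patch (inferior,
disc–condyle compartment); the disc is assumed to ride centrally, so both
compartments discretize the same stack pressure and their totals differ
only by discretization (the per-joint "mean contact force" is their
arithmetic mean). Per element:

* elastic pressure = Mooney–Rivlin uniaxial stress of the layer at stretch
  λ = 1 − δ/h (C1 = 4.5·10⁵ Pa, C2 = 4.5·10² Pa);
* damping pressure = transient Prony branches (G1..G4 = 0.50, 0.50, 0.72,
  2.50 MPa; τ1..τ4 = 50, 5, 0.2, 0.005 s; equilibrium G0 = 0.40 MPa is the
  elastic law's job) driven by the per-element penetration-strain history
  with the exponential-integrator update (exact for strain linear over a
  step); the total normal pressure is clamped non-negative (contact cannot
  pull), and pre-existing occlusal compression is primed into the history
  so it generates no spurious transient at t = 0;
* friction = regularized Coulomb (μ = 0.01, linear below 0.1 mm/s slip).

Per-element penetration beyond the stack thickness raises a bottom-out
error (bone-on-bone) and aborts the run with a diagnostic.

**Dental contacts.** Seven occlusal contact points (incisal pair,
premolar, first and second molar pairs per side) engage near closure:
near-rigid normal stiffness (4000 N/mm — teeth are treated as ankylotic),
constant-coefficient damping (no disc exists there), and a tangential
"cusp interdigitation" spring (1000 N/mm, engaged only under load and
capped at `cusp_slope` = 3 × the normal force, since inclines can only
redirect the normal load). The full-arch layout matters: the second molars
sit almost directly beneath the elevator-muscle resultant, so when one
joint unloads after a fracture, the lost share is absorbed within the
tooth row rather than leaking into the contralateral joint.

**Muscles.** Twelve named masticatory muscle groups per side (superficial
/ deep posterior / deep anterior masseter, posterior / anterior
temporalis, medial pterygoid, inferior / posterior lateral pterygoid,
digastric, geniohyoid, posterior / anterior mylohyoid) pull with
`a_role(t) · peak_force` along straight origin→insertion lines;
activations are identical left and right (bilateral symmetric drive).
Attachment coordinates and peak forces are idealized
physiological-cross-section-scale values with a single global scale chosen
during model design; only relative loads are interpreted downstream.

**Passive elements.** Three passive structures close the model where
muscle activation alone cannot:

* *Passive elevator recoil*: each closer muscle line carries a passive
  tension of `k s + A (e^{s/s₀} − 1)` (k = 0.5 N/mm, A = 0.35 N,
  s₀ = 2.6 mm) on its stretch `s` beyond the closed-pose length — small
  through the working range, steeply progressive near maximal opening.
  This is what limits the model's mouth opening to ≈30 mm, presses the
  condyles up-forward into the fossae at wide opening (the open-phase
  joint load), and recoils the jaw closed without storing slam-level
  energy.
* *Capsule tethers*: per side, a slack ligament (1.5 mm slack, 100 N/mm)
  anchoring the condyle centre to its as-built rest position. For a
  shortened-ramus geometry the anchor is the *displaced* rest position:
  the fragment stays suspended in its soft tissues rather than being
  artificially re-centred into the fossa.
* *Passive rotational stiffness/damping* about the COM (pitch/roll/yaw
  stiffness 2·10³ / 1·10⁵ / 5·10⁴ N·mm/rad; damping 160 / 500 / 500
  N·mm·s/rad, body frame, integrated implicitly so any coefficient is
  unconditionally stable). The high roll/yaw terms stand in for the broad
  sheet-like muscle attachments and soft tissues that keep the jaw from
  tipping; they are what let load transfer to the contralateral joint
  through the rigid body instead of through a roll that would unload the
  contralateral elevators.

**Activation protocol.** One run is two open–close cycles in 0.4 s: mouth
closed at 0, 185 and 365 ms, maximal opening at 75 and 275 ms. Opener
envelopes are raised-cosine pulses peaking exactly at the open keyframes,
with an asymmetric shape (75 ms rise, 105 ms decay) whose tail brakes the
recoil-driven closure eccentric-style; closer envelopes rise after each
open peak, peak at the approach to closure and decay in 30 ms, on top of a
tonic co-activation (0.3 of the envelope) that holds occlusion at rest.
Activation levels are `gain · envelope`, clipped to [0, 1]. The opener
gain is the one calibrated scalar: `calibrate_opener_gain` bisects it
until the baseline first-cycle peak opening hits the 30 mm target; the
shipped default (0.9109) gives 30.0 mm peaks at 76.4 / 276.4 ms at the
default timestep. The closer gain (0.6) was fixed during design so the jaw is
firmly in occlusion through the closed analysis windows.

**Integration.** Default dt = 0.05 ms (8001 steps per run); the `fast`
preset uses dt = 0.1 ms with a coarser surface triangulation (7 polar
rings, ≈200 elements per patch vs 12 rings, ≈600) for sweep-scale work.
Halving the timestep changes windowed mean forces by ≈0.01%, and the two
presets agree on window means to well under 2%. Point-contact damping
coefficients are deliberately small enough to respect the explicit
stability bound at the fast preset; the large passive linear/rotational
dampers are integrated implicitly.

## The shortening sweep and analysis stage

A unilateral condylar fracture with ramus shortening is imposed
geometrically: the condylar fragment (condyle centre, condylar patch, disc
patches) translates by 2–16 mm along the frozen mid-condyle→gonion axis of
the unshortened geometry (straight inferior in this idealization); muscle
attachments, fossa, and all contralateral/midline entities are untouched,
and activations are identical across the sweep. Severity categories:
minimal < 2 mm, moderate 2–15 mm, severe > 15 mm (boundaries inclusive to
"moderate").

The analysis windows are jaw-closed 180–189.9 ms and jaw-open 270–279.9 ms
(the second cycle); window means of the per-side joint mean-force traces
fill a per-run load summary. Percentages are 100 · force / baseline force
of the same side and phase, rounded half-up to one decimal. A separate
10% "attention" threshold flags notable consecutive changes; the cut-off
detector reports every consecutive shortening pair whose force drops by at
least 50% (both thresholds configurable). One published-table cell
(non-fractured side, closed, 16 mm: "93.2%") is consistent only with
normalization by the *contralateral* baseline; this package always
normalizes same-side (yielding 95.3 for those inputs) and documents the
discrepancy rather than reproducing it.

## Emergent behaviour (what the model reproduces)

With the defaults above, and with no per-run tuning:

* the baseline run is bilaterally symmetric to ≈0.3 N (float-exact mirror
  construction; the residual is integration noise);
* condylar load peaks around maximal opening and dips with the jaw closed
  in occlusion;
* across the sweep, the fractured-side open-window force falls
  monotonically from 100% toward 0%, the non-fractured open-window force
  rises above baseline (≈115→140% at the fast preset), and the
  non-fractured closed-window force stays within ≈5% of baseline — the
  asymmetric-load pattern of clinical interest, including the jaw's
  deviation toward the fractured side during opening;
* the fractured-side closed-window force collapses much faster in this
  idealized congruent-sphere geometry (essentially unloaded beyond ~2 mm)
  than in anatomically detailed models, where fossa shape lets a displaced
  condyle keep partial closed-mouth contact. Absolute newton values are
  properties of this synthetic geometry and muscle scale and are not
  comparable to any specific subject.

## What the synthetic set-up does not capture

No anatomical fossa/eminence shape, condylar ellipticity or tooth anatomy
(CT-derived geometry is out of scope); no disc displacement dynamics (the
disc rides centrally with the condyle — the convention for whether a disc
travels with a fractured fragment is a modelling choice, not an observed
fact); no Hill-type activation–contraction or tendon dynamics; no
periodontal compliance (teeth ankylotic); no remodelling. Hyoid-anchored
openers use skull-fixed effective origins. Passing tests on this geometry
demonstrate the mechanics of the load-transfer analysis, not
subject-specific force predictions.

## Numerical and reporting choices

Per-compartment totals combine per-element forces as the magnitude of the
vector sum (config-switchable to sum-of-magnitudes, since either reading
of "combined in a single number" is defensible). Equivalent stress per
element is the von Mises reduction of the local (normal pressure,
tangential traction) state, √(p² + 3τ²), exported as VTK cell data at the
185 ms and 275 ms keyframes. Runs that diverge or bottom out abort with a
diagnostic; in a sweep the failed run is marked in the manifest and the
remaining runs continue. Config files are YAML with unknown keys rejected;
the manifest records a key-order-independent SHA-256 config digest so
identical configurations produce byte-identical summaries.
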