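# Methods

This note documents the models, numerical choices and limitations behind
`straincycle`: what the simulator asserts about the world, how the
quantification stages interpret images, and what a green test does and does
not establish.

## 1. The monolayer simulator

### Cell-cycle state machine

Cells occupy {G0, G1, S, G2, M} and carry a scalar `A ≥ 0`, a proxy for
β-catenin transcriptional activity, drawn log-normally across cells
(`ln A0 ~ N(ln 0.3, 0.5)`).  Two thresholds grade the response:

| transition | rule | default |
| --- | --- | --- |
| G0 → G1 | hazard `h0 + h_strain·[strain]` | 0.014 /h + 0.02 /h |
| G1 → S | Erlang timer (mean 6 h, shape 4) **and** gate `A ≥ θ1`, licensed entrants only | θ1 = 1.0 |
| S → G2 | fixed duration | 8 h |
| G2 → M | hazard `k_M · A/θ2`, open only for `A ≥ θ2` | k_M = 0.5 /h, θ2 = 2.0 |
| M | instantaneous; parent → two daughters in G1, red restored | |

Treatment arms multiply activity: `A(t) = A0·(1 + β_s·σ(t − onset − 6 h) ·
[strain] + β_w·[wnt or D4476])`, with `β_s = 2`, `β_w = 9`, a logistic rise
of width 0.75 h, and iCRT3 forcing `A = 0`.  The 6 h delay of the strain arm
encodes the observation that strained cells enter S 6–8 h after stretch,
while the G0-exit (Yap) arm acts immediately.

**Trigger classes.**  Spontaneous ("basal") G0 exits resample `A` from the
log-normal tail above `θ2` — only high-activity cells complete unprompted
cycles, which is what keeps the control division rate equal to the S-entry
flux.  Strain-induced exits draw from the full distribution, so once strain
multiplies their activity by ~3 they mostly land in `[θ1, θ2)`: they enter S
but stall in G2.  That interval placement *is* the mechanism of the
strain-alone phenotype; no bespoke "arrest flag" exists.  Adding the Wnt arm
(×10) clears `θ2` for nearly everyone, which (a) flushes the standing G2/S
pool early — the transient mitotic burst under Wnt alone — and (b) lets
strain-induced entrants divide, the sustained strain+Wnt response.

**Daughters and contact inhibition.**  Daughters are born in G1 with red
fluorescence restored, draw a fresh `A0`, and are *unlicensed*: after their
G1 transit they re-enter G0 rather than S.  Without this rule any
activity-raising treatment would ignite runaway clonal re-cycling, which the
observed decay of the Wnt-alone burst excludes.  Sub-threshold or unlicensed
cells whose G1 timer has elapsed re-quiesce at 1 /h.

### Calibration by steady-state relations

Two numbers anchor the defaults: a basal S-entry flux λ = 0.01 per cell per
hour and an S/G2 dwell τ = 10 h (8 h S + ~2 h G2 at basal activity).  They
imply, analytically, a Geminin-positive fraction λ·τ ≈ 10 % and a division
rate λ·N ≈ 4.3 /h per 0.43 mm² frame (= 1 /h/0.1 mm²) at 1000 cells/mm².
Because only G0 cells are at risk of cycle entry and the steady-state G0
fraction is ≈ 0.72 (transiting cells plus post-mitotic daughters), the
per-G0-cell hazard is set to `h0 = 0.014 /h ≈ λ/0.72`.

### Quiescence vs. baseline turnover — a deliberate two-stage design

Deep quiescence (≥ 95 % G0) and a 10 % S/G2 pool cannot coexist in one state:
the green fraction is bounded by `100 − %G0`.  Both are nonetheless real
features of such experiments — the first characterizes the matured prep, the
second the monolayer as imaged.  The package therefore separates them:

* `initialize_quiescent_monolayer` matures the plated monolayer for 48 h
  under a density-suppressed G0-exit hazard (`(ρ_q/ρ)^8`, ρ_q = 750 /mm²);
  plating leaves 5 % of cells mid-cycle, they finish and re-quiesce, and the
  end state is ≥ 95 % G0 (typically 96–98 %).
* `simulate_timelapse` then seeds the basal cycling pipeline to its
  steady-state occupancy (≈ 6 % G1, 8 % S, 2 % G2) before frame 0, because a
  movie of a monolayer with ongoing basal turnover opens at that steady
  state, not at the post-maturation trough.  Standing-pool members are staged
  with length-biased transit durations (gamma(k+1, θ) for an Erlang(k)
  transit) — the correct stationary composition; naive sampling produces an
  early outflow spike and a sag in the green fraction.

The density suppression applies only during maturation; movie dynamics use
the constant basal hazard, otherwise the baseline flux would be extinguished
at super-confluent densities.

### Geometry, fluorophores, image formation

* Field 656 × 656 µm (≈ 0.43 mm², one movie frame), jittered hexagonal
  packing at 1000 cells/mm², 15-min frames, 0.65 µm/px, 4 µm nuclei.  These
  imaging conventions are package choices consistent with a 20× objective;
  they are not measured quantities.
* Brownian jitter 0.3 µm RMS per frame; a soft excluded-volume constraint
  keeps nuclear centres ≥ 6 µm apart (1.5 radii) — overlapping nuclei are
  unphysical and unsegmentable.
* Daughters are placed ± one nuclear radius from the parent (8 µm apart).
  Half that separation — an alternative convention — is unresolvable at the
  stated optics and would make every division undetectable by construction.
* Red (mKO2-Cdt1): produced in G0/G1 relaxing to 100 a.u.; degraded in S/G2
  with a 1 h half-life so red/green overlap is brief.  Green (mAG-Geminin):
  accumulates at 12 a.u./h from S entry (its level reads out time since S
  entry), collapses to 0 at mitosis, saturating at 200 a.u.
* Rendering: isotropic Gaussian spots (σ = half the nuclear radius), nuclear
  channel amplitude 300 over a background of 100, red/green gains 5; Poisson
  shot noise, Gaussian read noise (σ = 2), 16-bit clipping.
* Equi-biaxial stretch scales positions and field about the field centre;
  all pairwise distances scale by exactly the stretch factor (1.085 at the
  stretcher's maximum pressure).

### What the generator does *not* emulate

No cell death or extrusion, no directed migration, no photobleaching or
focus drift, no segmentation-hostile texture (nuclei are smooth Gaussians),
no anisotropic or spatially varying strain, and mitosis has no visible
rounding/condensation morphology — division is purely the one-frame
green-collapse + split signature.  A green pipeline test therefore
establishes correctness of the analysis logic on idealized optics, not
robustness to the full pathology of real microscopy.

## 2. Quantification stages

**Segmentation** (`segment_nuclei`): Gaussian smoothing (σ = 1 px), local
background subtraction (grey-opening approximation to a rolling ball, radius
25 px), global Otsu, hole filling, distance-transform watershed with minimum
seed separation 6 px (≈ one nuclear radius — closer seeds cannot be two
nuclei), minimum area 10 px².  A robust-noise guard (Otsu threshold must
exceed 4 MAD-sigmas) keeps blank frames empty.  Border-touching nuclei are
kept and flagged, since event counts are per-area.  Coordinates are 0-based,
x rightward, y downward.

**Tracking** (`link_frames`, `build_tracks`, `annotate_divisions`): optimal
bipartite assignment on squared displacement with a hard 1.5 µm gate (≈ 5 σ
of the per-frame Brownian step; a tighter "2× mean step" gate rejects ~4 % of
true links).  Gap closing bridges ≤ 1 missing frame.  A division is a track
terminating with ≥ 2 new tracks appearing within 6 µm in the next 2 frames;
the minimal-summed-distance pair become daughters, ties breaking to lower
track id.  Division detection here is geometric only — fluorescence
confirmation is a separate stage, so each is testable alone.

**Trace classification** (`classify_trace`): hysteresis on the balance ratio
`green/(green + red)` of background-subtracted nuclear means — GREEN above
0.60, reverting below 0.40.  With the default fluorophore kinetics the
recognition lag after true S entry is ~2.5 h; consequently S entries within
~3 h of the movie end are not yet recognized, and "accumulated" counts are a
slight undercount while mitosis counts are exact.  A mitosis requires both a
GREEN trace ending and an annotated split; either cue alone is logged as a
warning, not counted.

**Event accounting** (`count_cycle_events`): per-hour bins of S entries and
confirmed mitoses; rates reported per movie frame (0.43 mm²) and per
0.1 mm².  `divided ≤ accumulated` by construction; a cell still green at the
movie end counts as accumulated only.

**Strain estimation**: the bead estimator fits `post = s·pre + t` in closed
form (`s = Σ(pre−p̄)·(post−q̄)/Σ|pre−p̄|²`), exact on noiseless similarity
transforms, translation invariant, with independent per-axis scales reported
as an anisotropy diagnostic (not fitted).  The live-cell analogue computes
each nucleus's mean distance to its 7 nearest neighbours (k exposed, 7
validated) and reports the fractional increase of the population mean between
unmatched pre/post sets; edge cells are included.

**Statistics**: Welch t by default (pooled-variance optional), Holm-Sidak
step-down adjustment (`1 − (1−p)^(m−i+1)` with running maximum; verified
against a hand-evaluated example and a 1000-replicate null FWER check),
asymptotic two-sample KS, SEM = sd/√n with an explicit undefined flag at
n = 1.  The replicate unit is the independent simulated experiment (seed).
Comparison families are user-declared; the positive/negative intensity
threshold must be held constant across compared conditions.

## 3. Numerical choices and degenerate inputs

* Time stepping: one step per 15-min frame; hazards converted via
  `1 − exp(−h·dt)`.  Mitosis resolves within the step (instantaneous M).
* Determinism: one `numpy` Generator per state, seeded from the run seed;
  rendering uses an independent child seed.  Identical (condition, seed,
  parameters) give bit-identical ground truth.
* Degenerate inputs are rejected with explanatory errors: non-positive
  density/area/dt, shrinking stretch factors, < 3 beads or zero-variance
  bead sets, < 8 points for DNN-7, empty record lists for percentages, empty
  samples for KS, dilation that consumes the whole image.
* Empty frames yield missing values (NaN), never zeros.

## 4. Known limitations

* Tracking is not continuous through the stretch frame: the step
  displacement exceeds the gate, so image-level track statistics under
  strain conditions restart at stretch onset (treatment phenotypes are
  therefore assessed on simulator ground truth, where they are exact).
* The magnitude of strain-induced S/G2 accumulation is matched in shape
  (flat → rise after ~6–8 h), not to a published magnitude; no public value
  exists to calibrate against.
* Holm-Sidak familes, thresholds and gates are configuration, not estimates;
  the package deliberately refuses to auto-tune them.
* The activity scalar is a phenomenological stand-in: it reproduces
  epistasis (iCRT3 > Wnt/D4476 > strain) but carries no mechanistic dose
  units.
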