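# Methods

## Reporter model

The simulated system is a two-component reporter: a modification-binding
probe (target channel) and a chromatin-bound standard protein (standard
channel) expressed in fixed stoichiometry. The probe is modelled at
fast-exchange equilibrium with a single class of nuclear binding sites:
one dissociation constant `kd`, site concentration `s_tot`, free
concentration `f` equal on both sides of the nuclear envelope. Probe
conservation

    m_tot = f (v_n + v_c) + v_n · s_tot · f / (kd + f)

is a quadratic in `f`; `partition_ratio` evaluates its positive root with
the numerically stable "q" formulation (no cancellation when the linear
coefficient dominates) and returns the bound concentration
`b = s_tot f/(kd+f)`, the nuclear amount `v_n (f+b)` and the expected
readout ratio `alpha · v_n(f+b) / standard_amount`. The solution is
monotone non-decreasing in `s_tot`, non-increasing in `kd`, and is checked
against a bisection root-finder in the tests. Single-site, non-cooperative
binding and instantaneous equilibration are assumptions; the real probe
binds transiently (seconds), which is fast relative to the 5–10 min frame
intervals simulated here.

### Default calibration

Volumes are normalized (`v_n = 1`, `v_c = 19`; a plant cell's nucleus is a
small fraction of the protoplast). `m_tot = 20`, `kd = 1` put the probe in
mild depletion: binding consumes little of the total probe, so occupancy —
and hence the readout — is nearly linear in `s_tot` over the working range
(0–6; 1.7% deviation from the chord at midrange). Two consequences
matter: an exponential decay of `s_tot` reads out as an exponential ratio
decay (used by the inhibitor-treatment fit), and the dynamic range is
3.2× between `s_tot = 0` and the interphase default `s_tot = 5`. The
photometric calibration `alpha = 3000` photons per amount unit and the
standard budget of 10⁴ photons/nucleus put both channels near 10⁴
detected photons per nucleus, a realistic confocal sum-stack budget.
These are calibration choices of this package, not values taken from any
experiment.

## Scene generation

`make_root_layers_scene` places nuclei in four non-overlapping concentric
bands (epidermis outermost → pericycle innermost) by rejection sampling
with a hard minimum centre separation (default 2.5× the larger radius).
Defaults give the endodermis a lower mean site abundance and the
pericycle a 10× site-abundance variance (heterogeneous transcriptional
states among lateral-root founder cells); the control-line preset zeroes
`s_tot` everywhere, so the probe distributes by volume alone and every
nucleus shares one true ratio. `make_scatter_scene` is the single-tissue
variant for time-course and mitosis fields of view.

`make_fp_timecourse` scales every nucleus's `s_tot` by
`exp(-t/tau_decay)`, and after a washout time relaxes it back toward the
baseline with `tau_recovery`; geometry and budgets are frozen across
time. `tau_decay = inf` is the mock control. Defaults (`tau_decay` 25
min, sampling every 10 min for an hour) plateau by the end of the hour.

`make_mphase_sequence` takes one mitotic cell through a phase schedule:
prometaphase–anaphase frames set `s_tot = 0` (no accessible mark on
condensed chromatin) and concentrate the standard-channel mass into 35%
of the interphase footprint (≤ 40% enforced); telophase splits the object
into two daughters with half the budget, half the cell volume
(`volume_scale = 0.5`, which also halves `m_tot` and `v_c` so the
daughter's expected ratio matches the mother's at full recovery) and a
linear ramp of `s_tot` back to the interphase value. Interphase
neighbours are untouched.

## Rendering

Nuclei are rendered as full-depth cylinders: the circular footprint
extends through the whole Z range, as for a stack that spans the nucleus.
This is a deliberate choice over a 3-D ellipsoid: the measurement operates
on sum projections, and a flat-top column profile is what makes aperture
photometry consistent — the half-maximum contour tracks the true
footprint, and the integral inside it equals the compartment amount up to
blur edge-flux. Each compartment's total photon amount is divided evenly
over its discrete voxels, so photon conservation under voxelisation is
exact. The cytoplasm is an annular prism from 1× to 2× the nuclear radius
carrying the free probe at the same per-voxel density as the nuclear free
component (free concentration is continuous across the envelope, so the
free field is spatially flat across the nucleus boundary); vacuoles and
cell walls are not modelled.

The camera/optics model is a Gaussian PSF (lateral σ 0.5 px ≈ 0.1 µm at
0.2 µm pixels, the scale of a 60×/NA 1.2 confocal; axial σ 0.6 planes),
Poisson shot noise, linear gain, constant offset (100 counts), Gaussian
read noise (σ 2 counts) and clipping at the bit-depth ceiling (16-bit
default). All randomness flows from one integer seed through
`numpy.random.default_rng`; renders are bit-reproducible.

## Detection and segmentation

Both run on the **standard** channel only, so mask geometry is
independent of the quantity being measured. Detection is a circular
matched-filter bank: the smoothed projection (σ 1 px) is
normalized-cross-correlated with binary disk templates (radii 4–12 px by
default), the response maximised over radii, and local maxima above 0.7
accepted greedily with suppression radius 1.5× the detected radius, ties
broken by (y, x). Each template carries a 3 px background margin inside
its window: without that dark ring, smoothed read noise forms disk-like
blobs that reach NCC ≈ 0.6–0.7 against a borderless disk at the smallest
radius, while with it genuine nuclei score ≥ 0.85 and noise stays below
≈ 0.62, giving a clean threshold margin. Responses are Pearson
correlations, so the detector is invariant to offset and gain.

Segmentation is marker-controlled watershed on the inverted smoothed
projection (σ 0.5 px; brighter = lower height, 4-connectivity), restricted
to a global Otsu foreground and seeded at the detections. Each region is
then cut back to its half-maximum contour (pixels above the midpoint of
the region's intensity plateau — the 75th percentile — and the image
background): the global threshold sits far down the blurred edge and
inflates masks by 30–70% in area, whereas the half-max contour of a
blurred flat-top object tracks the true boundary. An accurate aperture
matters because the diffuse (free) probe component contributes in
proportion to mask area. Manual ROIs (polygon CSV, pixel-centre-in-polygon
rasterisation) produce the same label-image representation and flow
through the identical downstream path.

Background per channel is the median of pixels outside the label union
dilated by 15 px — the ring must clear the 2×-radius cytoplasm halo, or
the median is pulled up and ratios biased low. Frames default to 448×448
px so cytoplasm-free pixels remain the majority. QC flags (`border`,
`too_small`, `too_large`, `saturated`) are recorded per label and drive
exclusion downstream; nothing is silently dropped, and negative
background-corrected integrals are flagged rather than floored.

## Measurement and normalization

Integrated intensity is the projected sum over a label minus area ×
background; the ratio is target/standard, absent (and flagged) when the
standard integral is non-positive. Three normalizations:

* **per-root reference-tissue scaling** — each root's ratios divided by
  that root's epidermis median (median exactly 1 per root by
  construction) before roots are pooled, so roots with different
  acquisition scales combine;
* **control correction** — normalized ratios divided by the per-tissue
  median of a non-binding control line, removing tissue-specific optical
  effects (depth, scattering); applying a table to itself yields medians
  of exactly 1;
* **M/I relative ratio** — a mitotic object's ratio over the mean ratio
  of interphase neighbours within a radius, the neighbour set fixed at
  the first mitotic frame and tracked across frames by greedy
  nearest-centroid linking with a displacement gate.

Medians are used for all normalization denominators; means only for
per-root averages and the M/I neighbour pool. Time-course summaries are
per-root means per timepoint; the treatment fit is least-squares
`c + a·exp(-t/tau)` with data-driven initialisation, reporting the
half-time `tau·ln 2`.

## Statistics

`coefficient_of_variation` is the n−1 sample SD over the mean.
`wilcoxon_rank_sum` uses midranks; for combined n ≤ 16 without ties it
enumerates the exact null rank-sum distribution by dynamic programming
and reports the doubled-tail two-sided p, `min(1, 2·min(P(W≤w),
P(W≥w)))` — the convention of R's `wilcox.test`, mirrored by the
brute-force enumeration oracle in the tests; otherwise a normal
approximation with tie and continuity corrections. The t-test is Welch
by default (pooled available by flag) with Welch–Satterthwaite df;
constant-input degeneracies follow explicit conventions (equal means →
p = 1, unequal → p = 0, flagged). Bonferroni is `min(1, m·p)`;
`pairwise_tissue_tests` runs all C(k,2) tissue pairs with family size
m = C(k,2) and a significance mask on adjusted p at α = 0.05. Under the
null the family-wise error measures ≈ 0.03 (Bonferroni is conservative).

## Pipeline and determinism

One global seed fans out to per-stage child seeds via
`numpy.random.SeedSequence` over a stable (stage, item) path, so any
stage can be re-run in isolation. Every run writes the resolved config,
per-frame stacks and masks, a pooled measurement CSV (fixed column order,
6 significant digits), scenario-specific analysis tables, a log, and a
manifest with a SHA-256 per file; identical config + seed reproduce
identical hashes. Measured labels are matched to ground-truth nuclei by
greedy nearest-centroid assignment (gate 10 px) to attach tissue/phase
annotations and true ratios.

## What the generator does and does not emulate

It emulates: layered tissue geometry with tissue-dependent site
abundance, a nuclear standard and a partitioning probe with diffuse
cytoplasmic background, PSF blur, shot and read noise, saturation,
inhibitor decay/washout kinetics, and mitotic condensation/dispersal.
It does not emulate: vacuoles or irregular cell shapes, chromatin
texture within nuclei (nucleoli, heterochromatin exclusion),
depth-dependent scattering or attenuation, probe photobleaching, nucleus
movement or growth between frames, or segmentation-confounding debris.
Passing tests therefore demonstrate that the measurement chain is
unbiased and calibrated under the stated optical model, not that it is
robust to every feature of real root imagery; the manual-ROI path exists
precisely for cases where automatic detection fails on real data.

## Numerical choices and problem sizes

Quadratic root via the stable q-form; NCC through FFT-based template
matching with responses clamped where locally undefined; watershed ties
resolved by scikit-image's deterministic ordering; detection ties by
(response, y, x). Background medians; integer accumulation in int64.
Test and validation runs use desk-scale problems chosen to keep the whole
suite within a few minutes on one CPU: 448² frames with 40–50 nuclei,
five Z planes, 10⁴ photons/nucleus/channel, 12–20 scenes for detection
statistics, 10–20 seeds for time-course fits, 1000 replicates for
type-I-error calibration. The CV-scaling experiment uses uniform nucleus
radii and wider separation so the measured dispersion isolates the
photon-statistics floor; with the default radius spread (σ 0.7 px) a
budget-independent geometric dispersion component of ~2–3% adds on top,
which is also why measured control-line CVs (~0.02 uniform-geometry,
~0.04–0.05 with size variation) sit where they do.

## Known limitations

* The aperture measurement loses ≈ 0.4·σ_PSF·perimeter/area of each
  compact signal outside the mask; the loss cancels between channels for
  chromatin-bound signals but over-weights the diffuse component by a few
  percent, the dominant residual bias for small condensed objects.
* The exact rank-sum path requires untied data; ties always route to the
  corrected normal approximation regardless of sample size.
* Nearest-centroid tracking assumes displacements below the gate between
  frames; it has no appearance model and will swap labels for crossing
  nuclei.
* The equilibrium model has one site class and no cooperativity; probes
  with multivalent binding or slow exchange need a different forward
  model.
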