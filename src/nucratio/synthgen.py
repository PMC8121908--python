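"""Synthetic two-channel reporter scenes with known ground truth.

The simulated system is a two-component nuclear reporter: a probe that
shuttles between nucleus and cytoplasm and is enriched in the nucleus by
transient binding to nuclear modification sites (the *target* channel), and
a chromatin-bound standard protein expressed in fixed stoichiometry with it
(the *standard* channel).  The nuclear target/standard intensity ratio is
the readout; its expected value is a saturating function of the abundance
of unoccupied modification sites.

Probe partitioning is modelled as a fast-exchange equilibrium: a single
dissociation constant ``Kd``, one class of nuclear sites at concentration
``S_tot``, and a free-probe concentration ``f`` that equilibrates across
the nuclear envelope.  Conservation of the total probe amount ``M_tot``
over nuclear volume ``V_n`` and cytoplasmic volume ``V_c`` gives

    M_tot = f * (V_n + V_c) + V_n * S_tot * f / (Kd + f)

whose positive root is solved in closed form (:func:`partition_ratio`).

Scene generators build ground-truth nucleus layouts for the three
experiment designs the pipeline reproduces: concentric root tissue layers,
kinase-inhibitor (flavopiridol-style) decay/washout time courses, and
mitotic condensation/dispersal sequences.  :func:`render_scene` turns a
scene into a two-channel Z-stack with PSF blur, shot noise and camera read
noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .imgio import ImageStack

TISSUES = ("epidermis", "cortex", "endodermis", "pericycle")
PHASES = ("interphase", "prometaphase", "metaphase", "anaphase", "telophase")
#: mitotic phases during which chromatin is condensed and the envelope is down
CONDENSED_PHASES = ("prometaphase", "metaphase", "anaphase")


# ---------------------------------------------------------------------------
# equilibrium partition model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionParams:
    """Parameters of the equilibrium probe-partitioning model.

    Amounts and concentrations are in arbitrary but mutually consistent
    units; volumes are in normalized units (``v_n = 1`` is conventional).

    Parameters
    ----------
    m_tot : total probe amount.
    s_tot : concentration of unoccupied nuclear modification sites, on the
        same concentration scale as ``kd``.
    kd : dissociation constant of the probe-site interaction.
    v_n, v_c : nuclear and cytoplasmic volumes.
    alpha : calibration factor converting probe amount to expected photons.
    standard_amount : standard-channel nuclear amount (photon budget of the
        chromatin-bound standard); the denominator of the readout ratio.
    """

    m_tot: float
    s_tot: float
    kd: float
    v_n: float = 1.0
    v_c: float = 19.0
    alpha: float = 1.0
    standard_amount: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.m_tot, self.s_tot, self.kd, self.v_n, self.v_c,
                self.alpha, self.standard_amount)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("partition parameters must be finite")
        if self.m_tot < 0 or self.s_tot < 0:
            raise ValueError("m_tot and s_tot must be >= 0")
        if self.kd <= 0 or self.v_n <= 0 or self.alpha <= 0:
            raise ValueError("kd, v_n and alpha must be > 0")
        if self.v_c < 0 or self.standard_amount <= 0:
            raise ValueError("v_c must be >= 0 and standard_amount > 0")


@dataclass(frozen=True)
class PartitionResult:
    """Solution of the partition model for one parameter set."""

    free_conc: float          #: free probe concentration f (both compartments)
    bound_conc: float         #: bound nuclear concentration b = S_tot f/(Kd+f)
    nuclear_amount: float     #: V_n (f + b), total nuclear probe amount
    ratio: float              #: alpha * nuclear_amount / standard_amount


def partition_ratio(params: PartitionParams) -> PartitionResult:
    """Solve the equilibrium model and return the expected readout ratio.

    The free concentration is the positive root of

        (V_n+V_c) f^2 + [(V_n+V_c) Kd + S_tot V_n - M_tot] f - M_tot Kd = 0

    computed with the numerically stable quadratic formula (the ``q``
    formulation avoids cancellation when the linear coefficient dominates).
    The result is monotone non-decreasing in ``s_tot`` and non-increasing
    in ``kd``.
    """
    p = params
    a = p.v_n + p.v_c
    b = a * p.kd + p.s_tot * p.v_n - p.m_tot
    c = -p.m_tot * p.kd
    disc = b * b - 4.0 * a * c
    assert disc >= 0.0, "conservation quadratic has no real root"
    # c <= 0 guarantees one non-negative root; pick it stably
    q = -0.5 * (b + math.copysign(math.sqrt(disc), b))
    roots = [r for r in (q / a, c / q if q != 0.0 else 0.0) if r >= 0.0]
    f = max(roots) if roots else 0.0
    bound = p.s_tot * f / (p.kd + f)
    nuclear = p.v_n * (f + bound)
    return PartitionResult(
        free_conc=f,
        bound_conc=bound,
        nuclear_amount=nuclear,
        ratio=p.alpha * nuclear / p.standard_amount,
    )


# ---------------------------------------------------------------------------
# scene ground truth
# ---------------------------------------------------------------------------

@dataclass
class Nucleus:
    """Ground truth for one nucleus in one frame."""

    id: int
    y: float
    x: float
    radius_px: float
    tissue: str = "none"
    phase: str = "interphase"
    s_tot: float = 0.0
    standard_budget: float = 1e4   # photons in the standard channel
    #: cell-size factor applied to m_tot, v_n and v_c (0.5 for a daughter
    #: cell after division: half the probe, half the volumes)
    volume_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("nucleus radius must be > 0")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase label {self.phase!r}")
        if self.volume_scale <= 0:
            raise ValueError("volume_scale must be > 0")


@dataclass
class SceneTruth:
    """Ground-truth nuclei of one frame plus frame metadata."""

    nuclei: list[Nucleus]
    shape: tuple[int, int]
    pixel_size_um: float = 0.2
    t_min: float = 0.0

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nuclei]
        if len(ids) != len(set(ids)):
            raise ValueError("nucleus ids must be unique within a frame")
        h, w = self.shape
        for n in self.nuclei:
            if not (0 <= n.y < h and 0 <= n.x < w):
                raise ValueError(f"nucleus {n.id} center outside frame")

    def true_ratio(self, base: PartitionParams, nucleus: Nucleus) -> float:
        """Expected readout ratio of ``nucleus`` under model ``base``."""
        return partition_ratio(nucleus_params(base, nucleus)).ratio

    def true_ratios(self, base: PartitionParams) -> dict[int, float]:
        return {n.id: self.true_ratio(base, n) for n in self.nuclei}


@dataclass(frozen=True)
class NoiseModel:
    """Camera/optics model: Gaussian PSF, Poisson shot noise, linear camera."""

    psf_sigma_xy: float = 0.5      # px (~0.1 um lateral PSF sigma at 0.2 um pixels)
    psf_sigma_z: float = 0.6       # planes
    read_noise_sigma: float = 2.0  # counts
    camera_offset: float = 100.0   # counts
    gain: float = 1.0              # counts / photon
    bit_depth: int = 16
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if min(self.psf_sigma_xy, self.psf_sigma_z, self.read_noise_sigma,
               self.camera_offset, self.gain) < 0:
            raise ValueError("noise-model parameters must be non-negative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def saturation(self) -> int:
        return 2 ** self.bit_depth - 1


def nucleus_params(base: PartitionParams, nucleus: Nucleus) -> PartitionParams:
    """Per-nucleus partition parameters: site abundance, cell size, budget."""
    return replace(
        base,
        s_tot=nucleus.s_tot,
        m_tot=base.m_tot * nucleus.volume_scale,
        v_n=base.v_n * nucleus.volume_scale,
        v_c=base.v_c * nucleus.volume_scale,
        standard_amount=max(nucleus.standard_budget, 1e-300),
    )


NOISELESS = NoiseModel(psf_sigma_xy=0.0, psf_sigma_z=0.0,
                       read_noise_sigma=0.0, camera_offset=0.0,
                       gain=1.0, shot_noise=False)


@dataclass(frozen=True)
class LayerSpec:
    """Per-tissue layout parameters for a root-layer scene."""

    n: int
    s_tot_mean: float
    s_tot_sd: float = 0.0
    radius_mean: float = 10.0
    radius_sd: float = 0.7


@dataclass(frozen=True)
class FPScenario:
    """Kinase-inhibitor treatment time course for the modification sites.

    Site abundance decays as ``S0 exp(-t/tau_decay)``; after washout at
    ``t_wash`` it relaxes back toward ``S0`` with time constant
    ``tau_recovery``.  ``tau_decay = inf`` is the mock control.
    """

    s0: float
    tau_decay: float
    timepoints: tuple[float, ...]
    t_wash: float | None = None
    tau_recovery: float | None = None

    def __post_init__(self) -> None:
        if self.s0 <= 0 or self.tau_decay <= 0:
            raise ValueError("s0 and tau_decay must be > 0")
        if any(t < 0 for t in self.timepoints):
            raise ValueError("timepoints must be >= 0")
        if list(self.timepoints) != sorted(self.timepoints):
            raise ValueError("timepoints must be sorted ascending")
        if self.t_wash is not None and (
                self.tau_recovery is None or self.tau_recovery <= 0):
            raise ValueError("washout requires tau_recovery > 0")

    def s_tot_at(self, t: float) -> float:
        if t < 0:
            raise ValueError("timepoint before 0")
        if self.t_wash is None or t <= self.t_wash:
            return self.s0 * math.exp(-t / self.tau_decay)
        s_w = self.s0 * math.exp(-self.t_wash / self.tau_decay)
        return s_w + (self.s0 - s_w) * (
            1.0 - math.exp(-(t - self.t_wash) / self.tau_recovery))


# ---------------------------------------------------------------------------
# scene generators
# ---------------------------------------------------------------------------

#: concentric band extents per tissue, as fractions of the outer scene radius
_LAYER_BANDS: Mapping[str, tuple[float, float]] = {
    "epidermis": (0.78, 1.00),
    "cortex": (0.56, 0.78),
    "endodermis": (0.34, 0.56),
    "pericycle": (0.08, 0.34),
}


def make_root_layers_scene(
    layer_spec: Mapping[str, LayerSpec],
    shape: tuple[int, int] = (448, 448),
    seed: int = 0,
    min_separation_factor: float = 2.5,
    standard_budget: float = 1e4,
    max_tries: int = 5000,
) -> SceneTruth:
    """Place nuclei in four non-overlapping concentric tissue bands.

    Mimics the radial organisation of a root cross-section (epidermis
    outermost, pericycle innermost).  Placement is random sequential with a
    hard minimum centre separation of ``min_separation_factor`` times the
    larger of the two radii; if a band cannot host its requested nuclei an
    error names the offending layer.  Deterministic under a fixed seed.
    """
    unknown = set(layer_spec) - set(_LAYER_BANDS)
    if unknown:
        raise ValueError(f"unknown tissue layers: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    outer = 0.48 * min(h, w)
    nuclei: list[Nucleus] = []
    nid = 1
    for tissue in TISSUES:
        if tissue not in layer_spec:
            continue
        spec = layer_spec[tissue]
        if spec.n < 1:
            raise ValueError(f"layer {tissue!r} requests {spec.n} nuclei")
        lo, hi = (f * outer for f in _LAYER_BANDS[tissue])
        for _ in range(spec.n):
            radius = max(2.0, rng.normal(spec.radius_mean, spec.radius_sd))
            for attempt in range(max_tries):
                # uniform in the annulus: r ~ sqrt on [lo^2, hi^2]
                rr = math.sqrt(rng.uniform(lo * lo, hi * hi))
                th = rng.uniform(0.0, 2.0 * math.pi)
                y = cy + rr * math.sin(th)
                x = cx + rr * math.cos(th)
                if not (radius + 2 <= y < h - radius - 2
                        and radius + 2 <= x < w - radius - 2):
                    continue
                ok = all(
                    math.hypot(y - m.y, x - m.x)
                    >= min_separation_factor * max(radius, m.radius_px)
                    for m in nuclei
                )
                if ok:
                    break
            else:
                raise RuntimeError(
                    f"cannot place {spec.n} nuclei in layer {tissue!r} "
                    f"without overlap; band too narrow")
            s_tot = max(0.0, rng.normal(spec.s_tot_mean, spec.s_tot_sd))
            nuclei.append(Nucleus(id=nid, y=y, x=x, radius_px=radius,
                                  tissue=tissue, s_tot=s_tot,
                                  standard_budget=standard_budget))
            nid += 1
    return SceneTruth(nuclei=nuclei, shape=shape)


def default_layer_spec(
    n_per_layer: tuple[int, int, int, int] = (12, 10, 10, 8),
    s_tot_means: tuple[float, float, float, float] = (5.0, 4.0, 2.5, 5.0),
    s_tot_cv: float = 0.08,
    pericycle_var_factor: float = 10.0,
) -> dict[str, LayerSpec]:
    """Default tissue layout: endodermis lower, pericycle more dispersed.

    The pericycle site-abundance variance is ``pericycle_var_factor`` times
    that of the other layers, emulating the heterogeneous transcriptional
    states of presumptive lateral-root founder cells.
    """
    spec = {}
    for tissue, n, mu in zip(TISSUES, n_per_layer, s_tot_means):
        sd = s_tot_cv * mu
        if tissue == "pericycle":
            sd *= math.sqrt(pericycle_var_factor)
        spec[tissue] = LayerSpec(n=n, s_tot_mean=mu, s_tot_sd=sd)
    return spec


def make_scatter_scene(
    n: int,
    s_tot_mean: float,
    s_tot_sd: float = 0.0,
    shape: tuple[int, int] = (448, 448),
    seed: int = 0,
    tissue: str = "cortex",
    radius_mean: float = 10.0,
    radius_sd: float = 0.7,
    min_separation_factor: float = 2.5,
    standard_budget: float = 1e4,
    max_tries: int = 5000,
) -> SceneTruth:
    """Scatter nuclei of one tissue uniformly over the frame.

    Used for single-layer fields of view (e.g. cortex cells in a
    treatment time course, or the meristematic region of a mitosis
    sequence).  Same separation rule and determinism as
    :func:`make_root_layers_scene`.
    """
    if n < 1:
        raise ValueError("need at least one nucleus")
    rng = np.random.default_rng(seed)
    h, w = shape
    nuclei: list[Nucleus] = []
    for nid in range(1, n + 1):
        radius = max(2.0, rng.normal(radius_mean, radius_sd))
        for _ in range(max_tries):
            y = rng.uniform(radius + 2, h - radius - 3)
            x = rng.uniform(radius + 2, w - radius - 3)
            ok = all(
                math.hypot(y - m.y, x - m.x)
                >= min_separation_factor * max(radius, m.radius_px)
                for m in nuclei)
            if ok:
                break
        else:
            raise RuntimeError(
                f"cannot place {n} nuclei in a {shape} frame without overlap")
        s_tot = max(0.0, rng.normal(s_tot_mean, s_tot_sd))
        nuclei.append(Nucleus(id=nid, y=y, x=x, radius_px=radius,
                              tissue=tissue, s_tot=s_tot,
                              standard_budget=standard_budget))
    return SceneTruth(nuclei=nuclei, shape=shape)


def make_fp_timecourse(
    scenario: FPScenario, base_scene: SceneTruth
) -> list[SceneTruth]:
    """Apply a treatment time course to a base scene.

    Every nucleus's site abundance is scaled by the scenario's
    ``S_tot(t)/S0`` factor; geometry and photon budgets are held fixed
    across time so only the target-channel enrichment evolves.
    """
    frames = []
    for t in scenario.timepoints:
        factor = scenario.s_tot_at(t) / scenario.s0
        nuclei = [replace(n, s_tot=n.s_tot * factor)
                  for n in base_scene.nuclei]
        frames.append(SceneTruth(nuclei=nuclei, shape=base_scene.shape,
                                 pixel_size_um=base_scene.pixel_size_um,
                                 t_min=t))
    return frames


def make_mphase_sequence(
    base_scene: SceneTruth,
    mitotic_id: int,
    phase_schedule: Sequence[tuple[float, str]],
    seed: int = 0,
    condensation_area_factor: float = 0.35,
) -> list[SceneTruth]:
    """Generate a mitosis time course for one nucleus among interphase peers.

    During prometaphase-anaphase the mitotic object's sites are absent
    (``s_tot = 0``: the reporter sees no modification on condensed
    chromatin) and its standard-channel mass is concentrated into a region
    of ``condensation_area_factor`` times the interphase area (same total
    photons).  Telophase splits the object into two daughters whose site
    abundance ramps linearly back to the interphase value; neighbouring
    interphase nuclei are untouched.
    """
    if condensation_area_factor > 0.4:
        raise ValueError("condensed area must be <= 40% of interphase area")
    base = {n.id: n for n in base_scene.nuclei}
    if mitotic_id not in base:
        raise ValueError(f"no nucleus with id {mitotic_id} in base scene")
    for _, phase in phase_schedule:
        if phase not in PHASES:
            raise ValueError(f"unknown phase label {phase!r}")
    mother = base[mitotic_id]
    rng = np.random.default_rng(seed)
    split_angle = rng.uniform(0.0, 2.0 * math.pi)
    daughter_id = max(base) + 1
    n_telo = sum(1 for _, p in phase_schedule if p == "telophase")

    frames = []
    telo_i = 0
    for t, phase in phase_schedule:
        if phase == "interphase":
            mito = [replace(mother)]
        elif phase in CONDENSED_PHASES:
            mito = [replace(
                mother, phase=phase, s_tot=0.0,
                radius_px=mother.radius_px * math.sqrt(condensation_area_factor),
            )]
        else:  # telophase
            telo_i += 1
            frac = telo_i / n_telo
            r_d = mother.radius_px / math.sqrt(2.0)
            dy = 0.9 * mother.radius_px * math.sin(split_angle)
            dx = 0.9 * mother.radius_px * math.cos(split_angle)
            h, w = base_scene.shape
            mito = []
            for did, sgn in ((mitotic_id, 1.0), (daughter_id, -1.0)):
                mito.append(Nucleus(
                    id=did,
                    y=min(max(mother.y + sgn * dy, r_d + 2), h - r_d - 3),
                    x=min(max(mother.x + sgn * dx, r_d + 2), w - r_d - 3),
                    radius_px=r_d, tissue=mother.tissue, phase="telophase",
                    s_tot=mother.s_tot * frac,
                    standard_budget=mother.standard_budget / 2.0,
                    volume_scale=0.5,
                ))
        # preserve the base scene's nucleus order; daughters follow the
        # mother's slot
        nuclei: list[Nucleus] = []
        for n in base_scene.nuclei:
            if n.id == mitotic_id:
                nuclei.extend(mito)
            else:
                nuclei.append(replace(n))
        frames.append(SceneTruth(nuclei=nuclei,
                                 shape=base_scene.shape,
                                 pixel_size_um=base_scene.pixel_size_um,
                                 t_min=t))
    return frames


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _nucleus_voxels(
    nucleus: Nucleus, n_z: int, shape: tuple[int, int], scale: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel indices (z, y, x) of the nucleus volume, optionally scaled.

    The nucleus occupies its circular footprint through the full Z range
    (the imaged stack is assumed to span the nucleus), so the sum
    projection of a uniform density is a flat-topped disk.  Flat column
    profiles keep aperture photometry consistent: a half-maximum contour
    tracks the true footprint and the integral inside it equals the
    compartment amount up to blur edge-flux, which balances for a
    flat-top profile.
    """
    r = nucleus.radius_px * scale
    h, w = shape
    y0, y1 = max(0, int(nucleus.y - r) - 1), min(h, int(nucleus.y + r) + 2)
    x0, x1 = max(0, int(nucleus.x - r) - 1), min(w, int(nucleus.x + r) + 2)
    zz, yy, xx = np.meshgrid(np.arange(n_z), np.arange(y0, y1),
                             np.arange(x0, x1), indexing="ij")
    inside = (yy - nucleus.y) ** 2 + (xx - nucleus.x) ** 2 <= r * r
    return zz[inside], yy[inside], xx[inside]


def truth_label_mask(scene: SceneTruth) -> np.ndarray:
    """2-D ground-truth label image (nucleus ids) from scene geometry."""
    mask = np.zeros(scene.shape, dtype=np.int32)
    for n in scene.nuclei:
        zz, yy, xx = _nucleus_voxels(n, 1, scene.shape)
        mask[yy, xx] = n.id
    return mask


def render_scene(
    scene: SceneTruth,
    base_params: PartitionParams,
    noise: NoiseModel = NoiseModel(),
    n_z: int = 5,
    seed: int = 0,
    cytoplasm_extent: float = 2.0,
) -> ImageStack:
    """Render a scene into a two-channel Z-stack (target, standard).

    Standard channel: each nucleus's photon budget spread uniformly over
    its ellipsoid voxels.  Target channel: the nuclear probe amount from
    the partition model spread over the same voxels, plus the free
    cytoplasmic amount spread over an annular shell out to
    ``cytoplasm_extent`` times the nuclear radius.  Photon amounts are
    conserved exactly under voxelisation.  The photon image is then PSF
    blurred, shot noise applied, and converted to camera counts with
    linear gain, offset, Gaussian read noise and bit-depth clipping.
    """
    if n_z < 1:
        raise ValueError("n_z must be >= 1")
    h, w = scene.shape
    photons = np.zeros((2, n_z, h, w), dtype=np.float64)  # (C, Z, Y, X)
    for nuc in scene.nuclei:
        if nuc.standard_budget < 0:
            raise ValueError(f"negative photon budget for nucleus {nuc.id}")
        p = nucleus_params(base_params, nuc)
        res = partition_ratio(p)
        zz, yy, xx = _nucleus_voxels(nuc, n_z, scene.shape)
        if len(zz) == 0:
            continue
        target_total = p.alpha * res.nuclear_amount
        np.add.at(photons[0], (zz, yy, xx), target_total / len(zz))
        np.add.at(photons[1], (zz, yy, xx),
                  nuc.standard_budget / len(zz))
        # diffuse free probe in an annular cell-interior shell around the
        # nucleus (in-plane annulus, all Z planes).  Its per-voxel photon
        # density equals the nuclear *free* density: free-probe
        # concentration is equal across the nuclear envelope, so the free
        # component is spatially flat across the nucleus boundary.
        if cytoplasm_extent > 1.0 and p.v_c > 0:
            r_in, r_out = nuc.radius_px, cytoplasm_extent * nuc.radius_px
            h, w = scene.shape
            y0, y1 = max(0, int(nuc.y - r_out) - 1), \
                min(h, int(nuc.y + r_out) + 2)
            x0, x1 = max(0, int(nuc.x - r_out) - 1), \
                min(w, int(nuc.x + r_out) + 2)
            gy, gx = np.mgrid[y0:y1, x0:x1]
            d2 = (gy - nuc.y) ** 2 + (gx - nuc.x) ** 2
            ann = (d2 > r_in * r_in) & (d2 <= r_out * r_out)
            free_density = target_total / len(zz) \
                * res.free_conc / max(res.free_conc + res.bound_conc, 1e-300)
            photons[0][:, y0:y1, x0:x1][:, ann] += free_density
    if noise.psf_sigma_xy > 0 or noise.psf_sigma_z > 0:
        for c in range(2):
            photons[c] = gaussian_filter(
                photons[c],
                sigma=(noise.psf_sigma_z, noise.psf_sigma_xy,
                       noise.psf_sigma_xy),
                mode="constant")
    rng = np.random.default_rng(seed)
    if noise.shot_noise:
        detected = rng.poisson(photons).astype(np.float64)
    else:
        detected = photons
    counts = detected * noise.gain + noise.camera_offset
    if noise.read_noise_sigma > 0:
        counts = counts + rng.normal(0.0, noise.read_noise_sigma,
                                     size=counts.shape)
    counts = np.clip(np.rint(counts), 0, noise.saturation)
    dtype = np.uint8 if noise.bit_depth == 8 else np.uint16
    voxels = counts.astype(dtype)[np.newaxis]  # (T=1, C, Z, Y, X)
    return ImageStack(
        voxels=voxels,
        channel_roles={0: "target", 1: "standard"},
        pixel_size_xy=scene.pixel_size_um,
    )
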