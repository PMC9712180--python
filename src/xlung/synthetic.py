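"""Two-domain synthetic lung-phantom cohorts with a controllable ILD effect.

The generator emulates the statistical structure of lung CT in two
acquisition domains — a small-animal microCT-like domain and a clinical
HRCT-like domain — without any anatomical realism beyond a two-lobe
ellipsoidal lung inside a soft-tissue body:

- healthy lung parenchyma draws HU from a positively skewed shifted gamma
  (air-dominated tissue with a right tail toward denser structures), plus a
  sparse vessel/airway-wall component at a fixed offset above the subject's
  parenchymal mean and a small symmetric heavy-tail fraction (kurtosis
  driver); a low rate of benign texture patches is present in every subject;
- ILD, graded by a per-subject severity drawn from a spectrum, shifts the
  parenchymal mean up, scales the spread up, mildly symmetrizes the
  distribution and thins its tails, and adds spatially correlated fibrotic
  blobs covering ``texture_patch_rate x severity`` of the lung — lowering
  skewness and kurtosis and raising zone/dependence non-uniformity;
- subjects carry random effects (baseline mean, spread, skewness, vessel
  density, tail and patch fractions), so cohorts overlap realistically;
- the two domains differ in voxel spacing, noise level, a global HU bias
  term, and cohort heterogeneity, inducing a covariate shift with the
  disease effect itself shared;
- observer variability is emulated by smooth, bounded boundary jitter of the
  lung mask plus optional single-voxel erosion/dilation.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .prep import RoiMask, Volume, write_mask, write_volume


class PhantomConfigError(ValueError):
    """Invalid phantom configuration (e.g. the lung does not fit the grid)."""


@dataclass
class PhantomConfig:
    """Parameters of one acquisition domain's phantom population."""

    n_control: int = 20
    n_ild: int = 20
    domain_tag: str = "microct"  # {"microct", "hrct"}
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (0.14, 0.14, 0.18)
    healthy_mu_hu: float = -750.0
    healthy_sigma_hu: float = 80.0
    healthy_skew: float = 1.5
    ild_delta_mu_hu: float = 90.0
    ild_sigma_scale: float = 1.9
    ild_skew_scale: float = 0.9  # parenchymal skew multiplier at full severity
    texture_patch_rate: float = 0.12
    # benign patchy heterogeneity present in every subject (scarring, gravity-
    # dependent atelectasis): overlaps the mild-ILD patch range so texture
    # alone cannot separate the classes perfectly
    control_patch_rate: float = 0.03
    patch_rate_rel_sd: float = 0.5
    blob_mu_hu: float = -520.0
    blob_sigma_hu: float = 60.0
    noise_sigma_hu: float = 15.0
    bias_hu: float = 0.0  # global HU offset (domain shift)
    # sparse high-HU vessel/airway-wall component at a fixed offset above the
    # subject's parenchymal mean: the healthy lung's heavy right tail, with
    # per-subject density variation
    vessel_rate: float = 0.015
    vessel_offset_hu: float = 400.0
    vessel_sigma_hu: float = 80.0
    vessel_rate_rel_sd: float = 0.8
    # symmetric heavy-tail component: a per-subject fraction of parenchymal
    # deviations inflated by hv_gain (mixed texture floor); drives kurtosis
    # semi-independently of skewness, and ILD suppresses it ("thin tails")
    hv_frac: float = 0.03
    hv_gain: float = 3.0
    hv_frac_rel_sd: float = 0.65
    ild_hv_drop: float = 0.25
    # between-subject heterogeneity: healthy baseline varies per subject, and
    # ILD severity spans a spectrum (early to established fibrosis) that
    # scales the mean shift, the spread increase, and the fibrotic patch rate
    subject_mu_sd_hu: float = 50.0
    subject_sigma_rel_sd: float = 0.17
    subject_skew_rel_sd: float = 0.33
    ild_severity_range: tuple[float, float] = (0.3, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.domain_tag not in ("microct", "hrct"):
            raise PhantomConfigError(f"unknown domain tag {self.domain_tag!r}")
        if any(n < 16 for n in self.grid_shape):
            raise PhantomConfigError("grid_shape must be >= 16 along every axis")
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomConfigError("spacing must be strictly positive")
        if not (0.0 <= self.texture_patch_rate <= 1.0):
            raise PhantomConfigError("texture_patch_rate must lie in [0, 1]")
        if self.healthy_skew <= 0:
            raise PhantomConfigError("healthy_skew must be positive")
        if self.healthy_sigma_hu <= 0 or self.noise_sigma_hu < 0:
            raise PhantomConfigError("sigma parameters must be nonnegative")


def microct_config(**overrides) -> PhantomConfig:
    """Mouse-like domain: fine anisotropic spacing, low noise."""
    return PhantomConfig(**overrides)


def hrct_config(**overrides) -> PhantomConfig:
    """Human-like domain: coarse spacing, higher noise, global HU bias,
    larger cohort heterogeneity."""
    base = dict(
        domain_tag="hrct",
        grid_shape=(96, 96, 96),
        spacing_mm=(2.5, 2.5, 3.0),
        noise_sigma_hu=30.0,
        bias_hu=60.0,
        # patient cohorts are clinically more heterogeneous than inbred mice
        subject_mu_sd_hu=65.0,
        subject_sigma_rel_sd=0.27,
    )
    base.update(overrides)
    return PhantomConfig(**base)


@dataclass
class ObserverPerturbation:
    """Emulates repeated / multi-observer lung delineations."""

    n_observers: int = 3
    n_repeats: int = 2
    boundary_jitter_mm: float = 0.1
    erosion_dilation_prob: float = 0.02

    def __post_init__(self) -> None:
        if self.n_observers < 2:
            raise ValueError("interobserver analysis needs n_observers >= 2")
        if self.boundary_jitter_mm < 0 or not (0 <= self.erosion_dilation_prob <= 1):
            raise ValueError("invalid perturbation parameters")


# ---------------------------------------------------------------------------
# Phantom geometry and intensities
# ---------------------------------------------------------------------------

def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def lung_mask_for(cfg: PhantomConfig) -> np.ndarray:
    """Two-lobe ellipsoidal lung; raises if the lobes do not fit the grid."""
    nx, ny, nz = cfg.grid_shape
    radii = (0.16 * nx, 0.28 * ny, 0.36 * nz)
    if min(radii) < 2:
        raise PhantomConfigError("lung lobes do not fit the configured grid")
    cx_l, cx_r = 0.30 * nx, 0.70 * nx
    cy, cz = ny / 2, nz / 2
    left = _ellipsoid(cfg.grid_shape, (cx_l, cy, cz), radii)
    right = _ellipsoid(cfg.grid_shape, (cx_r, cy, cz), radii)
    return left | right


def _gamma_params(mu: float, sigma: float, skew: float):
    """Shifted-gamma parameterization: HU = anchor + Gamma(shape, scale)."""
    shape = (2.0 / skew) ** 2
    scale = sigma / np.sqrt(shape)
    anchor = mu - shape * scale
    return shape, scale, anchor


def expected_ild_mean_shift(cfg: PhantomConfig) -> float:
    """Closed-form expected mean HU difference (ILD − control) within lung.

    Averages the per-subject mixture mean over the uniform severity
    distribution s ~ U(lo, hi). Parenchyma plus the mean-relative vessel
    component average to mu + q*v_off in both arms (the heavy-tail inflation
    is symmetric and mean-preserving); fibrotic patches overwrite a fraction
    p*s of the lung, so the shift against a control subject is
    (1 - p s)(mu + d s + q v_off) + p s mu_b - (mu + q v_off).
    """
    lo, hi = cfg.ild_severity_range
    m1 = (lo + hi) / 2.0
    m2 = (lo**2 + lo * hi + hi**2) / 3.0
    p = cfg.texture_patch_rate
    c = cfg.control_patch_rate
    f = float(np.exp(cfg.patch_rate_rel_sd**2 / 2.0))  # mean lognormal factor
    d = cfg.ild_delta_mu_hu
    mu = cfg.healthy_mu_hu
    qv = cfg.vessel_rate * cfg.vessel_offset_hu
    return d * m1 - f * (
        (mu + qv - cfg.blob_mu_hu) * p * m1 + d * (c * m1 + p * m2)
    )


def generate_phantom(
    cfg: PhantomConfig, label: str, seed: int | None = None
) -> tuple[Volume, RoiMask]:
    """Generate one phantom volume and its true lung mask.

    ``label`` is ``"control"`` or ``"ild"``. The per-subject ``seed`` defaults
    to ``cfg.seed``.
    """
    if label not in ("control", "ild"):
        raise ValueError(f"label must be 'control' or 'ild', got {label!r}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    shape = cfg.grid_shape
    lung = lung_mask_for(cfg)

    data = np.full(shape, -1000.0)
    body = _ellipsoid(shape, tuple(n / 2 for n in shape), tuple(0.47 * n for n in shape))
    data[body] = 30.0  # soft tissue

    # per-subject random effects: baseline offset, spread/skew factors,
    # vessel density, heavy-tail fraction, ILD severity
    mu_offset = rng.normal(0.0, cfg.subject_mu_sd_hu)
    sigma_factor = max(0.5, 1.0 + rng.normal(0.0, cfg.subject_sigma_rel_sd))
    skew_factor = max(0.3, 1.0 + rng.normal(0.0, cfg.subject_skew_rel_sd))
    vessel_rate = cfg.vessel_rate * np.exp(rng.normal(0.0, cfg.vessel_rate_rel_sd))
    hv_frac = cfg.hv_frac * np.exp(rng.normal(0.0, cfg.hv_frac_rel_sd))
    severity = rng.uniform(*cfg.ild_severity_range)

    skew = cfg.healthy_skew * skew_factor
    if label == "ild":
        mu = cfg.healthy_mu_hu + mu_offset + cfg.ild_delta_mu_hu * severity
        sigma = cfg.healthy_sigma_hu * sigma_factor * (
            1.0 + (cfg.ild_sigma_scale - 1.0) * severity
        )
        # fibrosis fills the air-dominated tail: distribution symmetrizes
        skew *= 1.0 - (1.0 - cfg.ild_skew_scale) * severity
        # ... and thins the tails: the heavy-tail fraction shrinks
        hv_frac *= 1.0 - cfg.ild_hv_drop * severity
        patch_rate = cfg.control_patch_rate + cfg.texture_patch_rate * severity
    else:
        mu = cfg.healthy_mu_hu + mu_offset
        sigma = cfg.healthy_sigma_hu * sigma_factor
        patch_rate = cfg.control_patch_rate
    patch_rate *= np.exp(rng.normal(0.0, cfg.patch_rate_rel_sd))
    patch_rate = min(patch_rate, 0.6)
    g_shape, g_scale, _ = _gamma_params(mu, sigma, skew)
    n_lung = int(lung.sum())
    dev = rng.gamma(g_shape, g_scale, size=n_lung) - g_shape * g_scale
    if hv_frac > 0:
        inflate = rng.random(n_lung) < hv_frac
        dev[inflate] *= cfg.hv_gain
    data[lung] = mu + dev

    if vessel_rate > 0:
        vessels = lung & (rng.random(shape) < vessel_rate)
        nv = int(vessels.sum())
        data[vessels] = rng.normal(mu + cfg.vessel_offset_hu, cfg.vessel_sigma_hu, size=nv)

    if patch_rate > 0:
        field3 = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
        vals = field3[lung]
        thr = np.quantile(vals, 1.0 - patch_rate)
        blobs = lung & (field3 > thr)
        nb = int(blobs.sum())
        data[blobs] = rng.normal(cfg.blob_mu_hu, cfg.blob_sigma_hu, size=nb)

    data += cfg.bias_hu
    if cfg.noise_sigma_hu > 0:
        data += rng.normal(0.0, cfg.noise_sigma_hu, size=shape)
    np.clip(data, -1000.0, 200.0, out=data)
    return Volume(data, cfg.spacing_mm), RoiMask(lung, cfg.spacing_mm)


# ---------------------------------------------------------------------------
# Mask perturbation
# ---------------------------------------------------------------------------

def dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    return 2.0 * inter / (a.sum() + b.sum())


def perturb_mask(mask: RoiMask, obs: ObserverPerturbation, seed: int) -> RoiMask:
    """Smooth, bounded boundary jitter plus optional 1-voxel erosion/dilation.

    The boundary displacement is bounded by ``boundary_jitter_mm``; a Dice
    overlap of at least 0.5 with the input is enforced (retry with halved
    jitter, then error). The underlying volume is never touched.
    """
    if not mask.data.any():
        raise ValueError("cannot perturb an empty mask")
    rng = np.random.default_rng(seed)
    jitter_mm = obs.boundary_jitter_mm
    do_morph = rng.random() < obs.erosion_dilation_prob
    morph_op = rng.choice(["erode", "dilate"])

    for _ in range(4):
        new = _jitter_once(mask.data, mask.spacing, jitter_mm, rng)
        if do_morph and jitter_mm == obs.boundary_jitter_mm:
            if morph_op == "erode":
                eroded = ndimage.binary_erosion(new)
                new = eroded if eroded.any() else new
            else:
                new = ndimage.binary_dilation(new)
        if new.any() and dice(new, mask.data) >= 0.5:
            return RoiMask(new, mask.spacing, mask.origin)
        jitter_mm /= 2.0
    raise ValueError("mask perturbation kept emptying the mask or breaking overlap")


def _jitter_once(mask: np.ndarray, spacing, jitter_mm: float, rng) -> np.ndarray:
    if jitter_mm == 0:
        return mask.copy()
    # signed Euclidean distance to the mask boundary, in mm (negative inside)
    sampling = tuple(spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=sampling)
    outside = ndimage.distance_transform_edt(~mask, sampling=sampling)
    sdist = outside - inside
    noise = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma=3.0)
    sd = noise.std()
    if sd > 0:
        noise = np.clip(noise / (2.5 * sd), -1.0, 1.0)  # |field| <= 1
    return sdist <= noise * jitter_mm


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "subject_id", "domain", "label", "observer", "repeat", "volume_path", "mask_path",
]


def generate_cohort_entries(
    cfg: PhantomConfig,
    obs: ObserverPerturbation | None = None,
    n_stability_cases: int = 15,
) -> list[dict]:
    """Generate one domain's cohort in memory.

    Returns a list of manifest-like dicts carrying ``volume``/``mask`` objects.
    The main-analysis row of every subject has ``observer == 1, repeat == 1``.
    The first ``n_stability_cases`` subjects (alternating labels) additionally
    carry ``n_repeats`` intra-observer masks (observer 1) and ``n_observers``
    inter-observer masks (repeat 1), all perturbations of the true mask.
    """
    ss = np.random.SeedSequence(cfg.seed)
    labels = ["control"] * cfg.n_control + ["ild"] * cfg.n_ild
    # alternate labels so any stability subset prefix contains both classes
    interleaved = []
    ctrl = [l for l in labels if l == "control"]
    ild = [l for l in labels if l == "ild"]
    while ctrl or ild:
        if ild:
            interleaved.append(ild.pop())
        if ctrl:
            interleaved.append(ctrl.pop())
    labels = interleaved

    subj_seeds = ss.spawn(len(labels))
    entries: list[dict] = []
    for idx, (label, sseq) in enumerate(zip(labels, subj_seeds)):
        sid = f"{cfg.domain_tag}_{idx:03d}"
        child = sseq.spawn(2)
        vol, true_mask = generate_phantom(cfg, label, seed=child[0])
        is_stability = obs is not None and idx < n_stability_cases
        variants: list[tuple[int, int]] = [(1, 1)]
        if is_stability:
            variants += [(1, r) for r in range(2, obs.n_repeats + 1)]
            variants += [(o, 1) for o in range(2, obs.n_observers + 1)]
        mask_seeds = child[1].spawn(len(variants))
        for (o, r), mseq in zip(variants, mask_seeds):
            if obs is not None and is_stability:
                m = perturb_mask(true_mask, obs, seed=mseq)
            else:
                m = true_mask
            entries.append(
                dict(
                    subject_id=sid, domain=cfg.domain_tag, label=label,
                    observer=o, repeat=r, volume=vol, mask=m,
                )
            )
    return entries


def generate_cohort(
    cfg_mouse: PhantomConfig,
    cfg_human: PhantomConfig,
    obs: ObserverPerturbation | None = None,
    out_dir=None,
    n_stability_cases: int = 15,
) -> pd.DataFrame:
    """Generate a two-domain cohort; optionally write volumes/masks + manifest.

    With ``out_dir`` set, volumes and masks are written as ``.nii.gz`` and the
    returned manifest carries their paths; otherwise the manifest carries
    in-memory objects in ``volume``/``mask`` columns.
    """
    entries = generate_cohort_entries(cfg_mouse, obs, n_stability_cases)
    entries += generate_cohort_entries(cfg_human, obs, n_stability_cases)
    if out_dir is None:
        return pd.DataFrame(entries)

    from pathlib import Path

    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    rows = []
    written = set()
    for e in entries:
        vpath = out / "volumes" / f"{e['subject_id']}_ct.nii.gz"
        mpath = out / "volumes" / f"{e['subject_id']}_mask_o{e['observer']}_r{e['repeat']}.nii.gz"
        if e["subject_id"] not in written:
            write_volume(e["volume"], vpath)
            written.add(e["subject_id"])
        write_mask(e["mask"], mpath)
        rows.append(
            dict(
                subject_id=e["subject_id"], domain=e["domain"], label=e["label"],
                observer=e["observer"], repeat=e["repeat"],
                volume_path=str(vpath), mask_path=str(mpath),
            )
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def main_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Main-analysis rows: one per subject (observer 1, repeat 1)."""
    return table[(table["observer"] == 1) & (table["repeat"] == 1)].reset_index(drop=True)
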