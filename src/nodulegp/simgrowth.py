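"""Synthetic longitudinal lung-nodule patch simulator.

Generates paired baseline/follow-up 64x64 nodule image patches (32 mm square
ROI at 0.5 mm/pixel) with the statistical structure a growth-predictive model
is trained on: benign nodules are stable over the screening interval while
malignant nodules grow according to a sampled volume doubling time (VDT),

    d(t) = d0 * 2**(elapsed_days / (3 * VDT)),

the diameter form of exponential volume doubling. Nodules are rendered as
radially symmetric smoothed disks (sigmoid edge) with optional radial
spiculations, solid / ground-glass / mixed attenuation classes, a correlated
background field mimicking lung parenchyma, and additive per-timepoint noise.
Every operation is a pure function of its inputs and an integer seed.

Default distributions follow the cohort structure of NLST-style screening
populations: baseline equivalent diameters 4-30 mm, VDT between roughly six
months and four years for the malignant class, and margin/attenuation class
frequencies near those reported for screening-detected nodules.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "DAYS_PER_MONTH",
    "ImagePatch",
    "NodulePair",
    "SimulatorConfig",
    "SyntheticNoduleParams",
    "derive_seed",
    "generate_dataset",
    "generate_pair",
    "load_dataset",
    "measure_diameter_mm",
    "render_patch",
    "sample_nodule_params",
    "write_dataset",
]

DAYS_PER_MONTH = 365.25 / 12.0

_MASK64 = (1 << 64) - 1


def derive_seed(master_seed: int, index: int) -> int:
    """Derive an independent child seed via a splitmix64-style integer hash.

    Keeps per-subject random streams decorrelated without consuming a shared
    generator, so datasets are reproducible under any evaluation order.
    """
    z = (int(master_seed) + (int(index) + 1) * 0x9E3779B97F4A7C15) & _MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    z = z ^ (z >> 31)
    return int(z & 0x7FFFFFFF)


class ConfigurationError(ValueError):
    """Raised when simulator settings are internally inconsistent."""


@dataclass(frozen=True)
class SimulatorConfig:
    """Distribution bounds and rendering settings for the simulator.

    Class-conditional frequencies (spiculated margin, attenuation mix) follow
    screening-cohort proportions; rendering constants are chosen so that, under
    a (-1000, 400) HU display window mapped to [0, 1], background parenchyma
    sits near 0.11, ground-glass attenuation near 0.3-0.45 and solid tissue
    near 0.7-0.85.
    """

    diameter_range_mm: tuple[float, float] = (4.0, 30.0)
    # class-conditional baseline size: screening-detected malignant nodules
    # run markedly larger than benign ones (size is the dominant single-scan
    # malignancy correlate); lognormal (median, log-sd), truncated to range
    diameter_lognorm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"malignant": (13.0, 0.40),
                                 "benign": (6.0, 0.45)})
    vdt_range_days: tuple[float, float] = (180.0, 1460.0)
    spiculated_prob: dict[str, float] = field(
        default_factory=lambda: {"malignant": 0.27, "benign": 0.08})
    spicule_count_range: tuple[int, int] = (4, 9)
    attenuation_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            # (solid, ground_glass, mixed)
            "malignant": (0.71, 0.20, 0.09),
            "benign": (0.81, 0.13, 0.06),
        })
    solid_peak_range: tuple[float, float] = (0.70, 0.85)
    ground_glass_peak_range: tuple[float, float] = (0.30, 0.45)
    center_offset_max_mm: float = 2.0
    noise_sd: float = 0.02
    background_mean: float = 0.11
    background_sd: float = 0.03
    background_smooth_px: float = 1.5
    edge_softness_mm: float = 0.6
    spicule_amplitude_range: tuple[float, float] = (0.15, 0.30)
    spicule_width_rad: float = 0.10
    benign_jitter: bool = False  # +/-10% diameter jitter at follow-up
    patch_size: int = 64
    pixel_spacing_mm: float = 0.5

    def validate(self) -> None:
        lo, hi = self.diameter_range_mm
        if not (0 < lo <= hi):
            raise ConfigurationError(f"invalid diameter range ({lo}, {hi})")
        for label, (med, sd) in self.diameter_lognorm.items():
            if not (lo <= med <= hi) or sd <= 0:
                raise ConfigurationError(
                    f"diameter_lognorm[{label}]=({med}, {sd}) inconsistent "
                    f"with range ({lo}, {hi})")
        vlo, vhi = self.vdt_range_days
        if not (0 < vlo <= vhi):
            raise ConfigurationError(f"invalid VDT range ({vlo}, {vhi})")
        for label, p in self.spiculated_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"spiculated_prob[{label}]={p}")
        for label, probs in self.attenuation_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ConfigurationError(
                    f"attenuation_probs[{label}] must be a distribution")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticNoduleParams:
    """Ground-truth description of one synthetic nodule."""

    diameter_mm: float
    malignant: bool
    vdt_days: float | None
    margin: str  # "smooth" | "spiculated"
    spicule_count: int
    attenuation: str  # "solid" | "ground_glass" | "mixed"
    peak_intensity: float
    center_offset_mm: tuple[float, float]
    noise_sd: float
    seed: int

    def __post_init__(self):
        if not 4.0 <= self.diameter_mm <= 30.0:
            raise ValueError(f"diameter_mm={self.diameter_mm} outside [4, 30]")
        if self.malignant:
            if self.vdt_days is None or not 180.0 <= self.vdt_days <= 1460.0:
                raise ValueError(
                    f"malignant nodules need vdt_days in [180, 1460], got {self.vdt_days}")
        elif self.vdt_days is not None:
            raise ValueError("benign nodules are stable: vdt_days must be None")
        if self.margin not in ("smooth", "spiculated"):
            raise ValueError(f"margin={self.margin!r}")
        if self.margin == "smooth" and self.spicule_count != 0:
            raise ValueError("smooth margin requires spicule_count == 0")
        if self.spicule_count < 0:
            raise ValueError("spicule_count must be >= 0")
        if self.attenuation not in ("solid", "ground_glass", "mixed"):
            raise ValueError(f"attenuation={self.attenuation!r}")
        if not 0.0 < self.peak_intensity <= 1.0:
            raise ValueError("peak_intensity must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ImagePatch:
    """A 64x64 grid of normalized intensities covering a 32 mm square ROI."""

    values: np.ndarray
    pixel_spacing_mm: float = 0.5
    side_mm: float = 32.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"patch must be square 2D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("patch contains non-finite values")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("patch values must lie in [0, 1]")
        expected = v.shape[0] * self.pixel_spacing_mm
        if not math.isclose(self.side_mm, expected, rel_tol=1e-9):
            raise ValueError(
                f"side_mm={self.side_mm} != {v.shape[0]} * {self.pixel_spacing_mm}")

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class NodulePair:
    """One subject's baseline/follow-up patch pair — the unit of training."""

    baseline: ImagePatch
    followup: ImagePatch
    interval_months: float
    label: str  # "benign" | "malignant"
    subject_id: str

    def __post_init__(self):
        if self.interval_months <= 0:
            raise ValueError("interval_months must be positive")
        if self.label not in ("benign", "malignant"):
            raise ValueError(f"label={self.label!r}")
        if not math.isclose(self.baseline.pixel_spacing_mm,
                            self.followup.pixel_spacing_mm):
            raise ValueError("baseline and follow-up pixel spacing differ")


# ------------------------------------------------------------------ sampling
def sample_nodule_params(seed: int, label: str,
                         config: SimulatorConfig | None = None
                         ) -> SyntheticNoduleParams:
    """Draw one nodule's ground-truth parameters, deterministically in seed."""
    if label not in ("benign", "malignant"):
        raise ValueError(f"label={label!r}")
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    config = config or SimulatorConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    malignant = label == "malignant"

    lo, hi = config.diameter_range_mm
    med, log_sd = config.diameter_lognorm[label]
    diameter = float(np.clip(np.exp(np.log(med)
                                    + log_sd * rng.standard_normal()),
                             lo, hi))
    if malignant:
        vlo, vhi = config.vdt_range_days
        vdt = float(np.exp(rng.uniform(np.log(vlo), np.log(vhi))))
    else:
        vdt = None

    spiculated = rng.random() < config.spiculated_prob[label]
    n_spicules = int(rng.integers(*config.spicule_count_range,
                                  endpoint=True)) if spiculated else 0

    attenuation = str(rng.choice(["solid", "ground_glass", "mixed"],
                                 p=config.attenuation_probs[label]))
    if attenuation == "ground_glass":
        peak = float(rng.uniform(*config.ground_glass_peak_range))
    else:
        peak = float(rng.uniform(*config.solid_peak_range))

    off = config.center_offset_max_mm
    offset = (float(rng.uniform(-off, off)), float(rng.uniform(-off, off)))

    return SyntheticNoduleParams(
        diameter_mm=diameter,
        malignant=malignant,
        vdt_days=vdt,
        margin="spiculated" if spiculated else "smooth",
        spicule_count=n_spicules,
        attenuation=attenuation,
        peak_intensity=peak,
        center_offset_mm=offset,
        noise_sd=config.noise_sd,
        seed=int(seed),
    )


# ----------------------------------------------------------------- rendering
def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _edge_radius(theta: np.ndarray, radius_mm: float,
                 params: SyntheticNoduleParams,
                 config: SimulatorConfig) -> np.ndarray:
    """Angular edge-radius function; spiculation adds narrow radial spikes."""
    r_edge = np.full_like(theta, radius_mm)
    if params.spicule_count > 0:
        rng = np.random.default_rng(derive_seed(params.seed, 101))
        angles = rng.uniform(0, 2 * np.pi, size=params.spicule_count)
        amps = rng.uniform(*config.spicule_amplitude_range,
                           size=params.spicule_count)
        width = config.spicule_width_rad
        for ang, amp in zip(angles, amps):
            d = np.angle(np.exp(1j * (theta - ang)))  # wrapped difference
            r_edge = r_edge + radius_mm * amp * np.exp(-0.5 * (d / width) ** 2)
    return r_edge


def _nodule_foreground(params: SyntheticNoduleParams, diameter_mm: float,
                       config: SimulatorConfig) -> np.ndarray:
    n = config.patch_size
    half = n * config.pixel_spacing_mm / 2.0
    coords = (np.arange(n) + 0.5) * config.pixel_spacing_mm - half
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    oy, ox = params.center_offset_mm
    dy, dx = yy - oy, xx - ox
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    soft = config.edge_softness_mm

    def disk(radius_mm: float, peak: float,
             softness_mm: float | None = None) -> np.ndarray:
        r_edge = _edge_radius(theta, radius_mm, params, config)
        return peak * _sigmoid((r_edge - r) / (softness_mm or soft))

    radius = diameter_mm / 2.0
    if params.attenuation == "mixed":
        # solid core inside a ground-glass halo. The core's edge softness
        # scales with its radius so every length in the profile is
        # proportional to the diameter and growth ratios stay exact; the
        # profile-scan diameter of a mixed nodule tracks the dense core.
        core_radius = radius * 0.5
        rim = disk(radius, 0.35)
        core = disk(core_radius, min(params.peak_intensity, 0.5),
                    softness_mm=max(0.12 * core_radius, 0.15))
        return rim + core
    return disk(radius, params.peak_intensity)


def render_patch(params: SyntheticNoduleParams, elapsed_months: float,
                 config: SimulatorConfig | None = None,
                 diameter_scale: float = 1.0) -> ImagePatch:
    """Render the nodule as imaged ``elapsed_months`` after baseline.

    Malignant nodules grow as d(t) = d0 * 2**(t_days / (3 VDT)); benign
    nodules keep their baseline diameter. The anatomical background and the
    spicule geometry are fixed per nodule; acquisition noise is redrawn per
    timepoint. Diameters beyond 30 mm (long follow-up of fast growers) are
    clipped and flagged in ``meta['diameter_clipped']``.
    """
    if elapsed_months < 0:
        raise ValueError("elapsed_months must be >= 0")
    config = config or SimulatorConfig()
    config.validate()

    d = params.diameter_mm * diameter_scale
    if params.malignant:
        days = elapsed_months * DAYS_PER_MONTH
        d = d * 2.0 ** (days / (3.0 * params.vdt_days))
    clipped = False
    if d > 30.0:
        d, clipped = 30.0, True

    foreground = _nodule_foreground(params, d, config)

    bg_rng = np.random.default_rng(derive_seed(params.seed, 7))
    field_ = gaussian_filter(bg_rng.standard_normal(foreground.shape),
                             config.background_smooth_px)
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd
    background = config.background_mean + config.background_sd * field_

    noise = 0.0
    if params.noise_sd > 0:
        t_tag = 1000 + int(round(elapsed_months * 1000))
        noise_rng = np.random.default_rng(derive_seed(params.seed, t_tag))
        noise = params.noise_sd * noise_rng.standard_normal(foreground.shape)

    values = np.clip(background + foreground + noise, 0.0, 1.0)
    return ImagePatch(values=values,
                      pixel_spacing_mm=config.pixel_spacing_mm,
                      side_mm=config.patch_size * config.pixel_spacing_mm,
                      meta={"diameter_clipped": clipped,
                            "rendered_diameter_mm": d})


def generate_pair(params: SyntheticNoduleParams, interval_months: float = 12.0,
                  config: SimulatorConfig | None = None,
                  subject_id: str | None = None) -> NodulePair:
    """Render the baseline/follow-up pair for one nodule."""
    config = config or SimulatorConfig()
    baseline = render_patch(params, 0.0, config)
    scale = 1.0
    if config.benign_jitter and not params.malignant:
        jitter_rng = np.random.default_rng(derive_seed(params.seed, 55))
        scale = float(jitter_rng.uniform(0.9, 1.1))
    followup = render_patch(params, interval_months, config,
                            diameter_scale=scale)
    return NodulePair(
        baseline=baseline,
        followup=followup,
        interval_months=float(interval_months),
        label="malignant" if params.malignant else "benign",
        subject_id=subject_id or f"synthetic-{params.seed:08d}",
    )


def generate_dataset(n_malignant: int, n_benign: int, seed: int,
                     config: SimulatorConfig | None = None,
                     interval_months: float = 12.0
                     ) -> tuple[list[NodulePair], np.ndarray]:
    """Generate a labelled cohort of baseline/follow-up pairs.

    Returns exactly ``n_malignant + n_benign`` pairs (malignant first) and the
    matching 0/1 label vector. Per-subject seeds derive from ``seed`` through
    :func:`derive_seed`, so the dataset is byte-reproducible.
    """
    if n_malignant < 0 or n_benign < 0:
        raise ValueError("counts must be non-negative")
    config = config or SimulatorConfig()
    pairs: list[NodulePair] = []
    labels = []
    for i in range(n_malignant + n_benign):
        label = "malignant" if i < n_malignant else "benign"
        params = sample_nodule_params(derive_seed(seed, i), label, config)
        pairs.append(generate_pair(params, interval_months, config,
                                   subject_id=f"S{i:05d}"))
        labels.append(1 if label == "malignant" else 0)
    return pairs, np.asarray(labels, dtype=int)


# --------------------------------------------------------------- measurement
def measure_diameter_mm(patch: ImagePatch) -> float:
    """Estimate nodule diameter by a full-width-half-maximum profile scan.

    Independent of the renderer's internals: locates the intensity peak on a
    lightly smoothed copy, builds a median radial profile (median over angles
    suppresses spicules and noise), and interpolates the radius at which the
    profile crosses halfway between peak and background (border median).
    """
    v = patch.values
    n = v.shape[0]
    smoothed = gaussian_filter(v, 1.0)
    border = np.concatenate([v[0], v[-1], v[:, 0], v[:, -1]])
    bg = float(np.median(border))

    # centre: centroid of the above-half-maximum mask (argmax alone wanders
    # on the flat top of large nodules)
    peak0 = float(smoothed.max())
    mask = smoothed > bg + 0.5 * (peak0 - bg)
    if mask.any():
        ys, xs = np.nonzero(mask)
        cy, cx = int(round(ys.mean())), int(round(xs.mean()))
    else:
        cy, cx = np.unravel_index(np.argmax(smoothed), smoothed.shape)

    yy, xx = np.indices(v.shape)
    r = np.hypot(yy - cy, xx - cx)
    rbins = np.round(r).astype(int)
    max_r = min(n // 2, rbins.max())
    profile = np.array([np.median(v[rbins == k]) for k in range(max_r + 1)])

    peak = float(max(profile[0], smoothed[cy, cx]))
    half = bg + 0.5 * (peak - bg)
    below = np.nonzero(profile < half)[0]
    if len(below) == 0:
        return 2.0 * max_r * patch.pixel_spacing_mm
    k = int(below[0])
    if k == 0:
        return 0.0
    # linear interpolation between bins k-1 and k
    p0, p1 = profile[k - 1], profile[k]
    frac = (p0 - half) / (p0 - p1) if p0 != p1 else 0.5
    radius_px = (k - 1) + frac
    return float(2.0 * radius_px * patch.pixel_spacing_mm)


# ---------------------------------------------------------------- file forms
def write_dataset(pairs: Sequence[NodulePair], out_dir: str | Path) -> Path:
    """Write patches as 16-bit PNGs plus a manifest CSV; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "label", "interval_months",
                         "baseline_path", "followup_path"])
        for pair in pairs:
            paths = []
            for tag, patch in (("baseline", pair.baseline),
                               ("followup", pair.followup)):
                fn = f"{pair.subject_id}_{tag}.png"
                arr = np.round(patch.values * 65535.0).astype(np.uint16)
                iio.imwrite(out / fn, arr)
                paths.append(fn)
            writer.writerow([pair.subject_id, pair.label,
                             pair.interval_months, *paths])
    return manifest


def load_dataset(directory: str | Path) -> list[NodulePair]:
    """Read back a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    pairs: list[NodulePair] = []
    with open(directory / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            patches = {}
            for tag in ("baseline", "followup"):
                arr = iio.imread(directory / row[f"{tag}_path"])
                patches[tag] = ImagePatch(arr.astype(np.float64) / 65535.0)
            pairs.append(NodulePair(
                baseline=patches["baseline"],
                followup=patches["followup"],
                interval_months=float(row["interval_months"]),
                label=row["label"],
                subject_id=row["subject_id"],
            ))
    return pairs
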