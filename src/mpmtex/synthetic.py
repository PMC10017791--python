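"""Seeded synthetic two-class, three-channel FoV cohorts.

The generator emulates the texture contrast between colorectal liver
metastasis and normal liver parenchyma as it appears in label-free
multiphoton tiles, without attempting photorealism:

* **normal** tiles: quasi-periodic hepatocyte-cord bands in CARS and TPEF
  (cords one to two cells thick), bright CARS lipid droplets (mild
  steatosis), and sparse SHG collagen fibers (reticulin);
* **tumor** tiles: ring/nest gland motifs (bright epithelial rims around
  darker lumina) in CARS and TPEF, no droplets, and a dense mesh of SHG
  stroma fibers.

Both classes are rendered by one routine driven by a continuous motif
parameter vector.  The *separability* knob s in [0, 1] linearly
interpolates the tumor parameter vector from the normal one (s = 0, the
two classes are draws from the identical distribution) to the full tumor
motif (s = 1).  The class signal therefore enters through motif geometry
and density — second-order texture — not merely through mean brightness.

Intensities are photon-like counts (Poisson or Gaussian noise around a
smooth motif field scaled to ~22 000 counts) stored as 16-bit rasters,
leaving clear headroom below the 65 535 saturation ceiling so that only
deliberately generated artifact tiles saturate.

Reproducibility: every FoV consumes its own random substream keyed by
(seed, patient index, sample index, tile index); cohorts regenerate
bit-identically from config + seed, and partial regeneration of one tile
does not disturb the others.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .types import DEFAULT_FOV_SHAPE, FovImage, SampleRecord

#: Mean photon count of a unit-intensity motif field (16-bit headroom).
PHOTON_SCALE = 22_000
_U16_MAX = 65_535

ARTIFACT_KINDS = ("hole", "border", "saturation")


@dataclass(frozen=True)
class MotifParams:
    """Continuous generative parameters of one tissue class.

    Densities are expected counts per full-size (152 x 302) tile and are
    rescaled with tile area; lengths are in pixels (1 um/pixel).
    """

    cord_amplitude: float = 0.45      # hepatocyte-cord band contrast
    cord_period: float = 24.0         # cord spacing, px
    gland_density: float = 0.0        # glands per full tile
    gland_radius: float = 22.0        # mean gland radius, px
    droplet_density: float = 25.0     # lipid droplets per full tile
    droplet_radius: float = 4.0       # droplet radius, px
    fiber_density: float = 4.0        # SHG fibers per full tile
    fiber_amplitude: float = 0.55

    @staticmethod
    def lerp(a: "MotifParams", b: "MotifParams", t: float) -> "MotifParams":
        vals = {
            k: (1.0 - t) * va + t * getattr(b, k)
            for k, va in asdict(a).items()
        }
        return MotifParams(**vals)


NORMAL_MOTIF = MotifParams()
TUMOR_MOTIF = MotifParams(
    cord_amplitude=0.05,
    cord_period=24.0,
    gland_density=22.0,
    gland_radius=22.0,
    droplet_density=0.0,
    droplet_radius=4.0,
    fiber_density=30.0,
    fiber_amplitude=0.8,
)


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: 'poisson' (photon shot noise, strength 1/scale)
    or 'gaussian' (additive, sd = scale * sqrt(counts))."""

    kind: str = "poisson"
    scale: float = 1.0

    def __post_init__(self):
        if self.kind not in ("poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.kind!r}")
        if self.scale <= 0:
            raise ValueError("noise scale must be positive")


@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for a seeded synthetic cohort.

    The default cohort used throughout the test suite is 8 matched
    patients x 2 samples x 30 tiles = 480 FoVs at full 152 x 302 geometry.
    ``sample_jitter_sd`` is the log-normal sd of per-sample multiplicative
    jitter on motif amplitudes/densities, emulating inter-patient
    variability; it applies identically to both classes.
    """

    fov_shape: tuple[int, int] = DEFAULT_FOV_SHAPE
    n_matched_patients: int = 8
    n_tumor_only: int = 0
    n_normal_only: int = 0
    tiles_per_sample: int = 30
    separability: float = 1.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    normal_motif: MotifParams = NORMAL_MOTIF
    tumor_motif: MotifParams = TUMOR_MOTIF
    sample_jitter_sd: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must lie in [0, 1]")
        if self.tiles_per_sample < 1:
            raise ValueError("tiles_per_sample must be >= 1")

    def grid_shape(self) -> tuple[int, int]:
        rows = max(1, int(np.floor(np.sqrt(self.tiles_per_sample))))
        cols = int(np.ceil(self.tiles_per_sample / rows))
        return rows, cols

    # -- JSON round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fov_shape"] = list(self.fov_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "fov_shape" in d:
            d["fov_shape"] = tuple(d["fov_shape"])
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseModel(**d["noise"])
        for key in ("normal_motif", "tumor_motif"):
            if key in d and isinstance(d[key], dict):
                d[key] = MotifParams(**d[key])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "SyntheticConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# rendering primitives


def _smooth_noise(shape, sigma, rng) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _add_disk(img, r0, c0, radius, amp, softness=1.0):
    """Add a soft-edged disk into img (bounding-box local computation)."""
    R, C = img.shape
    ext = int(np.ceil(radius + 3 * softness))
    r_lo, r_hi = max(0, int(r0) - ext), min(R, int(r0) + ext + 1)
    c_lo, c_hi = max(0, int(c0) - ext), min(C, int(c0) + ext + 1)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr = np.arange(r_lo, r_hi)[:, None] - r0
    cc = np.arange(c_lo, c_hi)[None, :] - c0
    d = np.hypot(rr, cc)
    img[r_lo:r_hi, c_lo:c_hi] += amp / (1.0 + np.exp((d - radius) / softness))


def _add_gland(img_c, img_t, r0, c0, radius, rim_amp):
    """Gland/nest motif: bright epithelial rim, suppressed lumen."""
    R, C = img_c.shape
    width = max(2.0, 0.28 * radius)
    ext = int(np.ceil(radius + 3 * width))
    r_lo, r_hi = max(0, int(r0) - ext), min(R, int(r0) + ext + 1)
    c_lo, c_hi = max(0, int(c0) - ext), min(C, int(c0) + ext + 1)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr = np.arange(r_lo, r_hi)[:, None] - r0
    cc = np.arange(c_lo, c_hi)[None, :] - c0
    d = np.hypot(rr, cc)
    rim = np.exp(-(((d - radius) / width) ** 2))
    lumen = np.exp(-((d / (0.6 * radius)) ** 2))
    img_c[r_lo:r_hi, c_lo:c_hi] += rim_amp * rim - 0.45 * rim_amp * lumen
    img_t[r_lo:r_hi, c_lo:c_hi] += 0.8 * rim_amp * rim - 0.3 * rim_amp * lumen


def _add_fibers(img, n_fibers, amplitude, rng):
    """Gently curved collagen fibers rendered as blurred polylines."""
    R, C = img.shape
    canvas = np.zeros_like(img)
    for _ in range(n_fibers):
        r = rng.uniform(0, R)
        c = rng.uniform(0, C)
        theta = rng.uniform(0, 2 * np.pi)
        curv = rng.normal(0, 0.01)
        length = rng.uniform(0.3, 1.2) * min(R, C)
        n_steps = int(length / 0.7)
        for _step in range(n_steps):
            ri, ci = int(round(r)), int(round(c))
            if 0 <= ri < R and 0 <= ci < C:
                canvas[ri, ci] += 1.0
            theta += curv
            r += 0.7 * np.sin(theta)
            c += 0.7 * np.cos(theta)
    if n_fibers:
        canvas = ndimage.gaussian_filter(canvas, 1.0)
        peak = canvas.max()
        if peak > 0:
            img += amplitude * canvas / peak


def _render_fields(params: MotifParams, shape, rng) -> tuple[np.ndarray, ...]:
    """Noise-free motif fields (cars, tpef, shg) in relative units."""
    R, C = shape
    area_scale = (R * C) / (DEFAULT_FOV_SHAPE[0] * DEFAULT_FOV_SHAPE[1])

    speckle_c = _smooth_noise(shape, 2.5, rng)
    speckle_t = _smooth_noise(shape, 2.5, rng)

    # hepatocyte cords: randomly oriented quasi-periodic bands
    theta = rng.uniform(0, np.pi)
    rr = np.arange(R)[:, None]
    cc = np.arange(C)[None, :]
    u = rr * np.sin(theta) + cc * np.cos(theta)
    phase_jitter = 4.0 * _smooth_noise(shape, 18, rng)
    cords = 0.5 * (1.0 + np.sin(2 * np.pi * (u + phase_jitter) / params.cord_period))

    cars = 0.30 + 0.06 * speckle_c + params.cord_amplitude * 0.30 * cords
    tpef = 0.26 + 0.06 * speckle_t + params.cord_amplitude * 0.24 * cords
    shg = np.full(shape, 0.03)

    n_glands = rng.poisson(params.gland_density * area_scale)
    for _ in range(n_glands):
        r0, c0 = rng.uniform(0, R), rng.uniform(0, C)
        radius = max(6.0, rng.normal(params.gland_radius, 0.2 * params.gland_radius))
        _add_gland(cars, tpef, r0, c0, radius, rim_amp=0.45)

    n_droplets = rng.poisson(params.droplet_density * area_scale)
    for _ in range(n_droplets):
        r0, c0 = rng.uniform(0, R), rng.uniform(0, C)
        radius = max(1.5, rng.normal(params.droplet_radius, 1.0))
        _add_disk(cars, r0, c0, radius, amp=0.55, softness=0.8)

    n_fibers = rng.poisson(params.fiber_density * area_scale)
    _add_fibers(shg, n_fibers, params.fiber_amplitude, rng)

    # per-channel floor keeps tissue above the QC foreground threshold
    cars = np.clip(cars, 0.18, 1.30)
    tpef = np.clip(tpef, 0.18, 1.30)
    shg = np.clip(shg, 0.0, 1.30)
    return cars, tpef, shg


def _apply_noise(field: np.ndarray, noise: NoiseModel, rng) -> np.ndarray:
    lam = field * PHOTON_SCALE
    if noise.kind == "poisson":
        counts = rng.poisson(lam * noise.scale) / noise.scale
    else:
        counts = lam + rng.normal(0.0, noise.scale * np.sqrt(np.maximum(lam, 1.0)))
    return np.clip(np.rint(counts), 0, _U16_MAX).astype(np.uint16)


def _effective_params(tissue_class: str, config: SyntheticConfig) -> MotifParams:
    if tissue_class == "normal":
        return config.normal_motif
    if tissue_class == "tumor":
        return MotifParams.lerp(
            config.normal_motif, config.tumor_motif, config.separability
        )
    raise ValueError(f"unknown tissue class {tissue_class!r}")


_JITTERED_FIELDS = (
    "cord_amplitude",
    "gland_density",
    "droplet_density",
    "fiber_density",
    "fiber_amplitude",
)


def _jitter_params(params: MotifParams, rng, sd: float) -> MotifParams:
    """Per-sample log-normal jitter on amplitudes and densities."""
    if sd <= 0:
        return params
    updates = {
        f: getattr(params, f) * float(np.exp(rng.normal(0.0, sd)))
        for f in _JITTERED_FIELDS
    }
    return replace(params, **updates)


# ---------------------------------------------------------------------------
# public generators


def generate_fov(
    tissue_class: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    tile_row: int = 0,
    tile_col: int = 0,
    fov_id: str = "fov",
    params: MotifParams | None = None,
) -> FovImage:
    """Draw one synthetic FoV of the given class.

    ``params`` overrides the class motif parameters (used internally to
    inject per-sample jitter); by default they follow the config and its
    separability setting.
    """
    if params is None:
        params = _effective_params(tissue_class, config)
    elif tissue_class not in ("normal", "tumor"):
        raise ValueError(f"unknown tissue class {tissue_class!r}")
    fields = _render_fields(params, config.fov_shape, rng)
    cars, tpef, shg = (_apply_noise(f, config.noise, rng) for f in fields)
    return FovImage(
        cars=cars, tpef=tpef, shg=shg,
        tile_row=tile_row, tile_col=tile_col, fov_id=fov_id,
    ).validate()


def _tile_rng(config: SyntheticConfig, p_idx: int, s_idx: int, t_idx: int):
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), p_idx, s_idx, t_idx])
    )


def _sample_rng(config: SyntheticConfig, p_idx: int, s_idx: int):
    # 3-element entropy tuple: disjoint from the 4-element per-tile streams
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), p_idx, s_idx])
    )


def _make_sample(
    config: SyntheticConfig, p_idx: int, s_idx: int,
    patient_id: str, tissue_label: str,
) -> SampleRecord:
    rows, cols = config.grid_shape()
    suffix = "N" if tissue_label == "normal" else "T"
    sample_id = f"{patient_id}-{suffix}"
    base = _effective_params(tissue_label, config)
    params = _jitter_params(base, _sample_rng(config, p_idx, s_idx), config.sample_jitter_sd)
    fovs = []
    for t in range(config.tiles_per_sample):
        r, c = divmod(t, cols)
        fovs.append(
            generate_fov(
                tissue_label,
                config,
                _tile_rng(config, p_idx, s_idx, t),
                tile_row=r,
                tile_col=c,
                fov_id=f"{sample_id}-r{r:02d}c{c:02d}",
                params=params,
            )
        )
    return SampleRecord(
        patient_id=patient_id,
        sample_id=sample_id,
        tissue_label=tissue_label,
        fovs=fovs,
        grid_shape=(rows, cols),
    ).validate()


def generate_cohort(config: SyntheticConfig) -> list[SampleRecord]:
    """Generate the full cohort: matched patients (one normal + one tumor
    sample each) followed by optional single-tissue patients.

    Deterministic in config + seed; patient/sample identifiers are unique
    and independent of the seed.
    """
    samples: list[SampleRecord] = []
    p_idx = 0
    for _ in range(config.n_matched_patients):
        pid = f"P{p_idx + 1:02d}"
        samples.append(_make_sample(config, p_idx, 0, pid, "normal"))
        samples.append(_make_sample(config, p_idx, 1, pid, "tumor"))
        p_idx += 1
    for _ in range(config.n_tumor_only):
        pid = f"P{p_idx + 1:02d}"
        samples.append(_make_sample(config, p_idx, 1, pid, "tumor"))
        p_idx += 1
    for _ in range(config.n_normal_only):
        pid = f"P{p_idx + 1:02d}"
        samples.append(_make_sample(config, p_idx, 0, pid, "normal"))
        p_idx += 1
    return samples


def generate_artifact_fov(
    kind: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    tile_row: int = 0,
    tile_col: int = 0,
    fov_id: str = "artifact",
) -> FovImage:
    """A normal-class tile carrying one constructed acquisition artifact.

    * ``hole``: a contiguous near-zero region (~8% of the area) — fails
      the largest-background-component rule while coverage stays high;
    * ``border``: one near-zero strip covering ~25% of the tile — fails
      the coverage rule;
    * ``saturation``: a CARS region (~3%) pinned at the 16-bit maximum.
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}")
    fov = generate_fov("normal", config, rng, tile_row, tile_col, fov_id)
    R, C = config.fov_shape
    if kind == "hole":
        radius = np.sqrt(0.08 * R * C / np.pi)
        r0 = rng.uniform(0.35 * R, 0.65 * R)
        c0 = rng.uniform(0.35 * C, 0.65 * C)
        rr = np.arange(R)[:, None] - r0
        cc = np.arange(C)[None, :] - c0
        mask = np.hypot(rr, cc) <= radius
        for arr in (fov.cars, fov.tpef, fov.shg):
            arr[mask] = rng.poisson(30, mask.sum())
    elif kind == "border":
        width = max(1, int(0.25 * C))
        for arr in (fov.cars, fov.tpef, fov.shg):
            arr[:, :width] = rng.poisson(30, (R, width))
    else:  # saturation
        radius = np.sqrt(0.03 * R * C / np.pi)
        r0 = rng.uniform(0.3 * R, 0.7 * R)
        c0 = rng.uniform(0.3 * C, 0.7 * C)
        rr = np.arange(R)[:, None] - r0
        cc = np.arange(C)[None, :] - c0
        fov.cars[np.hypot(rr, cc) <= radius] = _U16_MAX
    return fov
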