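"""Synthetic pushbroom NIR scenes with known ground truth.

Real steak hypercubes for the tenderness problem are not publicly deposited,
so the pipeline is exercised end-to-end on synthetic scenes that reproduce the
statistical structure the analysis relies on:

* two spectral classes (tender, WBSF < 53 N vs tough, WBSF >= 53 N) whose lean
  reflectance differs by a small smooth offset concentrated in a stated
  wavelength window (default 1000-1100 nm, where real tenderness groups
  separate most), on a base curve with absorption features near 1113, 1187 and
  1289 nm;
* an elliptical lean region on a dark background, with brighter fat streaks
  whose reflectance at 1210 nm exceeds the published high-mask threshold;
* per-pixel multiplicative scatter and additive baseline drift, i.i.d. white
  noise, ~1% dead pixels stuck at the black level, and rare single-band
  spikes injected at 8 per-pixel standard deviations;
* white/black reference scans so that reflectance calibration inverts the
  sensor model exactly where no artifact was injected.

The amplitude convention is chosen so the published segmentation thresholds
(0.068 / 0.19 at 1210 nm) are directly meaningful on synthetic scenes: lean
reflectance sits near 0.11 at 1210 nm, fat near 0.23, background near 0.03.

Pixels are conditionally independent given their class: there is no per-animal
spectral random effect beyond the class offset.  This makes synthetic
classification an easier problem than real steaks, which is exactly what the
recovery tests require — known signal in, signal out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .hypercube import Hypercube, ReferencePair, write_cube

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "CohortSample",
    "Cohort",
    "DegenerateSceneError",
    "make_class_spectrum",
    "render_sample",
    "make_cohort",
    "headline_scene",
    "write_sample",
    "write_cohort",
]

WBSF_BOUNDARY_N = 53.0
#: per-group WBSF mean and SD (newtons) of the emulated cohort
WBSF_GROUP_STATS = {1: (47.27, 4.92), 2: (64.97, 11.90)}
#: WBSF range (N) the truncated normals are confined to
WBSF_RANGE_N = (34.68, 106.10)

# sensor-count model: raw = reflectance * (white - black) + black
_BLACK_LEVEL = 100.0
_WHITE_LEVEL = 3000.0
_COUNT_SCALE = _WHITE_LEVEL - _BLACK_LEVEL


class DegenerateSceneError(ValueError):
    """Scene parameters leave no usable lean region."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic acquisition.

    Rates and fractions are proportions in [0, 1]; reflectance quantities are
    dimensionless.  ``class_effect`` is the peak reflectance offset of group 1
    over group 2 inside ``class_bands``.  The same spec + seed always renders
    bit-identical scenes.
    """

    n_samples: int = 58
    image_shape: tuple[int, int] = (64, 64)
    n_bands: int = 256
    wavelength_range: tuple[float, float] = (900.0, 1700.0)
    class_effect: float = 0.02
    class_bands: tuple[tuple[float, float], ...] = ((1000.0, 1100.0),)
    group1_fraction: float = 30.0 / 58.0
    fat_fraction: float = 0.10
    dead_pixel_rate: float = 0.01
    spike_rate: float = 0.002
    spike_magnitude_sd: float = 8.0
    noise_sd: float = 0.005
    scatter_sd: float = 0.05
    baseline_sd: float = 0.01
    ref_rows: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fat_fraction", "dead_pixel_rate", "spike_rate",
                     "group1_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        if not self.wavelength_range[0] < self.wavelength_range[1]:
            raise ValueError("wavelength_range must be increasing")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.n_bands)


def headline_scene(**overrides) -> SceneSpec:
    """A noisier, weaker-contrast preset.

    Emulates the regime where pixel classification lands near the published
    ~70% correct-classification range rather than the clean default contrast.
    """
    params = dict(class_effect=0.006, noise_sd=0.012, scatter_sd=0.08,
                  baseline_sd=0.015)
    params.update(overrides)
    return SceneSpec(**params)


@dataclass
class GroundTruth:
    """Per-sample truth emitted alongside each rendered scene.

    ``labels`` codes each pixel 0=background, 1=lean, 2=fat, 3=dead; spike
    positions are (row, col, band) triples.  The clean reflectance cube is the
    scene before artifact injection and sensor-count encoding.
    """

    sample_id: str
    group: int
    wbsf_n: float
    labels: np.ndarray
    dead_mask: np.ndarray
    spikes: np.ndarray
    clean: np.ndarray = field(repr=False)

    LABEL_BACKGROUND = 0
    LABEL_LEAN = 1
    LABEL_FAT = 2
    LABEL_DEAD = 3


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

# Gaussian absorption features: (center nm, depth, width nm)
_ABSORPTION_FEATURES = ((1113.0, 0.030, 25.0), (1187.0, 0.040, 22.0),
                        (1289.0, 0.050, 30.0))


def _base_curve(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth lean reflectance: gentle slope minus three absorption dips."""
    lo, hi = wavelengths[0], wavelengths[-1]
    curve = 0.10 + 0.08 * (wavelengths - lo) / max(hi - lo, 1.0)
    for center, depth, width in _ABSORPTION_FEATURES:
        curve = curve - depth * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
    return curve


def _class_offset(wavelengths: np.ndarray, spec: SceneSpec) -> np.ndarray:
    """Smooth bump of height ``class_effect`` inside each class band, 0 outside."""
    offset = np.zeros_like(wavelengths)
    for lo, hi in spec.class_bands:
        inside = (wavelengths >= lo) & (wavelengths <= hi)
        u = (wavelengths[inside] - lo) / max(hi - lo, 1e-9)
        offset[inside] = np.maximum(offset[inside], np.sin(np.pi * u) ** 2)
    if offset.max() > 0:  # peak offset equals class_effect on the band grid
        offset *= spec.class_effect / offset.max()
    return offset


def make_class_spectrum(group: int, spec: SceneSpec) -> np.ndarray:
    """Mean lean reflectance spectrum of a tenderness group.

    Group 1 (tender) is offset above group 2 by up to ``class_effect`` inside
    ``class_bands``; outside those windows the groups coincide.
    """
    if group not in (1, 2):
        raise ValueError(f"group must be 1 or 2, got {group}")
    wavelengths = spec.wavelengths
    curve = _base_curve(wavelengths)
    if group == 1:
        curve = curve + _class_offset(wavelengths, spec)
    return np.clip(curve, 1e-6, 1.0 - 1e-6)


def _fat_spectrum(spec: SceneSpec) -> np.ndarray:
    """Fat reflectance: brighter than lean so the 0.19 high mask catches it."""
    return np.clip(_base_curve(spec.wavelengths) + 0.12, 1e-6, 1.0 - 1e-6)


def _background_spectrum(spec: SceneSpec) -> np.ndarray:
    """Dark conveyor background, safely below the 0.068 low mask at 1210 nm."""
    return np.full(spec.n_bands, 0.03)


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

def _scene_masks(spec: SceneSpec, rng: np.random.Generator):
    """Elliptical lean region with smooth-noise fat streaks inside it."""
    rows, cols = spec.image_shape
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    ay = 0.38 * rows * rng.uniform(0.9, 1.05)
    ax = 0.38 * cols * rng.uniform(0.9, 1.05)
    foreground = ((r - cy) / ay) ** 2 + ((c - cx) / ax) ** 2 <= 1.0
    if not foreground.any():
        raise DegenerateSceneError("no foreground pixels in scene")
    fat = np.zeros_like(foreground)
    if spec.fat_fraction > 0:
        texture = ndimage.gaussian_filter(rng.standard_normal(spec.image_shape), 2.0)
        cut = np.quantile(texture[foreground], 1.0 - spec.fat_fraction)
        fat = foreground & (texture >= cut)
    lean = foreground & ~fat
    if not lean.any():
        raise DegenerateSceneError("fat_fraction leaves no lean pixels")
    return lean, fat


def _isolated_positions(candidates: np.ndarray, n: int, rng: np.random.Generator,
                        shape: tuple[int, int]) -> np.ndarray:
    """Greedily pick ``n`` mutually non-adjacent positions (8-neighbourhood)."""
    taken = np.zeros(shape, dtype=bool)
    blocked = np.zeros(shape, dtype=bool)
    order = rng.permutation(len(candidates))
    picked = []
    for idx in order:
        rr, cc = candidates[idx]
        if blocked[rr, cc]:
            continue
        picked.append((rr, cc))
        taken[rr, cc] = True
        blocked[max(rr - 1, 0):rr + 2, max(cc - 1, 0):cc + 2] = True
        if len(picked) == n:
            break
    return np.asarray(picked, dtype=int).reshape(-1, 2)


def render_sample(group: int, spec: SceneSpec, sample_id: str = "sample",
                  wbsf_n: float | None = None,
                  rng: np.random.Generator | None = None):
    """Render one acquisition: raw cube, white/black reference scans, truth.

    The clean reflectance scene (class spectra + scatter/baseline/noise) is
    inverted through the sensor model ``raw = R * (white - black) + black``
    using the very reference frames that are emitted, so calibrating the raw
    cube recovers the clean scene exactly outside injected artifacts.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_shape
    wavelengths = spec.wavelengths
    lean, fat = _scene_masks(spec, rng)
    labels = np.zeros(spec.image_shape, dtype=np.uint8)
    labels[lean] = GroundTruth.LABEL_LEAN
    labels[fat] = GroundTruth.LABEL_FAT

    # clean reflectance scene
    clean = np.empty((rows, cols, spec.n_bands))
    clean[:, :] = _background_spectrum(spec)
    clean[lean] = make_class_spectrum(group, spec)
    clean[fat] = _fat_spectrum(spec)
    # per-pixel multiplicative scatter and additive baseline drift; these model
    # sample surface geometry, so they apply to foreground pixels only
    foreground = lean | fat
    if spec.scatter_sd > 0:
        gain = 1.0 + spec.scatter_sd * rng.standard_normal((rows, cols))
        clean[foreground] *= gain[foreground, None]
    if spec.baseline_sd > 0:
        drift = spec.baseline_sd * rng.standard_normal((rows, cols))
        clean[foreground] += drift[foreground, None]
    if spec.noise_sd > 0:
        clean += spec.noise_sd * rng.standard_normal(clean.shape)

    # spikes are reflectance-domain outliers at 8 per-pixel spectral SDs
    n_spike = rng.binomial(rows * cols, spec.spike_rate)
    spikes = np.zeros((0, 3), dtype=int)
    if n_spike > 0:
        all_pos = np.argwhere(np.ones(spec.image_shape, dtype=bool))
        pos = _isolated_positions(all_pos, n_spike, rng, spec.image_shape)
        bands = rng.integers(0, spec.n_bands, size=len(pos))
        signs = rng.choice([-1.0, 1.0], size=len(pos))
        out = []
        for (rr, cc), b, sg in zip(pos, bands, signs):
            m0 = clean[rr, cc].mean()
            s0 = clean[rr, cc].std(ddof=1)
            if s0 <= 0:
                continue
            # placed relative to the pixel mean so the excursion is exactly
            # spike_magnitude_sd pre-injection SDs
            clean[rr, cc, b] = m0 + sg * spec.spike_magnitude_sd * s0
            out.append((rr, cc, b))
        spikes = np.asarray(out, dtype=int).reshape(-1, 3)

    # reference scans with smooth column/band illumination structure
    col_gain = 1.0 + 0.05 * np.sin(np.linspace(0, np.pi, cols))[:, None]
    band_gain = 1.0 + 0.10 * np.sin(np.linspace(0, 2 * np.pi, spec.n_bands))[None, :]
    white_field = _BLACK_LEVEL + _COUNT_SCALE * col_gain * band_gain
    black_field = np.full((cols, spec.n_bands), _BLACK_LEVEL)
    ref_noise = spec.noise_sd * _COUNT_SCALE * 0.1
    white_scan = white_field[None] + ref_noise * rng.standard_normal(
        (spec.ref_rows, cols, spec.n_bands))
    black_scan = black_field[None] + ref_noise * rng.standard_normal(
        (spec.ref_rows, cols, spec.n_bands))
    refs = ReferencePair(white=white_scan, black=black_scan)
    white_avg, black_avg = refs.averaged()

    raw = clean * (white_avg - black_avg)[None] + black_avg[None]

    # dead pixels: isolated positions stuck at the black level across bands
    n_dead = rng.binomial(rows * cols, spec.dead_pixel_rate)
    dead_mask = np.zeros(spec.image_shape, dtype=bool)
    if n_dead > 0:
        candidates = np.ones(spec.image_shape, dtype=bool)
        candidates[spikes[:, 0], spikes[:, 1]] = False  # keep spikes observable
        all_pos = np.argwhere(candidates)
        pos = _isolated_positions(all_pos, n_dead, rng, spec.image_shape)
        dead_mask[pos[:, 0], pos[:, 1]] = True
        raw[dead_mask] = black_avg[pos[:, 1]] + ref_noise * rng.standard_normal(
            (len(pos), spec.n_bands))
        labels[dead_mask] = GroundTruth.LABEL_DEAD

    if wbsf_n is None:
        wbsf_n = WBSF_GROUP_STATS[group][0]
    truth = GroundTruth(sample_id=sample_id, group=group, wbsf_n=float(wbsf_n),
                        labels=labels, dead_mask=dead_mask, spikes=spikes,
                        clean=clean)
    cube = Hypercube(values=raw, wavelengths=wavelengths, sample_id=sample_id)
    return cube, refs, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSample:
    sample_id: str
    group: int
    wbsf_n: float


@dataclass
class Cohort:
    """A simulated study cohort: sample metadata plus the scene spec.

    Scenes are rendered lazily per sample (each from its own child seed) so a
    58-sample cohort never has to hold 58 cubes in memory at once.
    """

    spec: SceneSpec
    samples: list[CohortSample]

    def render(self, sample: CohortSample):
        idx = next(i for i, s in enumerate(self.samples) if s.sample_id == sample.sample_id)
        rng = np.random.default_rng([self.spec.seed, 1 + idx])
        return render_sample(sample.group, self.spec, sample_id=sample.sample_id,
                             wbsf_n=sample.wbsf_n, rng=rng)

    @property
    def groups(self) -> dict[str, int]:
        return {s.sample_id: s.group for s in self.samples}


def _truncated_wbsf(group: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """WBSF draws from per-group truncated normals respecting the 53 N boundary."""
    mean, sd = WBSF_GROUP_STATS[group]
    lo, hi = (WBSF_RANGE_N[0], WBSF_BOUNDARY_N) if group == 1 else \
        (WBSF_BOUNDARY_N, WBSF_RANGE_N[1])
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    return dist.ppf(rng.uniform(size=n))


def make_cohort(spec: SceneSpec) -> Cohort:
    """Build a cohort with near-parity groups and group-consistent WBSF values.

    Group sizes follow ``group1_fraction`` (default 30/58); WBSF is drawn from
    truncated normals per group so that every value is consistent with its
    group's side of the 53 N boundary.
    """
    if spec.n_samples < 2:
        raise ValueError("a cohort needs at least 2 samples")
    n1 = int(round(spec.group1_fraction * spec.n_samples))
    n1 = min(max(n1, 1), spec.n_samples - 1)
    n2 = spec.n_samples - n1
    rng = np.random.default_rng([spec.seed, 0])
    wbsf1 = _truncated_wbsf(1, n1, rng)
    wbsf2 = _truncated_wbsf(2, n2, rng)
    samples = []
    width = len(str(spec.n_samples))
    for i in range(spec.n_samples):
        group = 1 if i < n1 else 2
        w = wbsf1[i] if group == 1 else wbsf2[i - n1]
        samples.append(CohortSample(sample_id=f"S{i + 1:0{width}d}", group=group,
                                    wbsf_n=float(w)))
    return Cohort(spec=spec, samples=samples)


# ---------------------------------------------------------------------------
# On-disk cohorts (ENVI rasters + delimited truth tables)
# ---------------------------------------------------------------------------

def write_sample(out_dir: str | Path, cube: Hypercube, refs: ReferencePair,
                 truth: GroundTruth) -> None:
    """Write one acquisition: cube, reference scans and per-pixel label raster."""
    out_dir = Path(out_dir)
    sid = truth.sample_id
    write_cube(cube, out_dir / f"{sid}_raw")
    wl = cube.wavelengths
    write_cube(Hypercube(refs.white, wl, sample_id=f"{sid}_white"),
               out_dir / f"{sid}_white")
    write_cube(Hypercube(refs.black, wl, sample_id=f"{sid}_black"),
               out_dir / f"{sid}_black")
    write_cube(Hypercube(truth.labels[:, :, None].astype(float), np.array([0.0]),
                         sample_id=f"{sid}_labels"),
               out_dir / f"{sid}_labels", dtype=np.uint8)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Render and write every sample plus the reference WBSF table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["sample_id\twbsf_n\tgroup"]
    for sample in cohort.samples:
        cube, refs, truth = cohort.render(sample)
        write_sample(out_dir, cube, refs, truth)
        lines.append(f"{sample.sample_id}\t{sample.wbsf_n:.2f}\t{sample.group}")
    table = out_dir / "reference_table.tsv"
    table.write_text("\n".join(lines) + "\n")
    return table
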