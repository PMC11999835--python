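"""Synthetic meat reflectance spectra and master/slave instrument simulation.

The visible reflectance of muscle tissue in 400-800 nm is dominated by haem
pigment absorption: a strong Soret band near 420 nm (deoxymyoglobin) and the
oxymyoglobin doublet at 540/575 nm.  Beef additionally shows a weak metmyoglobin
feature near 630 nm, and chicken breast sits at a visibly higher overall
reflectance than beef or duck.  The generator models each species as a linear
baseline minus Gaussian absorption dips, with multiplicative sample-to-sample
variability in overall level and in each band depth.

Two simulated instruments observe the same latent spectra:

* a benchtop "master" spectrometer (300-800 nm, 1.3 nm resolution), and
* a portable push-broom "slave" imager (400-800 nm, 5 nm resolution) whose
  response differs from the master by a smooth wavelength-dependent gain
  (mean ~1.15), an additive offset, a small wavelength-calibration shift and
  a broader slit function.

Observation = Gaussian slit convolution -> sampling on the instrument's
(shifted) grid -> gain/offset -> additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .datasets import HyperCube, SpectrumSet

__all__ = [
    "MeatClassModel",
    "InstrumentModel",
    "default_class_models",
    "default_master",
    "default_slave",
    "dense_grid",
    "generate_latent_spectra",
    "apply_instrument",
    "generate_paired_sets",
    "generate_spliced_cube",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class MeatClassModel:
    """Reflectance model of one meat species.

    ``bands`` are ``(center_nm, depth, width_nm)`` Gaussian absorption dips
    subtracted from the linear baseline ``baseline_level + baseline_slope *
    (lambda - 600)``.  ``within_class_sd`` is the multiplicative fractional
    s.d. applied to the overall level and to each band depth independently.
    """

    class_name: str
    baseline_level: float
    baseline_slope: float = 0.0
    bands: tuple[tuple[float, float, float], ...] = ()
    within_class_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_level <= 1.0:
            raise ValueError("baseline_level must be in (0, 1]")
        for center, depth, width in self.bands:
            if not 400.0 <= center <= 800.0:
                raise ValueError(f"band center {center} nm outside [400, 800]")
            if depth < 0:
                raise ValueError("band depths must be >= 0")
            if width <= 0:
                raise ValueError("band widths must be > 0")


@dataclass(frozen=True)
class InstrumentModel:
    """Simulated spectrometer/imager response.

    ``gain`` may be a scalar or a per-band vector on ``grid_nm``; the band
    reported at wavelength w actually samples the scene at
    ``w + wavelength_shift_nm`` (a calibration error).
    """

    name: str
    grid_nm: np.ndarray
    fwhm_nm: float
    gain: float | np.ndarray = 1.0
    offset: float | np.ndarray = 0.0
    wavelength_shift_nm: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid_nm, dtype=float)
        if grid.ndim != 1 or not np.all(np.diff(grid) > 0):
            raise ValueError("grid_nm must be strictly increasing")
        if grid[0] < 300.0 - 1e-9 or grid[-1] > 800.0 + 1e-9:
            raise ValueError("instrument grid must lie within [300, 800] nm")
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "grid_nm", grid)
        gain = np.asarray(self.gain, dtype=float)
        if gain.ndim == 1 and gain.size != grid.size:
            raise ValueError("per-band gain length must match grid")
        object.__setattr__(self, "gain", gain if gain.ndim else float(gain))


def dense_grid(start: float = 295.0, stop: float = 820.0, step: float = 0.5) -> np.ndarray:
    """Dense latent wavelength grid supporting both instruments' slits."""
    return np.arange(start, stop + step / 2, step)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_class_models() -> dict[str, MeatClassModel]:
    """Chicken / beef / duck defaults.

    Chicken carries the highest baseline reflectance; beef and duck are
    similar to each other and darker, and beef adds the 630 nm metmyoglobin
    dip.  Band centers: 420, 540, 575 (+630 for beef) nm.
    """
    return {
        "beef": MeatClassModel(
            "beef", baseline_level=0.46, baseline_slope=5.0e-4,
            bands=((420.0, 0.32, 9.0), (540.0, 0.20, 10.0),
                   (575.0, 0.18, 9.0), (630.0, 0.06, 8.0)),
        ),
        "chicken": MeatClassModel(
            "chicken", baseline_level=0.63, baseline_slope=4.0e-4,
            bands=((420.0, 0.28, 9.0), (540.0, 0.15, 10.0), (575.0, 0.13, 9.0)),
        ),
        "duck": MeatClassModel(
            "duck", baseline_level=0.43, baseline_slope=4.5e-4,
            bands=((420.0, 0.30, 9.0), (540.0, 0.22, 10.0), (575.0, 0.16, 9.0)),
        ),
    }


def default_master(noise_sd: float = 0.003, seed: int = 101) -> InstrumentModel:
    """Benchtop reference spectrometer: 300-800 nm at 1.3 nm."""
    return InstrumentModel(
        name="master",
        grid_nm=np.arange(300.0, 800.0 + 1e-9, 1.3),
        fwhm_nm=1.3,
        noise_sd=noise_sd,
        seed=seed,
    )


def _slave_response_curve(grid: np.ndarray) -> np.ndarray:
    """Smooth wavelength-dependent slave gain, mean ~1.15 over 400-800 nm.

    A linear detector-response tilt plus localized deviations near 410 and
    620 nm, where master/slave disagreement is strongest.
    """
    return (
        1.15
        + 0.30 * (grid - 600.0) / 200.0
        - 0.25 * np.exp(-(((grid - 620.0) / 25.0) ** 2))
        + 0.22 * np.exp(-(((grid - 410.0) / 15.0) ** 2))
    )


def default_slave(noise_sd: float = 0.003, seed: int = 202) -> InstrumentModel:
    """Portable push-broom imager: 400-800 nm at 5 nm, shifted response.

    Defaults encode the study's instrument mismatch: gain ~1.15 (smooth
    spectral response curve), offset 0.03, +3 nm wavelength-calibration
    error and a 5 nm slit versus the master's 1.3 nm.
    """
    grid = np.arange(400.0, 800.0 + 1e-9, 5.0)
    return InstrumentModel(
        name="slave",
        grid_nm=grid,
        fwhm_nm=5.0,
        gain=_slave_response_curve(grid),
        offset=0.03,
        wavelength_shift_nm=3.0,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_latent_spectra(
    class_model: MeatClassModel,
    n: int,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> SpectrumSet:
    """Draw ``n`` latent (instrument-free) spectra for one species.

    Each spectrum is ``level_i * (baseline - sum_b depth_bi * G_b)`` clipped
    to [0, 1], where ``level_i`` and per-band ``depth_bi`` carry independent
    multiplicative N(1, within_class_sd^2) variability.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    wl = dense_grid() if grid is None else np.asarray(grid, dtype=float)
    for center, _, _ in class_model.bands:
        if not wl[0] <= center <= wl[-1]:
            raise ValueError(
                f"band center {center} nm outside latent grid "
                f"[{wl[0]}, {wl[-1]}] nm"
            )
    rng = np.random.default_rng(seed)
    baseline = class_model.baseline_level + class_model.baseline_slope * (wl - 600.0)
    shapes = np.array(
        [np.exp(-0.5 * ((wl - c) / w) ** 2) for c, _, w in class_model.bands]
    )  # (n_bands, n_wl)
    depths = np.array([d for _, d, _ in class_model.bands])
    sd = class_model.within_class_sd
    level_f = 1.0 + sd * rng.standard_normal(n)
    depth_f = 1.0 + sd * rng.standard_normal((n, depths.size))
    dips = (depth_f * depths) @ shapes if depths.size else np.zeros((n, wl.size))
    spectra = np.clip(level_f[:, None] * (baseline[None, :] - dips), 0.0, 1.0)
    labels = np.full(n, class_model.class_name)
    ids = np.array([f"{class_model.class_name}_{i:03d}" for i in range(n)])
    return SpectrumSet(wl, spectra, labels, ids)


def apply_instrument(
    latent: SpectrumSet,
    instrument: InstrumentModel,
    rng: np.random.Generator | None = None,
) -> SpectrumSet:
    """Observe latent spectra through an instrument model.

    Convolves with the Gaussian slit (sigma = FWHM / 2.3548), samples at
    ``grid_nm + wavelength_shift_nm``, applies gain and offset, and adds
    Gaussian noise.  Output wavelengths are the instrument's nominal grid.
    """
    wl = latent.wavelengths_nm
    spacing = float(np.median(np.diff(wl)))
    sample_at = instrument.grid_nm + instrument.wavelength_shift_nm
    if sample_at[0] < wl[0] - 1e-9 or sample_at[-1] > wl[-1] + 1e-9:
        raise ValueError(
            f"instrument samples [{sample_at[0]:.1f}, {sample_at[-1]:.1f}] nm "
            f"but the latent grid only covers [{wl[0]:.1f}, {wl[-1]:.1f}] nm"
        )
    sigma_px = instrument.fwhm_nm * _FWHM_TO_SIGMA / spacing
    if sigma_px > 1e-3:
        smoothed = gaussian_filter1d(latent.spectra, sigma_px, axis=1, mode="nearest")
    else:
        smoothed = latent.spectra
    out = np.vstack([np.interp(sample_at, wl, row) for row in smoothed])
    out = out * instrument.gain + instrument.offset
    if instrument.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(instrument.seed)
        out = out + instrument.noise_sd * rng.standard_normal(out.shape)
    return SpectrumSet(instrument.grid_nm.copy(), out, latent.labels, latent.sample_ids)


def generate_paired_sets(
    class_models: dict[str, MeatClassModel] | None = None,
    n_per_class: int = 48,
    master: InstrumentModel | None = None,
    slave: InstrumentModel | None = None,
    seed: int = 0,
) -> tuple[SpectrumSet, SpectrumSet]:
    """Same latent samples observed by both instruments, row-aligned.

    Defaults emulate the study: 3 species x 48 samples = 144 paired spectra.
    """
    class_models = class_models or default_class_models()
    master = master or default_master()
    slave = slave or default_slave()
    ss = np.random.SeedSequence(seed)
    latent_seeds = ss.spawn(len(class_models))
    noise_master, noise_slave = (np.random.default_rng(s) for s in ss.spawn(2))
    parts = []
    for sub, name in zip(latent_seeds, sorted(class_models)):
        parts.append(
            generate_latent_spectra(
                class_models[name], n_per_class,
                seed=sub.generate_state(1)[0] % (2**31),
            )
        )
    latent = SpectrumSet(
        parts[0].wavelengths_nm,
        np.vstack([p.spectra for p in parts]),
        np.concatenate([p.labels for p in parts]),
        np.concatenate([p.sample_ids for p in parts]),
    )
    m_view = apply_instrument(latent, master, rng=noise_master)
    s_view = apply_instrument(latent, slave, rng=noise_slave)
    return m_view, s_view


def _stripe_truth_map(shape: tuple[int, int], counts: np.ndarray) -> np.ndarray:
    """Vertical-stripe layout: pixels assigned class-by-class in column-major
    order so pixel counts are honoured exactly (ragged boundary column)."""
    rows, cols = shape
    flat = np.repeat(np.arange(counts.size), counts)
    return flat.reshape(cols, rows).T  # column-major fill


def _checker_truth_map(shape: tuple[int, int], fractions: np.ndarray,
                       block: int = 8) -> np.ndarray:
    """Checkerboard stress layout: blocks assigned by largest remainder."""
    rows, cols = shape
    br, bc = -(-rows // block), -(-cols // block)
    n_blocks = br * bc
    counts = _largest_remainder(fractions, n_blocks)
    # interleave the class blocks proportionally for a checkerboard feel
    keys = np.concatenate([(np.arange(c) + 0.5) / c for c in counts if c > 0])
    classes = np.repeat(np.arange(counts.size), counts)
    blocks = classes[np.argsort(keys, kind="stable")]
    grid = blocks.reshape(br, bc)
    return np.kron(grid, np.ones((block, block), dtype=int))[:rows, :cols]


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` items to ``fractions`` by the largest-remainder rule."""
    quotas = fractions * total
    counts = np.floor(quotas).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(quotas - counts))
    counts[order[:short]] += 1
    return counts


def generate_spliced_cube(
    class_models: dict[str, MeatClassModel] | None = None,
    proportions=(1.0, 1.0, 1.0),
    shape: tuple[int, int] = (60, 60),
    slave: InstrumentModel | None = None,
    seed: int = 0,
    layout: str = "stripes",
) -> HyperCube:
    """Build a spliced-meat cube with known per-class regions.

    ``proportions`` is a ratio triple over the alphabetical class order
    (e.g. beef:chicken:duck = 2:1:1); it is normalised by its sum and
    realised to the nearest pixel by the largest-remainder rule.
    """
    class_models = class_models or default_class_models()
    slave = slave or default_slave()
    rows, cols = shape
    if rows < 16 or cols < 16:
        raise ValueError("cube shape must be at least 16x16")
    names = sorted(class_models)
    fractions = np.asarray(proportions, dtype=float)
    if fractions.size != len(names):
        raise ValueError("one proportion per class required")
    fractions = fractions / fractions.sum()
    counts = _largest_remainder(fractions, rows * cols)
    if np.any(counts < 1):
        bad = names[int(np.argmin(counts))]
        raise ValueError(f"region for class {bad!r} would contain no pixels")
    if layout == "stripes":
        truth = _stripe_truth_map(shape, counts)
    elif layout == "checkerboard":
        truth = _checker_truth_map(shape, fractions)
        counts = np.bincount(truth.ravel(), minlength=len(names))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    ss = np.random.SeedSequence(seed)
    latent_seeds = ss.spawn(len(names))
    noise_rng = np.random.default_rng(ss.spawn(1)[0])
    bands = slave.grid_nm.size
    cube = np.empty((rows * cols, bands))
    flat_truth = truth.ravel()
    for k, (name, sub) in enumerate(zip(names, latent_seeds)):
        idx = np.flatnonzero(flat_truth == k)
        latent = generate_latent_spectra(
            class_models[name], idx.size, seed=sub.generate_state(1)[0] % (2**31)
        )
        cube[idx] = apply_instrument(latent, slave, rng=noise_rng).spectra
    true_props = np.bincount(flat_truth, minlength=len(names)) / (rows * cols)
    return HyperCube(
        cube.reshape(rows, cols, bands),
        slave.grid_nm.copy(),
        truth_map=truth,
        truth_proportions=true_props,
        class_order=names,
    )
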