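"""Synthetic mixed-pixel scenes with exact ground truth.

No imagery or field data ship with this package, so every workflow is
exercised on simulated scenes: each pixel is a convex combination of a small
random subset (the "support") of a parametric V-I-S endmember library, plus
additive Gaussian band noise at a chosen SNR.  Field surveys are emulated by
sampling pixels and perturbing their true cover with measurement noise.

The spectra are shaped on the nominal band centers of two 30 m sensors: a
six-band Landsat-TM-like profile (blue, green, red, NIR, SWIR1, SWIR2) and a
four-band HJ-1B-CCD-like profile (blue, green, red, NIR).  Vegetation shows
the red-edge jump (NIR >> red), soil a bright monotone ramp, water low and
decreasing, impervious surface a mid-gray with a mild bow.  Band centers
only shape these spectra; the unmixing itself never consults wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fvc import FvcMap, classify_fvc, fvc_from_abundance
from .io import ImageCube, SpectralLibrary
from .lsmm import AbundanceMap
from .evaluation import PlotRecord

__all__ = ["SENSOR_PROFILES", "SimulationConfig", "SceneTruth",
           "make_endmember_spectra", "simulate_scene", "simulate_field_plots",
           "write_scene"]

#: Nominal band centers (nm) used only to shape parametric spectra.
SENSOR_PROFILES = {
    "tm6": {"centers": [485, 560, 660, 830, 1650, 2215],
            "names": ["blue", "green", "red", "nir", "swir1", "swir2"]},
    "hj4": {"centers": [475, 560, 660, 830],
            "names": ["blue", "green", "red", "nir"]},
}

# Base reflectance templates on the 6-band profile; hj4 truncates to 4.
# Repeated classes cycle through their variants (e.g. a second "soil"
# endmember becomes the darker loessal soil); "other" is dry grass / litter
# (non-photosynthetic vegetation with the cellulose SWIR2 drop).
_TEMPLATES = {
    "vegetation": [("vegetation", [0.045, 0.080, 0.050, 0.450, 0.230, 0.120])],
    "soil": [("sandy_soil", [0.100, 0.145, 0.200, 0.260, 0.330, 0.360]),
             ("loessal_soil", [0.060, 0.085, 0.120, 0.150, 0.170, 0.160])],
    "water": [("water", [0.060, 0.048, 0.032, 0.015, 0.006, 0.003])],
    "impervious": [("impervious", [0.190, 0.200, 0.215, 0.205, 0.225, 0.210])],
    "other": [("dry_litter", [0.120, 0.170, 0.230, 0.300, 0.380, 0.280])],
}
_JITTER_SD = 0.004


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic scene.

    Defaults mirror the desk-scale test conditions: a 64 x 64 scene of
    four V-I-S endmembers mixed at most two per pixel, 30 dB band SNR,
    uniform Dirichlet fractions, and a 30-plot field survey with 0.05
    cover-measurement noise (the survey comprised 30 plots sized to the
    pixel footprint).
    """

    rows: int = 64
    cols: int = 64
    sensor_profile: str = "tm6"
    n_endmembers: int = 4
    max_support: int = 2
    snr_db: float = 30.0
    dirichlet_alpha: float = 1.0
    field_plots: int = 30
    field_noise_sd: float = 0.05
    seed: int = 0
    classes: list[str] | None = None  # override the default V-I-S roster

    def __post_init__(self) -> None:
        if self.classes is not None and len(self.classes) != self.n_endmembers:
            raise ValueError("classes length must equal n_endmembers")
        if self.sensor_profile not in SENSOR_PROFILES:
            raise ValueError(f"unknown sensor profile {self.sensor_profile!r}")
        if not 1 <= self.max_support <= self.n_endmembers:
            raise ValueError("need 1 <= max_support <= n_endmembers")
        if self.classes is None and not 1 <= self.n_endmembers <= 4:
            raise ValueError("default roster supports 1-4 endmembers; pass "
                             "an explicit class list for more")
        if not np.isfinite(self.snr_db) and self.snr_db != np.inf:
            raise ValueError("snr_db must be finite or +inf (noiseless)")


@dataclass
class SceneTruth:
    """A simulated cube together with its exact generating truth."""

    cube: ImageCube
    true_abundances: AbundanceMap
    true_fvc: FvcMap
    library: SpectralLibrary
    config: SimulationConfig


def make_endmember_spectra(sensor_profile: str, classes: list[str],
                           seed: int = 0) -> SpectralLibrary:
    """Parametric V-I-S endmember spectra with small seeded jitter.

    Vegetation always keeps NIR above red (red-edge); spectra are clipped
    to stay positive.  Deterministic for a given seed.
    """
    if sensor_profile not in SENSOR_PROFILES:
        raise ValueError(f"unknown sensor profile {sensor_profile!r}")
    if len(classes) == 0:
        raise ValueError("at least one class required")
    profile = SENSOR_PROFILES[sensor_profile]
    m = len(profile["centers"])
    rng = np.random.default_rng(seed)
    spectra = []
    names = []
    counts: dict[str, int] = {}
    for cls in classes:
        if cls not in _TEMPLATES:
            raise ValueError(f"unknown V-I-S class {cls!r}")
        variants = _TEMPLATES[cls]
        k = counts.get(cls, 0)
        counts[cls] = k + 1
        name, base = variants[k % len(variants)]
        base = np.array(base, dtype=float)
        spec = base[:m] + rng.normal(0.0, _JITTER_SD, size=m)
        spec = np.clip(spec, 1e-3, 1.0)
        if cls == "vegetation":
            # guarantee the red-edge survives jitter
            red, nir = 2, 3
            spec[nir] = max(spec[nir], spec[red] + 0.2)
        if k >= len(variants):
            name = f"{name}_{k // len(variants) + 1}"
        names.append(name)
        spectra.append(spec)
    return SpectralLibrary(names=names, vis_class=list(classes),
                           spectra=np.vstack(spectra),
                           band_names=list(profile["names"][:m]))


def _default_classes(n: int) -> list[str]:
    """Dominant surfaces of a semi-arid grassland watershed: green
    vegetation on a mosaic of bright sandy and darker loessal soils, plus
    standing dry grass / litter.  Open water and built surfaces cover well
    under a percent of such terrain and are left to explicit class lists."""
    order = ["vegetation", "soil", "soil", "other"]
    return order[:n]


def simulate_scene(config: SimulationConfig) -> SceneTruth:
    """Generate a scene of sparse convex mixtures plus band noise.

    Per pixel: a support of at most ``max_support`` endmembers is drawn
    (support size uniform on 1..max_support), fractions come from a
    symmetric Dirichlet restricted to the support, and i.i.d. Gaussian noise
    is added per band with variance set so that the band's signal-variance /
    noise-variance ratio equals ``snr_db``.  Truth is stored exactly.
    """
    rng = np.random.default_rng(config.seed)
    classes = config.classes or _default_classes(config.n_endmembers)
    library = make_endmember_spectra(config.sensor_profile, classes,
                                     seed=int(rng.integers(2 ** 31)))
    n = library.n_endmembers
    rows, cols = config.rows, config.cols
    npix = rows * cols

    support_sizes = rng.integers(1, config.max_support + 1, size=npix)
    fractions = np.zeros((npix, n))
    for i in range(npix):
        s = int(support_sizes[i])
        members = rng.choice(n, size=s, replace=False)
        fractions[i, members] = rng.dirichlet(
            np.full(s, config.dirichlet_alpha))

    signal = fractions @ library.spectra            # (npix, m)
    data = signal.copy()
    if np.isfinite(config.snr_db):
        band_var = signal.var(axis=0)
        noise_var = band_var / (10.0 ** (config.snr_db / 10.0))
        noise = rng.standard_normal(signal.shape) * np.sqrt(noise_var)
        data = signal + noise

    m = library.n_bands
    cube = ImageCube(data=data.reshape(rows, cols, m),
                     band_names=list(library.band_names),
                     geotransform=(0.0, 1.0, 0.0, 0.0, 0.0, 1.0))
    frac_img = fractions.reshape(rows, cols, n)
    truth_abund = AbundanceMap(fractions=frac_img,
                               endmember_names=list(library.names),
                               residual_rms=np.zeros((rows, cols)),
                               selected_mask=frac_img > 0,
                               mask=cube.mask.copy(),
                               geotransform=cube.geotransform)
    truth_fvc = classify_fvc(fvc_from_abundance(truth_abund, library))
    return SceneTruth(cube=cube, true_abundances=truth_abund,
                      true_fvc=truth_fvc, library=library, config=config)


def simulate_field_plots(truth: SceneTruth, count: int,
                         field_noise_sd: float, seed: int = 0
                         ) -> list[PlotRecord]:
    """Emulate a field survey: distinct pixels, noisy cover readings.

    Plot coordinates sit at pixel centers; measured cover is the true FVC
    plus Gaussian noise, clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    valid_r, valid_c = np.nonzero(~truth.cube.mask)
    if count > valid_r.size:
        raise ValueError(
            f"requested {count} plots but only {valid_r.size} pixels exist")
    pick = rng.choice(valid_r.size, size=count, replace=False)
    gt = truth.cube.geotransform or (0.0, 1.0, 0.0, 0.0, 0.0, 1.0)
    x0, dxc, dxr, y0, dyc, dyr = gt
    plots = []
    for i, idx in enumerate(pick):
        r, c = int(valid_r[idx]), int(valid_c[idx])
        x = x0 + (c + 0.5) * dxc + (r + 0.5) * dxr
        y = y0 + (c + 0.5) * dyc + (r + 0.5) * dyr
        true = float(truth.true_fvc.fvc[r, c])
        measured = true + rng.normal(0.0, field_noise_sd) if field_noise_sd > 0 else true
        plots.append(PlotRecord(id=f"plot_{i + 1:03d}", x=x, y=y,
                                measured_fvc=float(np.clip(measured, 0.0, 1.0))))
    return plots


def write_scene(truth: SceneTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write scene, truth products, library and config to a directory."""
    from .io import write_raster, write_spectral_library

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["scene"] = write_raster(truth.cube, out / "scene.tif")
    abund_cube = ImageCube(data=truth.true_abundances.fractions,
                           mask=truth.cube.mask,
                           band_names=list(truth.library.names),
                           geotransform=truth.cube.geotransform)
    paths["truth_abund"] = write_raster(abund_cube, out / "truth_abund.tif")
    fvc_data = np.stack([truth.true_fvc.fvc,
                         truth.true_fvc.category.astype(float)], axis=2)
    fvc_cube = ImageCube(data=fvc_data, mask=truth.cube.mask,
                         band_names=["fvc", "category"],
                         geotransform=truth.cube.geotransform)
    paths["truth_fvc"] = write_raster(fvc_cube, out / "truth_fvc.tif")
    paths["library"] = write_spectral_library(truth.library, out / "library.csv")
    cfg = {k: (None if v is None else (float(v) if isinstance(v, float) else v))
           for k, v in vars(truth.config).items()}
    (out / "config.yaml").write_text(yaml.safe_dump(cfg))
    paths["config"] = out / "config.yaml"
    return paths
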