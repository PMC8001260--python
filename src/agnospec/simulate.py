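"""Synthetic peak-list generator for the four spectral classes.

The study spectra behind the classification protocol are not public, so
this module generates labeled peak lists carrying the qualitative
structure each class shows in real negative-ESI FT-ICR data:

* Petroleum — many long CH2 homologous series concentrated in a narrow
  KMD band, each followed by an "echo" band of the same shape at a
  distinct KMD and reduced intensity;
* Synthetic (iterative abiotic reactions) — mass ladders built on
  non-CH2 repeat units (HCN, CH2O, C2H4O), whose KMD drifts steadily
  along the ladder and so spreads across KMD bins in ordered
  progressions;
* Biological — comparatively few discrete masses with high log-intensity
  contrast, plus a handful of short lipid-like CH2 series;
* Meteorite — very high peak density with KMD spread over the full
  axis and moderate intensity contrast.

All classes share a common noise-floor model (sparse random
low-intensity peaks) and a small seeded mass jitter (0.2 ppm RMS) that
emulates FT-ICR mass accuracy without breaking 1-ppm biomarker
matching.  The generator is a deliberate caricature for pipeline
testing, not a chemical simulator: it reproduces peak-count density,
intensity contrast and KMD banding, not real compositional chemistry.

A ``difficulty`` knob in [0, 1] interpolates every class toward one
common random model; at 1 the classes are statistically identical and
classification accuracy must fall to chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .peaklist import (
    CH2_MASS,
    KENDRICK_FACTOR,
    Peak,
    Spectrum,
    write_manifest,
    write_peaklist,
)

__all__ = [
    "REPEAT_UNITS",
    "SynthParams",
    "CLASS_PRESETS",
    "generate_spectrum",
    "generate_dataset",
]

#: Monoisotopic masses (Da) of common abiotic repeat units.
REPEAT_UNITS = {
    "CH2": CH2_MASS,
    "HCN": 27.01089904,
    "CH2O": 30.01056468,
    "C2H4O": 44.02621475,
}

_MZ_WINDOW = (150.0, 750.0)


@dataclass(frozen=True)
class SynthParams:
    """Generator settings for one synthetic spectrum.

    Intensities are expressed on the natural-log scale relative to the
    noise floor; the abundance coordinate downstream only sees log
    contrasts, so the absolute scale is arbitrary.
    """

    class_name: str
    seed: int
    n_series: int = 0  # CH2 homologous series
    series_len: tuple[int, int] = (8, 30)  # min/max peaks per series
    kmd_band_mDa: tuple[float, float] = (0.0, 40.0)  # band center, spread
    n_ladders: int = 0  # non-CH2 repeat-unit ladders
    repeat_units: tuple[str, ...] = ("HCN", "CH2O", "C2H4O")
    n_singletons: int = 0  # isolated compound masses
    singleton_log_mu: float = 4.0
    singleton_log_sigma: float = 2.5  # log-intensity contrast
    series_log_mu: float = 3.0
    series_log_sigma: float = 0.8
    echo: bool = False
    echo_kmd_offset_mDa: float = 200.0
    echo_log_drop: float = 2.5
    n_random: int = 0  # dense random peaks (full KMD spread)
    noise_floor: int = 200
    noise_log_range: tuple[float, float] = (0.0, 1.0)
    mz_window: tuple[float, float] = _MZ_WINDOW
    jitter_ppm_rms: float = 0.2
    difficulty: float = 0.0  # 0 = preset structure, 1 = common random model

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for n in (self.n_series, self.n_ladders, self.n_singletons,
                  self.n_random, self.noise_floor):
            if n < 0:
                raise ValueError("counts must be non-negative")
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValueError("difficulty must lie in [0, 1]")
        for u in self.repeat_units:
            if REPEAT_UNITS.get(u, 0) <= 0:
                raise ValueError(f"unknown repeat unit {u!r}")


# Per-class defaults, mirroring the qualitative structure described in
# the module docstring.
CLASS_PRESETS: dict[str, SynthParams] = {
    "Petroleum": SynthParams(
        class_name="Petroleum", seed=0, n_series=25, series_len=(15, 40),
        kmd_band_mDa=(-20.0, 30.0), echo=True, noise_floor=250,
    ),
    "Synthetic": SynthParams(
        class_name="Synthetic", seed=0, n_ladders=18, noise_floor=250,
        series_log_sigma=1.2,
    ),
    "Biological": SynthParams(
        class_name="Biological", seed=0, n_singletons=180, n_series=6,
        series_len=(5, 12), kmd_band_mDa=(50.0, 15.0), noise_floor=150,
    ),
    "Meteorite": SynthParams(
        class_name="Meteorite", seed=0, n_random=4500, noise_floor=400,
        singleton_log_sigma=1.2,
    ),
}


def _mz_from_kendrick(nominal_km: np.ndarray, kmd_mDa: float) -> np.ndarray:
    """Measured m/z of peaks on one CH2 series with a fixed KMD (mDa)."""
    km = nominal_km - kmd_mDa / 1000.0
    return km / KENDRICK_FACTOR


def _series_peaks(rng, p: SynthParams, kmd_mDa: float, log_drop: float = 0.0):
    """One CH2 homologous series: (mz array, log-intensity array)."""
    lo, hi = p.mz_window
    length = int(rng.integers(p.series_len[0], p.series_len[1] + 1))
    start = int(rng.integers(int(lo) + 2, int(lo) + 260))
    nominal = start + 14 * np.arange(length)
    mz = _mz_from_kendrick(nominal.astype(float), kmd_mDa)
    keep = (mz >= lo) & (mz <= hi)
    mz = mz[keep]
    level = rng.normal(p.series_log_mu, p.series_log_sigma) - log_drop
    # hump-shaped intensity profile along the series
    t = np.linspace(-1, 1, len(mz)) if len(mz) > 1 else np.zeros(len(mz))
    logi = level - 1.5 * t**2 + rng.normal(0, 0.3, len(mz))
    return mz, logi


def _ladder_peaks(rng, p: SynthParams):
    """One repeat-unit mass ladder: (mz array, log-intensity array)."""
    lo, hi = p.mz_window
    unit = REPEAT_UNITS[p.repeat_units[int(rng.integers(len(p.repeat_units)))]]
    start = rng.uniform(lo, lo + 120.0)
    n_steps = int(np.floor((hi - start) / unit)) + 1
    mz = start + unit * np.arange(n_steps)
    mz = mz[(mz >= lo) & (mz <= hi)]
    level = rng.normal(p.series_log_mu, p.series_log_sigma)
    decay = rng.uniform(0.02, 0.12)  # ladders thin out with mass
    logi = level - decay * np.arange(len(mz)) + rng.normal(0, 0.3, len(mz))
    return mz, logi


def _random_peaks(rng, p: SynthParams, n: int, mu: float, sigma: float):
    lo, hi = p.mz_window
    mz = rng.uniform(lo, hi, n)
    logi = rng.normal(mu, sigma, n)
    return mz, logi


def generate_spectrum(p: SynthParams) -> Spectrum:
    """Generate one synthetic peak list; deterministic given params."""
    rng = np.random.default_rng(p.seed)
    lo, hi = p.mz_window
    mz_parts, logi_parts = [], []

    # interpolate structured counts toward a common random model
    scale = 1.0 - p.difficulty
    n_series = int(round(p.n_series * scale))
    n_ladders = int(round(p.n_ladders * scale))
    n_singletons = int(round(p.n_singletons * scale))
    n_random = int(round(p.n_random * scale))
    # structured peaks removed by difficulty are replaced by draws from a
    # model shared by all classes, so at difficulty = 1 every class has
    # the same peak-count and intensity distribution
    n_common = int(round(p.difficulty * 1500))
    n_noise = int(round((1.0 - p.difficulty) * p.noise_floor
                        + p.difficulty * 250))

    for _ in range(n_series):
        kmd = rng.normal(*p.kmd_band_mDa)
        mz, logi = _series_peaks(rng, p, kmd)
        mz_parts.append(mz)
        logi_parts.append(logi)
        if p.echo:
            emz, elogi = _series_peaks(
                rng, p, kmd + p.echo_kmd_offset_mDa, log_drop=p.echo_log_drop
            )
            mz_parts.append(emz)
            logi_parts.append(elogi)
    for _ in range(n_ladders):
        mz, logi = _ladder_peaks(rng, p)
        mz_parts.append(mz)
        logi_parts.append(logi)
    if n_singletons:
        mz, logi = _random_peaks(
            rng, p, n_singletons, p.singleton_log_mu, p.singleton_log_sigma
        )
        mz_parts.append(mz)
        logi_parts.append(logi)
    if n_random:
        mz, logi = _random_peaks(rng, p, n_random, 2.0, p.singleton_log_sigma)
        mz_parts.append(mz)
        logi_parts.append(logi)
    if n_common:
        mz, logi = _random_peaks(rng, p, n_common, 2.0, 1.5)
        mz_parts.append(mz)
        logi_parts.append(logi)
    if n_noise:
        mz = rng.uniform(lo, hi, n_noise)
        logi = rng.uniform(*p.noise_log_range, n_noise)
        mz_parts.append(mz)
        logi_parts.append(logi)

    mz = np.concatenate(mz_parts) if mz_parts else np.empty(0)
    logi = np.concatenate(logi_parts) if logi_parts else np.empty(0)
    mz = mz * (1.0 + rng.normal(0.0, p.jitter_ppm_rms * 1e-6, len(mz)))
    keep = (mz >= lo) & (mz <= hi)
    mz, logi = mz[keep], logi[keep]

    peaks = [Peak(float(m), float(np.exp(li))) for m, li in zip(mz, logi)]
    return Spectrum(
        sample_id=f"{p.class_name.lower()}-{p.seed}",
        peaks=peaks,
        label=p.class_name,
    )


def generate_dataset(
    per_class: int,
    master_seed: int = 0,
    out_dir: str | Path | None = None,
    difficulty: float = 0.0,
) -> list[Spectrum]:
    """Generate ``per_class`` spectra for each of the four classes.

    Child seeds are derived deterministically from ``master_seed`` via a
    seed sequence, so one integer reproduces the whole dataset.  When
    ``out_dir`` is given, peak lists are written as CSV files along with
    a ``manifest.csv`` in the same directory.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    classes = sorted(CLASS_PRESETS)
    child_seeds = np.random.SeedSequence(master_seed).generate_state(
        per_class * len(classes)
    )
    spectra = []
    idx = 0
    for cls in classes:
        preset = CLASS_PRESETS[cls]
        for i in range(per_class):
            seed = int(child_seeds[idx] % (2**31))
            idx += 1
            p = replace(preset, seed=seed, difficulty=difficulty)
            s = generate_spectrum(p)
            s.sample_id = f"{cls.lower()}-{i:03d}"
            spectra.append(s)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for s in spectra:
            fname = f"{s.sample_id}.csv"
            write_peaklist(s, out_dir / fname)
            rows.append((fname, s.sample_id, s.label))
        write_manifest(rows, out_dir / "manifest.csv")
    return spectra
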