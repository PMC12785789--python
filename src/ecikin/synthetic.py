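"""Synthetic inputs emulating the barrel-maturation study conditions.

No raw voltammograms, daily ECI tables or stave photographs are publicly
deposited, so every stage of the pipeline is exercised on generated data
with the structure the analysis assumes:

* DPV voltammograms: Gaussian oxidation peaks on a linear baseline with
  additive Gaussian noise, on the standard scan grid (−0.3 to 1.0 V vs
  Ag/AgCl(sat), 5 mV steps, 261 points).
* ECI time series: the bi-exponential extraction/adsorption model under
  the canonical sign convention, plus a linear late-phase ramp after a
  configurable onset (the closed-form model cannot produce the observed
  late increase, so phase (iv) is additive by construction; the fitting
  window is applied independently downstream), plus i.i.d. Gaussian noise.
* Stave-surface images: sinusoidal wood grain, random char-speckle
  blotches whose density/contrast grow with toast level, and pixel noise,
  clipped to 8-bit range.
* The toast-level × descriptor feature matrix from the reference tables
  (with injectable placeholders for the two FTIR descriptors that have no
  published scalar values).

All generators are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference as ref
from .kinetics import ECISeries, KineticParams, eval_model
from .voltammetry import Voltammogram

__all__ = [
    "PeakSpec",
    "KineticScenario",
    "TextureScenario",
    "DEFAULT_GRID",
    "gen_voltammogram",
    "gen_eci_series",
    "gen_texture_image",
    "gen_dpv_day_series",
    "assemble_feature_matrix",
]

#: Default DPV scan grid: (start V, stop V, step V) → 261 points.
DEFAULT_GRID: tuple[float, float, float] = (-0.3, 1.0, 0.005)


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian oxidation peak: centre [V], height [μA], sigma [V]."""

    center_potential: float
    height: float
    width: float

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("peak height must be ≥ 0")
        if self.width <= 0:
            raise ValueError("peak width must be > 0")


@dataclass(frozen=True)
class KineticScenario:
    """Ground-truth ECI kinetics for one toast level.

    Magnitudes follow the published convention; the generator applies the
    canonical signs (extraction negative).  ``late_slope``/``late_onset``
    parameterize the additive phase-(iv) ramp; ``noise_sd`` is the i.i.d.
    measurement noise per point [μA/V].
    """

    eci_eq: float
    a1_mag: float
    k1: float
    a2_mag: float
    k2: float
    late_slope: float = 0.002
    late_onset: float = 60.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("rate constants must be positive")
        if self.a1_mag < 0 or self.a2_mag < 0:
            raise ValueError("amplitude magnitudes must be ≥ 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if self.late_onset < 0:
            raise ValueError("late_onset must be ≥ 0")

    @classmethod
    def from_toast_level(cls, level: str, **overrides) -> "KineticScenario":
        """Scenario with the reference kinetic parameters of a toast level."""
        p = ref.KINETIC_REFERENCE[level]
        kw = dict(eci_eq=p["eci_eq"], a1_mag=p["a1_mag"], k1=p["k1"],
                  a2_mag=p["a2_mag"], k2=p["k2"])
        kw.update(overrides)
        return cls(**kw)

    @property
    def params(self) -> KineticParams:
        """The signed model parameters (canonical convention)."""
        return KineticParams.from_magnitudes(
            self.eci_eq, self.a1_mag, self.k1, self.a2_mag, self.k2
        )


@dataclass(frozen=True)
class TextureScenario:
    """Parameters of a synthetic stave-surface image.

    ``grain_*`` controls the periodic wood grain; ``speckle_*`` the random
    dark char blotches; intensities are gray levels in [0, 255].
    """

    image_size: int = 128
    grain_period: float = 24.0
    grain_orientation: float = 90.0   # degrees; 90 = vertical grain lines
    grain_amplitude: float = 20.0
    speckle_density: float = 0.004    # fraction of pixels seeding a blotch
    speckle_contrast: float = 50.0    # blotches cover ≈16 px each, so a
    base_level: float = 140.0         # density of 0.004 chars ≈6% of the area
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.speckle_density <= 1:
            raise ValueError("speckle_density must lie in [0, 1]")
        if self.image_size < 2:
            raise ValueError("image_size must be ≥ 2")
        if self.noise_sd < 0 or self.grain_amplitude < 0 or self.speckle_contrast < 0:
            raise ValueError("amplitudes and noise must be ≥ 0")

    @classmethod
    def preset(cls, level: str, **overrides) -> "TextureScenario":
        """Toast-level presets: speckle density/contrast grow, surface darkens."""
        presets = {
            "light": dict(speckle_density=0.002, speckle_contrast=40.0,
                          base_level=150.0, noise_sd=5.0),
            "medium": dict(speckle_density=0.004, speckle_contrast=50.0,
                           base_level=110.0, noise_sd=8.0),
            "intense": dict(speckle_density=0.008, speckle_contrast=60.0,
                            base_level=70.0, noise_sd=12.0),
        }
        kw = presets[level]
        kw.update(overrides)
        return cls(**kw)


def gen_voltammogram(
    peaks: Sequence[PeakSpec],
    baseline_slope: float = 0.0,
    baseline_intercept: float = 0.0,
    noise_sd: float = 0.0,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    seed: int | None = None,
    **metadata,
) -> Voltammogram:
    """Simulate a DPV curve: Gaussian peaks + linear baseline + Gaussian noise.

    current(E) = intercept + slope·E + Σ h·exp(−(E−c)²/(2σ²)) + ε

    Raises if any peak centre lies outside the scan range (naming it).
    """
    start, stop, step = grid
    if step <= 0:
        raise ValueError("grid step must be positive")
    n = int(round((stop - start) / step)) + 1
    E = start + step * np.arange(n)
    for p in peaks:
        if not (start <= p.center_potential <= stop):
            raise ValueError(
                f"peak at {p.center_potential} V lies outside scan range "
                f"[{start}, {stop}] V"
            )
    I = baseline_intercept + baseline_slope * E
    for p in peaks:
        I = I + p.height * np.exp(-((E - p.center_potential) ** 2) / (2 * p.width**2))
    if noise_sd > 0:
        I = I + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return Voltammogram(potentials=E, currents=I, **metadata)


def eci_truth(s: KineticScenario, days) -> np.ndarray:
    """Noise-free ECI curve of a scenario: canonical model + late ramp."""
    t = np.asarray(days, dtype=float)
    vals = np.asarray(eval_model(s.params, t), dtype=float)
    ramp = np.where(t > s.late_onset, s.late_slope * (t - s.late_onset), 0.0)
    return vals + ramp


def gen_eci_series(
    s: KineticScenario,
    days: Sequence[float],
    replicates_per_day: int = 1,
) -> ECISeries:
    """Generate a noisy ECI series from a kinetic scenario.

    ``replicates_per_day`` independent noisy measurements are drawn per
    day (replicate ids 0..r−1); identical scenarios (including the seed)
    give bit-identical series.
    """
    days = np.asarray(days, dtype=float)
    if days.size and ((days < 0).any() or np.any(np.diff(days) < 0)):
        raise ValueError("days must be non-negative and sorted")
    if replicates_per_day < 1:
        raise ValueError("replicates_per_day must be ≥ 1")
    t = np.repeat(days, replicates_per_day)
    reps = np.tile(np.arange(replicates_per_day), days.size)
    vals = eci_truth(s, t)
    if s.noise_sd > 0:
        vals = vals + np.random.default_rng(s.seed).normal(0.0, s.noise_sd, size=t.size)
    return ECISeries(days=t, values=vals, replicates=reps)


def gen_texture_image(s: TextureScenario) -> np.ndarray:
    """Synthesize an 8-bit stave-surface image from a texture scenario.

    Sinusoidal grain along the configured orientation, dark circular char
    blotches (radius 1–3 px) at randomly seeded positions, and Gaussian
    pixel noise, clipped to [0, 255].
    """
    rng = np.random.default_rng(s.seed)
    nsz = s.image_size
    yy, xx = np.mgrid[0:nsz, 0:nsz].astype(float)
    theta = np.deg2rad(s.grain_orientation)
    phase = (xx * np.cos(theta) + yy * np.sin(theta)) / s.grain_period
    img = s.base_level + s.grain_amplitude * np.sin(2 * np.pi * phase)

    n_blotch = int(round(s.speckle_density * nsz * nsz))
    if n_blotch and s.speckle_contrast > 0:
        cy = rng.integers(0, nsz, n_blotch)
        cx = rng.integers(0, nsz, n_blotch)
        rad = rng.integers(1, 4, n_blotch)
        depth = s.speckle_contrast * rng.uniform(0.5, 1.0, n_blotch)
        for y0, x0, r, d in zip(cy, cx, rad, depth):
            ylo, yhi = max(y0 - r, 0), min(y0 + r + 1, nsz)
            xlo, xhi = max(x0 - r, 0), min(x0 + r + 1, nsz)
            sub_y, sub_x = np.mgrid[ylo:yhi, xlo:xhi]
            mask = (sub_y - y0) ** 2 + (sub_x - x0) ** 2 <= r * r
            img[ylo:yhi, xlo:xhi][mask] -= d
    if s.noise_sd > 0:
        img = img + rng.normal(0.0, s.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def gen_dpv_day_series(
    s: KineticScenario,
    days: Sequence[float],
    targets: tuple[float, float] = (0.34, 0.50),
    split: float = 0.5,
    peak_width: float = 0.03,
    dpv_noise_sd: float = 0.0,
    toast_level: str | None = None,
) -> list[Voltammogram]:
    """Voltammograms whose peak heights follow a kinetic scenario's ECI curve.

    The target ECI value of each day is apportioned between the two peaks
    (fraction ``split`` of the index through the first peak), so
    peak detection followed by the index computation recovers the curve.
    Negative model values (possible right at t = 0) are clipped to 0.
    """
    e1, e2 = targets
    out = []
    vals = eci_truth(s, np.asarray(days, dtype=float))
    if s.noise_sd > 0:
        vals = vals + np.random.default_rng(s.seed).normal(0.0, s.noise_sd, len(vals))
    for d, eci in zip(days, vals):
        eci = max(float(eci), 0.0)
        peaks = [
            PeakSpec(e1, split * eci * e1, peak_width),
            PeakSpec(e2, (1.0 - split) * eci * e2, peak_width),
        ]
        out.append(gen_voltammogram(
            peaks, noise_sd=dpv_noise_sd, seed=s.seed + int(d),
            day=float(d), toast_level=toast_level,
        ))
    return out


def assemble_feature_matrix(
    kinetics: pd.DataFrame | None = None,
    descriptors: pd.DataFrame | None = None,
    ftir_oh: Mapping[str, float] | None = None,
    ftir_co: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Build the 3 × 11 toast-level × descriptor matrix in canonical order.

    Parameters
    ----------
    kinetics : DataFrame, optional
        Rows indexed by toast level with columns a1, a2, k1, k2, eci_eq
        (amplitudes as magnitudes).  Defaults to the reference kinetic
        parameters.
    descriptors : DataFrame, optional
        Rows indexed by toast level with the structural descriptor
        columns (ftir_oh, ftir_co, raman_g, contrast, entropy,
        homogeneity).  Defaults to the reference values, with synthetic
        placeholder FTIR triples.
    ftir_oh, ftir_co : mapping, optional
        Override just the FTIR descriptors (level → value).

    Raises
    ------
    ValueError
        If the two tables cover different toast levels, or any of the 11
        descriptors is missing (naming it).
    """
    levels = list(ref.TOAST_LEVELS)
    if kinetics is None:
        kinetics = pd.DataFrame({
            "a1": [ref.KINETIC_REFERENCE[l]["a1_mag"] for l in levels],
            "a2": [ref.KINETIC_REFERENCE[l]["a2_mag"] for l in levels],
            "k1": [ref.KINETIC_REFERENCE[l]["k1"] for l in levels],
            "k2": [ref.KINETIC_REFERENCE[l]["k2"] for l in levels],
            "eci_eq": [ref.KINETIC_REFERENCE[l]["eci_eq"] for l in levels],
        }, index=levels)
    if descriptors is None:
        oh = dict(ftir_oh or ref.FTIR_OH_PLACEHOLDER)
        co = dict(ftir_co or ref.FTIR_CO_PLACEHOLDER)
        descriptors = pd.DataFrame({
            "ftir_oh": [oh[l] for l in levels],
            "ftir_co": [co[l] for l in levels],
            "raman_g": [ref.RAMAN_G[l] for l in levels],
            "contrast": [ref.TEXTURE_REFERENCE[l]["contrast"] for l in levels],
            "entropy": [ref.TEXTURE_REFERENCE[l]["entropy"] for l in levels],
            "homogeneity": [ref.TEXTURE_REFERENCE[l]["homogeneity"] for l in levels],
        }, index=levels)
    elif ftir_oh is not None or ftir_co is not None:
        descriptors = descriptors.copy()
        if ftir_oh is not None:
            descriptors["ftir_oh"] = [ftir_oh[l] for l in descriptors.index]
        if ftir_co is not None:
            descriptors["ftir_co"] = [ftir_co[l] for l in descriptors.index]

    if set(kinetics.index) != set(descriptors.index):
        raise ValueError("kinetics and descriptors must cover the same toast levels")
    row_order = [l for l in levels if l in kinetics.index] or list(kinetics.index)
    merged = descriptors.join(kinetics)
    for col in ref.DESCRIPTOR_ORDER:
        if col not in merged.columns:
            raise ValueError(f"missing descriptor: {col!r}")
        if merged[col].isna().any():
            raise ValueError(f"missing values in descriptor: {col!r}")
    return merged.loc[row_order, list(ref.DESCRIPTOR_ORDER)].astype(float)
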