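"""Synthetic SERS spectra of adenosine-phosphate (AP) mixtures.

Generates labelled spectra with the statistical structure the analysis
pipeline assumes: shared adenine-moiety bands near 730/1330/1460 cm^-1
(ring breathing; C-N/C-C stretch; N7-C8 stretch + NH2 scissor),
phosphate-sensitive bands near 1075 and 1180 cm^-1 whose amplitude scales
with the number of phosphate groups (AMP 1, ADP 2, ATP 3), a smooth random
quintic baseline, per-spectrum multiplicative enhancement variability
(substrate-to-substrate SERS efficiency), additive white noise, and broad
band-free stretches so a pure-noise shift cluster exists.

The inter-species differences are deliberately subtle: adenine band centers
are offset by a few cm^-1 per species, so mixtures differ mainly in line
shape and in the phosphate-band weight — the regime that makes simultaneous
recognition of the three APs hard.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .dataset import GROUP_RATIOS, SPECIES, SpectrumSet, group_from_ratio, make_labels

#: Phosphate-group count per species; scales the phosphate-band amplitudes.
PHOSPHATE_COUNT: dict[str, int] = {"AMP": 1, "ADP": 2, "ATP": 3}

#: Shared adenine bands as (center cm^-1, FWHM cm^-1, amplitude).
#: The ring-breathing band near 730 cm^-1 is the strongest feature.
ADENINE_BANDS: tuple[tuple[float, float, float], ...] = (
    (730.0, 12.0, 1.00),
    (1330.0, 14.0, 0.55),
    (1460.0, 16.0, 0.40),
)

#: Phosphate-sensitive bands as (center, FWHM, amplitude per phosphate group).
PHOSPHATE_BANDS: tuple[tuple[float, float, float], ...] = (
    (1075.0, 12.0, 0.10),
    (1180.0, 12.0, 0.12),
)


@dataclasses.dataclass(frozen=True)
class BandSpec:
    """One vibrational band: a symmetric peak on the shift axis."""

    center: float
    width: float  # full width at half maximum, cm^-1
    amplitude: float
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if not 200.0 <= self.center <= 1700.0:
            raise ValueError(f"band center {self.center} outside [200, 1700] cm^-1")
        if self.width <= 0:
            raise ValueError(f"band width must be positive, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"band amplitude must be >= 0, got {self.amplitude}")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def evaluate(self, shifts: np.ndarray) -> np.ndarray:
        """Peak profile on the grid; the value at ``center`` is ``amplitude``."""
        x = np.asarray(shifts, dtype=float)
        half = self.width / 2.0
        if self.shape == "lorentzian":
            return self.amplitude * half**2 / ((x - self.center) ** 2 + half**2)
        # gaussian parameterized by FWHM
        sigma = self.width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return self.amplitude * np.exp(-0.5 * ((x - self.center) / sigma) ** 2)


@dataclasses.dataclass(frozen=True)
class SpeciesProfile:
    """Band dictionary of one adenosine phosphate."""

    species: str
    bands: tuple[BandSpec, ...]
    phosphate_count: int

    def evaluate(self, shifts: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(shifts, dtype=float))
        for band in self.bands:
            out += band.evaluate(shifts)
        return out


@dataclasses.dataclass
class SyntheticConfig:
    """Generator configuration.

    Defaults emulate the measured-study conditions: 7 mixing ratios with 20
    replicates each (140 spectra) on a 200-1700 cm^-1 grid at 1 cm^-1 step.
    ``noise_sd`` is expressed relative to the strongest clean band of each
    spectrum; its default, together with ``enhancement_sd`` and the baseline
    ranges, is calibrated so the full feature-selected + augmented MLP
    pipeline operates in a realistic high-but-imperfect accuracy regime.
    """

    grid_lo: float = 200.0
    grid_hi: float = 1700.0
    grid_step: float = 1.0
    replicates_per_ratio: int = 20
    ratios: tuple[tuple[int, int, int], ...] = tuple(GROUP_RATIOS.values())
    #: per-species center offset (cm^-1) applied to the adenine bands
    adenine_offsets: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"AMP": 0.0, "ADP": 2.0, "ATP": 4.0}
    )
    peak_shape: str = "lorentzian"
    #: uniform sampling ranges for quintic-baseline coefficients c0..c5 on
    #: the normalized coordinate t = (shift - lo)/(hi - lo) in [0, 1]
    baseline_coeff_ranges: tuple[tuple[float, float], ...] = (
        (0.5, 2.0),
        (-0.5, 0.5),
        (-0.5, 0.5),
        (-0.5, 0.5),
        (-0.5, 0.5),
        (-0.5, 0.5),
    )
    #: log-scale sd of the per-spectrum multiplicative enhancement factor
    enhancement_sd: float = 0.15
    #: additive white-noise sd as a fraction of each spectrum's max clean band;
    #: calibrated so the feature-selected + augmented MLP pipeline operates in
    #: the 0.85-0.95 pooled-accuracy band
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_lo >= self.grid_hi:
            raise ValueError("grid_lo must be < grid_hi")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.replicates_per_ratio < 1:
            raise ValueError("replicates_per_ratio must be >= 1")
        if len(self.baseline_coeff_ranges) != 6:
            raise ValueError("baseline_coeff_ranges must give 6 (lo, hi) pairs")
        for ratio in self.ratios:
            if any(r < 0 for r in ratio) or not any(r > 0 for r in ratio):
                raise ValueError(f"invalid mixing ratio {ratio}")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_hi - self.grid_lo) / self.grid_step)) + 1
        return self.grid_lo + self.grid_step * np.arange(n)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["adenine_offsets"] = dict(self.adenine_offsets)
        return d


def species_profile(species: str, config: SyntheticConfig | None = None) -> SpeciesProfile:
    """Default band dictionary for one AP species.

    The three adenine bands are identical across species up to the
    configured small center offsets; the two phosphate bands scale linearly
    with the species' phosphate count.
    """
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    config = config or SyntheticConfig()
    offset = float(config.adenine_offsets.get(species, 0.0))
    if abs(offset) > 5.0:
        raise ValueError(f"adenine offset for {species} exceeds 5 cm^-1: {offset}")
    count = PHOSPHATE_COUNT[species]
    bands = [
        BandSpec(center + offset, width, amp, config.peak_shape)
        for center, width, amp in ADENINE_BANDS
    ]
    bands += [
        BandSpec(center, width, amp_per_p * count, config.peak_shape)
        for center, width, amp_per_p in PHOSPHATE_BANDS
    ]
    return SpeciesProfile(species=species, bands=tuple(bands), phosphate_count=count)


def default_profiles(config: SyntheticConfig | None = None) -> dict[str, SpeciesProfile]:
    config = config or SyntheticConfig()
    return {sp: species_profile(sp, config) for sp in SPECIES}


def render_clean_spectrum(
    ratio: Sequence[float],
    profiles: Mapping[str, SpeciesProfile],
    shifts: np.ndarray,
) -> np.ndarray:
    """Noise- and baseline-free mixture spectrum.

    The ratio is normalized to fractions over its non-zero components; the
    output is the fraction-weighted sum of the species band sums (linear
    mixing), hence strictly non-negative.
    """
    ratio = np.asarray(ratio, dtype=float)
    if ratio.shape != (3,):
        raise ValueError("ratio must be a triplet")
    if np.any(ratio < 0):
        raise ValueError(f"ratio entries must be non-negative, got {ratio}")
    total = ratio.sum()
    if total == 0:
        raise ValueError("all-zero mixing ratio cannot be rendered")
    fractions = ratio / total
    out = np.zeros_like(np.asarray(shifts, dtype=float))
    for frac, sp in zip(fractions, SPECIES):
        if frac > 0:
            out += frac * profiles[sp].evaluate(shifts)
    return out


def _random_baseline(
    rng: np.random.Generator,
    shifts: np.ndarray,
    coeff_ranges: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Quintic baseline with coefficients drawn uniformly per degree.

    Evaluated on the normalized coordinate t in [0, 1] so that ranges are
    scale-free; any such polynomial is also a quintic in the raw shift, so
    a quintic baseline corrector can remove it exactly.
    """
    t = (shifts - shifts[0]) / (shifts[-1] - shifts[0])
    coeffs = np.array([rng.uniform(lo, hi) for lo, hi in coeff_ranges])
    return np.polynomial.polynomial.polyval(t, coeffs)


def generate_dataset(config: SyntheticConfig | None = None) -> SpectrumSet:
    """Generate the full labelled synthetic dataset.

    For each mixing ratio, ``replicates_per_ratio`` spectra are produced as

        enhancement * clean_mixture + baseline + noise

    with a log-normal per-spectrum enhancement factor, a random quintic
    baseline and i.i.d. Gaussian noise of sd ``noise_sd`` times the
    spectrum's maximum clean intensity.  Bit-reproducible for a fixed seed.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    shifts = config.grid()
    profiles = default_profiles(config)

    rows: list[np.ndarray] = []
    ids: list[str] = []
    ratios: list[tuple[int, int, int]] = []
    for ratio in config.ratios:
        clean = render_clean_spectrum(ratio, profiles, shifts)
        sigma = config.noise_sd * clean.max()
        gid = group_from_ratio(ratio)
        for rep in range(1, config.replicates_per_ratio + 1):
            enhancement = float(np.exp(rng.normal(0.0, config.enhancement_sd))) if config.enhancement_sd > 0 else 1.0
            baseline = _random_baseline(rng, shifts, config.baseline_coeff_ranges)
            noise = rng.normal(0.0, sigma, size=shifts.shape) if sigma > 0 else 0.0
            rows.append(enhancement * clean + baseline + noise)
            ids.append(f"g{gid}_r{rep}")
            ratios.append(tuple(ratio))

    labels = make_labels(ids, ratios, origin="measured")
    return SpectrumSet(
        shifts=shifts,
        intensities=np.vstack(rows),
        labels=labels,
        meta={"config": config.to_dict()},
    )
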