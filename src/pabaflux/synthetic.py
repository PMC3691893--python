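"""Ground-truth synthetic N-acetyl-PABA ¹³C studies.

Generates, from stated acetyl isotopomer enrichments, the multiplet areas
and Lorentzian line spectra that the quantification chain consumes — the
exact inverse of the enrichment equations, so that noise-free synthesis
followed by integration and quantification recovers the input profile.

Forward model
-------------
With excesses (e₁, e₂, e₁₂) in percent and natural abundance NA = 1.11%:

* total [2-¹³C] = e₂ + NA; total [1-¹³C] = e₁ + NA; total [1,2-¹³C₂] = e₁₂
  (the doubly labeled background, ~NA², is negligible and omitted).
* A per-carbon aromatic reference area ``A`` corresponds to NA, so a signal
  carrying p% enrichment has area (p/NA)·A before attenuation.
* Per-signal T₁/nOe attenuation factors multiply the acetyl and aromatic
  areas; the matching correction factor is CF = att_aromatic/att_c2.

Spectra are sums of Lorentzians: each singlet at its center, each doublet
as two half-area lines at ±J/(2·ν₀) ppm, plus seeded additive Gaussian
noise.  An optional N-acetyl-PAH interference line can be placed at a
configurable offset downfield of each acetyl component (excluded from the
default integration windows).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .nmr import (MultipletAreas, NATURAL_ABUNDANCE_PCT, QuantificationError,
                  Spectrum, SpectrumLayout)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Ground truth and instrument emulation parameters.

    Attenuation defaults reflect the physics qualitatively: the
    protonated methyl (C2) relaxes efficiently and keeps most of its nOe
    (0.9), the quaternary carbonyl C1 is T₁/nOe-penalized (0.5), and the
    protonated aromatic reference carbons are the anchor (1.0).  All of it
    is absorbed by CF downstream; the exact values are synthetic
    conventions, as are the acetyl chemical shifts.
    """

    excess_1_13c: float = 0.4
    excess_2_13c: float = 1.1
    excess_12_13c2: float = 2.0
    natural_abundance: float = NATURAL_ABUNDANCE_PCT
    layout: SpectrumLayout = field(default_factory=SpectrumLayout)
    noise_sd: float = 0.002          # fraction of the max clean intensity
    attenuation_c1: float = 0.5
    attenuation_c2: float = 0.9
    attenuation_aromatic: float = 1.0
    linewidth_factor_35: float = 1.0  # the C3,5 signal may be broader
    aromatic_area_per_carbon: float = 1.0
    pah_offset_ppm: float | None = None   # e.g. 0.15 to add interference
    pah_relative_amplitude: float = 0.08
    region_half_width_ppm: float = 1.0
    points_per_linewidth: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("excess_1_13c", "excess_2_13c", "excess_12_13c2"):
            if getattr(self, name) < 0:
                raise QuantificationError(f"{name} must be >= 0")
        if not 0 < self.natural_abundance < 100:
            raise QuantificationError("natural_abundance must be in (0, 100)%")
        tot_c1 = self.excess_1_13c + self.natural_abundance + self.excess_12_13c2
        tot_c2 = self.excess_2_13c + self.natural_abundance + self.excess_12_13c2
        if tot_c1 > 100 or tot_c2 > 100:
            raise QuantificationError(
                "infeasible enrichments: a per-carbon total exceeds 100%")
        for name in ("attenuation_c1", "attenuation_c2", "attenuation_aromatic"):
            if not 0 < getattr(self, name) <= 1:
                raise QuantificationError(f"{name} must be in (0, 1]")
        if self.noise_sd < 0:
            raise QuantificationError("noise_sd must be >= 0")

    @property
    def true_correction_factor(self) -> float:
        """CF consistent with the attenuation factors (what a matched
        nonenriched reference would yield)."""
        return self.attenuation_aromatic / self.attenuation_c2

    def nonenriched(self) -> "SyntheticStudyConfig":
        """The matching reference: same instrument, zero excesses."""
        return replace(self, excess_1_13c=0.0, excess_2_13c=0.0,
                       excess_12_13c2=0.0)


def profile_to_areas(cfg: SyntheticStudyConfig) -> MultipletAreas:
    """Ground-truth multiplet areas implied by the configured enrichments.

    Exact inverse of the quantification chain: with the matching CF
    attached, quantification of these areas returns the configured
    profile to machine precision.
    """
    na = cfg.natural_abundance
    a = cfg.aromatic_area_per_carbon
    total_1 = cfg.excess_1_13c + na
    total_2 = cfg.excess_2_13c + na
    total_12 = cfg.excess_12_13c2
    return MultipletAreas(
        c1_singlet=(total_1 / na) * a * cfg.attenuation_c1,
        c1_doublet=(total_12 / na) * a * cfg.attenuation_c1,
        c2_singlet=(total_2 / na) * a * cfg.attenuation_c2,
        c2_doublet=(total_12 / na) * a * cfg.attenuation_c2,
        aromatic_26=2.0 * a * cfg.attenuation_aromatic,
        aromatic_35=2.0 * a * cfg.attenuation_aromatic,
        correction_factor=cfg.true_correction_factor,
    )


def _lorentzian(x: np.ndarray, center: float, area: float,
                fwhm: float) -> np.ndarray:
    gamma = fwhm / 2.0
    return area * gamma / (np.pi * ((x - center) ** 2 + gamma ** 2))


def _axis(cfg: SyntheticStudyConfig) -> np.ndarray:
    """Concatenated sampling windows around the three spectral regions."""
    lay = cfg.layout
    step = lay.linewidth_ppm / cfg.points_per_linewidth
    hw = cfg.region_half_width_ppm
    centers = sorted({lay.c2_center_ppm, lay.aromatic_35_ppm,
                      lay.aromatic_26_ppm, lay.c1_center_ppm})
    segments: list[np.ndarray] = []
    prev_hi = -np.inf
    for c in centers:
        lo, hi = c - hw, c + hw
        lo = max(lo, prev_hi + step)  # merge overlapping regions
        if hi > lo:
            segments.append(np.arange(lo, hi, step))
            prev_hi = segments[-1][-1]
    return np.concatenate(segments)


def areas_to_spectrum(areas: MultipletAreas, cfg: SyntheticStudyConfig,
                      rng: np.random.Generator | None = None) -> Spectrum:
    """Synthesize a sampled ¹³C spectrum from multiplet areas.

    Singlets are single Lorentzians; doublets are two half-area lines at
    center ± J/(2·ν₀).  With a fixed seed the spectrum is bit-identical
    across reruns.
    """
    lay = cfg.layout
    x = _axis(cfg)
    fwhm = lay.linewidth_ppm
    centers = lay.peak_centers()
    y = np.zeros_like(x)
    components = [
        ("C1S", areas.c1_singlet), ("C1D_left", areas.c1_doublet / 2),
        ("C1D_right", areas.c1_doublet / 2),
        ("C2S", areas.c2_singlet), ("C2D_left", areas.c2_doublet / 2),
        ("C2D_right", areas.c2_doublet / 2),
    ]
    for label, area in components:
        y += _lorentzian(x, centers[label], area, fwhm)
        if cfg.pah_offset_ppm:
            y += _lorentzian(x, centers[label] + cfg.pah_offset_ppm,
                             area * cfg.pah_relative_amplitude, fwhm)
    y += _lorentzian(x, centers["P26"], areas.aromatic_26, fwhm)
    y += _lorentzian(x, centers["P35"], areas.aromatic_35,
                     fwhm * cfg.linewidth_factor_35)
    if cfg.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        y = y + rng.normal(0.0, cfg.noise_sd * float(y.max()), size=y.size)
    return Spectrum(x, y, lay.spectrometer_c13_freq)


def synthesize_spectrum(cfg: SyntheticStudyConfig,
                        rng: np.random.Generator | None = None) -> Spectrum:
    """Profile → areas → spectrum in one step."""
    return areas_to_spectrum(profile_to_areas(cfg), cfg, rng)


@dataclass(frozen=True)
class SyntheticStudy:
    """A generated cohort: per-animal spectra, matching nonenriched
    reference, and the ground-truth table."""

    spectra: tuple[Spectrum, ...]
    reference: Spectrum
    truth: pd.DataFrame          # per-animal excess enrichments, %
    config: SyntheticStudyConfig
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, spec in enumerate(self.spectra, start=1):
            spec.to_csv(out / f"animal_{i:02d}.csv")
        self.reference.to_csv(out / "reference_nonenriched.csv")
        self.truth.to_csv(out / "truth.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


#: Default between-animal SDs for (e1, e2, e12), percent.
DEFAULT_ANIMAL_SD = (0.1, 0.1, 0.2)


def generate_study(cfg: SyntheticStudyConfig, n_animals: int = 4,
                   between_animal_sd: tuple[float, float, float] = DEFAULT_ANIMAL_SD,
                   seed: int | None = None) -> SyntheticStudy:
    """Generate an n-animal cohort around the configured ground truth.

    Per-animal excess enrichments are drawn from independent normals
    centered on the configured truth (clipped at 0) with the given SDs,
    emulating biological between-animal variation; each animal gets its
    own noisy spectrum, and one nonenriched reference spectrum is included
    for CF derivation.  The manifest records the seed and truth.
    """
    if n_animals < 1:
        raise QuantificationError("n_animals must be >= 1")
    seed = cfg.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    truth_rows = []
    spectra = []
    means = np.array([cfg.excess_1_13c, cfg.excess_2_13c, cfg.excess_12_13c2])
    sds = np.asarray(between_animal_sd, dtype=float)
    if sds.shape != (3,) or np.any(sds < 0):
        raise QuantificationError("between_animal_sd must be three values >= 0")
    for i in range(n_animals):
        e1, e2, e12 = np.clip(means + sds * rng.standard_normal(3), 0.0, None)
        animal_cfg = replace(cfg, excess_1_13c=float(e1),
                             excess_2_13c=float(e2), excess_12_13c2=float(e12))
        spectra.append(synthesize_spectrum(animal_cfg, rng))
        truth_rows.append({"animal": i + 1, "excess_1_13c": e1,
                           "excess_2_13c": e2, "excess_12_13c2": e12})
    reference = synthesize_spectrum(cfg.nonenriched(), rng)
    truth = pd.DataFrame(truth_rows)
    manifest = {
        "seed": seed,
        "n_animals": n_animals,
        "between_animal_sd": list(map(float, sds)),
        "truth_mean": {"excess_1_13c": cfg.excess_1_13c,
                       "excess_2_13c": cfg.excess_2_13c,
                       "excess_12_13c2": cfg.excess_12_13c2},
        "noise_sd": cfg.noise_sd,
    }
    return SyntheticStudy(spectra=tuple(spectra), reference=reference,
                          truth=truth, config=cfg, manifest=manifest)
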