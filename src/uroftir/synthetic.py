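"""Synthetic liquid-urine ATR-FTIR cohort generator.

The clinical spectra behind the screening study are not publicly
deposited, so the pipeline is exercised on simulated cohorts that copy the
study's structure: 206 control and 103 cancer patients, three technical
replicates each, 24 noise-averaged scans per replicate, spectra on a
4000-400 cm^-1 grid dominated by the water background, and two narrow
class-dependent bands (1773 and 2093 cm^-1) whose absorbance is *lower* in
the cancer group.

Measurement model per replicate spectrum::

    A(v) = s * [ sum_b amp_b(patient) * exp(-(v - c_b)^2 / (2 w_b^2)) ]
           + offset + slope * (v - v_mid) + eps(v)

where s is a multiplicative scatter factor and eps white noise with
standard deviation ``noise_sd / sqrt(scans)`` (scan averaging emulated as
noise reduction).  Band amplitudes are drawn once per patient (replicates
share them); for biomarker bands the class-1 mean is shifted down by
``class_delta``.  Band shapes are Gaussian — real ATR-FTIR bands are
Voigt-like, but Gaussians keep closed-form expectations for testing.

A matching double-distilled-water reference spectrum (water bands only,
own noise draw) is emitted so the subtraction stage runs exactly as in the
real workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectraSet, WavenumberGrid, assemble_set, write_dpt

__all__ = [
    "BandSpec",
    "CohortSpec",
    "SyntheticCohort",
    "default_cohort_spec",
    "generate_patient",
    "generate_cohort",
    "null_cohort",
    "cohort_to_set",
    "write_cohort",
]

#: the study's fixed seed
DEFAULT_SEED = 333

#: cancer-subtype composition of the study cohort (sums to 103)
SUBTYPE_COUNTS = {"breast": 29, "cervical": 10, "ovarian": 31, "uterine": 32, "vulvar": 1}


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``class_delta`` is the control-minus-cancer mean amplitude difference
    (positive = more absorbance in controls); ``class_shift`` the
    control-minus-cancer band-position separation in cm^-1, applied
    symmetrically (control at centre + shift/2, cancer at centre - shift/2)
    so the class difference stays centred on ``centre``  (disease-associated
    bands change position as well as intensity, and a position change is
    what gives a symmetric band a class signal *at its centre* in
    first-derivative space); ``patient_sd`` the between-patient amplitude
    standard deviation; ``position_sd`` the between-patient band-position
    jitter in cm^-1 (matrix and pH effects move biofluid band positions by
    about a wavenumber); ``width_sd`` the between-patient band-width jitter
    in cm^-1 (its perturbation mode vanishes at the band centre, so width
    variability broadens flanks without blurring the centre).
    """

    centre: float          # cm^-1
    width: float           # Gaussian sigma, cm^-1
    amplitude: float       # mean amplitude in controls, AU
    class_delta: float = 0.0
    class_shift: float = 0.0
    patient_sd: float = 0.0
    position_sd: float = 0.0
    width_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Structural and noise parameters of a simulated cohort.

    Defaults copy the study conditions (cohort sizes, replicates, scans,
    grid) with effect sizes calibrated once to a standardised difference of
    about d = 2.5 at the planted band centres on raw water-subtracted
    absorbance (see ``analysis/00_calibrate_effect.py``).
    """

    n_control: int = 206
    n_cancer: int = 103
    replicates: int = 3
    scans: int = 24
    grid_max: float = 4000.0
    grid_min: float = 400.0
    grid_step: float = 1.0
    water_bands: tuple[BandSpec, ...] = (
        BandSpec(3350.0, 160.0, 0.85),   # O-H stretch
        BandSpec(1640.0, 40.0, 0.35),    # H-O-H bend
    )
    solute_bands: tuple[BandSpec, ...] = (
        BandSpec(1460.0, 25.0, 0.080, patient_sd=0.002, position_sd=1.0),   # urea
        BandSpec(1160.0, 30.0, 0.050, patient_sd=0.0015, position_sd=1.0),  # creatinine
    )
    # each biomarker is a narrow band whose position separates the classes
    # (first-derivative signal peaked at the centre) riding on a broad
    # envelope whose level separates them (raw-absorbance signal at the
    # centre, confirming control > cancer)
    biomarker_bands: tuple[BandSpec, ...] = (
        BandSpec(1773.0, 6.0, 0.030, class_shift=4.5,
                 patient_sd=0.002, position_sd=0.2, width_sd=2.0),
        BandSpec(1773.0, 20.0, 0.022, class_delta=0.0125,
                 patient_sd=0.002, position_sd=0.5, width_sd=2.0),
        BandSpec(2093.0, 6.0, 0.030, class_shift=4.5,
                 patient_sd=0.0018, position_sd=0.2, width_sd=2.0),
        BandSpec(2093.0, 20.0, 0.020, class_delta=0.012,
                 patient_sd=0.0018, position_sd=0.5, width_sd=2.0),
    )
    noise_sd: float = 0.005              # per-scan white noise, AU
    baseline_offset_range: tuple[float, float] = (-0.002, 0.002)
    baseline_slope_range: tuple[float, float] = (-1e-6, 1e-6)  # AU per cm^-1
    fringe_amplitude: float = 0.006      # etalon-type baseline ripple, AU
    fringe_period_range: tuple[float, float] = (30.0, 45.0)  # cm^-1
    scatter_range: tuple[float, float] = (0.97, 1.03)
    seed: int = DEFAULT_SEED
    with_subtypes: bool = True

    def __post_init__(self) -> None:
        if self.n_control <= 0 or self.n_cancer <= 0 or self.replicates <= 0:
            raise ValueError("cohort counts must be positive")
        if self.scans <= 0:
            raise ValueError("scans must be positive")
        if self.with_subtypes and sum(SUBTYPE_COUNTS.values()) != self.n_cancer:
            object.__setattr__(self, "with_subtypes", False)

    @property
    def grid(self) -> WavenumberGrid:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return WavenumberGrid(np.linspace(self.grid_max, self.grid_min, n))

    @property
    def all_bands(self) -> tuple[BandSpec, ...]:
        return self.water_bands + self.solute_bands + self.biomarker_bands

    @property
    def replicate_noise_sd(self) -> float:
        """Effective white-noise sd after averaging ``scans`` scans."""
        return self.noise_sd / np.sqrt(self.scans)


def default_cohort_spec(**overrides) -> CohortSpec:
    """The shipped default cohort (the study conditions)."""
    return CohortSpec(**overrides)


def null_cohort(spec: CohortSpec | None = None) -> CohortSpec:
    """Same cohort with every class effect zeroed — the no-signal control."""
    spec = spec or CohortSpec()
    return replace(
        spec,
        biomarker_bands=tuple(
            replace(b, class_delta=0.0, class_shift=0.0)
            for b in spec.biomarker_bands
        ),
    )


@dataclass
class SyntheticCohort:
    """In-memory cohort: replicate spectra, metadata table, water reference."""

    spec: CohortSpec
    spectra: list[Spectrum]
    metadata: pd.DataFrame
    water: Spectrum


def _gaussian(grid: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - centre) / width) ** 2)


def generate_patient(spec: CohortSpec, label: int, patient_id: str,
                     rng: np.random.Generator) -> list[Spectrum]:
    """Simulate one patient's technical replicates.

    The per-band amplitude is drawn once per patient and shared by the
    replicates, which differ in baseline, scatter and noise.
    """
    grid = spec.grid
    v = grid.values
    v_mid = 0.5 * (spec.grid_max + spec.grid_min)

    shapes = np.vstack([
        _gaussian(
            v,
            b.centre + (-0.5 if label == 1 else 0.5) * b.class_shift
            + (rng.normal(0.0, b.position_sd) if b.position_sd > 0 else 0.0),
            max(1.0, b.width + (rng.normal(0.0, b.width_sd) if b.width_sd > 0 else 0.0)),
        )
        for b in spec.all_bands
    ])
    amps = np.array([
        b.amplitude - (b.class_delta if label == 1 else 0.0)
        + (rng.normal(0.0, b.patient_sd) if b.patient_sd > 0 else 0.0)
        for b in spec.all_bands
    ])
    signal = amps @ shapes

    replicates = []
    for rep in range(1, spec.replicates + 1):
        scatter = rng.uniform(*spec.scatter_range)
        offset = rng.uniform(*spec.baseline_offset_range)
        slope = rng.uniform(*spec.baseline_slope_range)
        period = rng.uniform(*spec.fringe_period_range)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        fringe = spec.fringe_amplitude * np.cos(2.0 * np.pi * v / period + phase)
        noise = rng.normal(0.0, spec.replicate_noise_sd, size=v.size)
        absorbance = (scatter * signal + offset + slope * (v - v_mid)
                      + fringe + noise)
        replicates.append(Spectrum(grid, absorbance, patient_id=patient_id,
                                   replicate=rep, label=label))
    return replicates


def _water_reference(spec: CohortSpec, rng: np.random.Generator) -> Spectrum:
    grid = spec.grid
    signal = sum(
        b.amplitude * _gaussian(grid.values, b.centre, b.width)
        for b in spec.water_bands
    )
    noise = rng.normal(0.0, spec.replicate_noise_sd, size=len(grid))
    return Spectrum(grid, signal + noise, patient_id="water", replicate=0)


def generate_cohort(spec: CohortSpec | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate the full cohort in randomised patient order.

    ``seed`` overrides ``spec.seed``; identical seeds give bit-identical
    cohorts.  Metadata columns: patient_id, replicate, label and (when
    enabled) the cancer subtype, with subtype counts matching the study.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    labels = np.array([0] * spec.n_control + [1] * spec.n_cancer)
    order = rng.permutation(labels.size)
    labels = labels[order]

    subtype_pool: list[str] = []
    if spec.with_subtypes:
        for name, count in SUBTYPE_COUNTS.items():
            subtype_pool.extend([name] * count)
        rng.shuffle(subtype_pool)

    water = _water_reference(spec, rng)

    spectra: list[Spectrum] = []
    meta_rows = []
    cancer_seen = 0
    width = len(str(labels.size))
    for i, label in enumerate(labels):
        pid = f"P{i + 1:0{width}d}"
        subtype = None
        if label == 1 and spec.with_subtypes:
            subtype = subtype_pool[cancer_seen]
            cancer_seen += 1
        reps = generate_patient(spec, int(label), pid, rng)
        spectra.extend(reps)
        for rep in reps:
            meta_rows.append({"patient_id": pid, "replicate": rep.replicate,
                              "label": int(label), "subtype": subtype})
    metadata = pd.DataFrame(meta_rows)
    return SyntheticCohort(spec=spec, spectra=spectra, metadata=metadata, water=water)


def cohort_to_set(cohort: SyntheticCohort, subtract_water: bool = True) -> SpectraSet:
    """Replicate-average and water-subtract into the analysis matrix."""
    background = cohort.water if subtract_water else None
    return assemble_set(cohort.spectra, cohort.metadata, background=background)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write .dpt files, water.dpt and metadata.csv (the on-disk workflow)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = cohort.metadata.copy()
    files = []
    for s in cohort.spectra:
        name = f"{s.patient_id}_r{s.replicate}.dpt"
        write_dpt(out / name, s)
        files.append(name)
    meta["file"] = files
    write_dpt(out / "water.dpt", cohort.water)
    meta.to_csv(out / "metadata.csv", index=False)
    return out
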