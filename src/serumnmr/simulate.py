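"""Synthetic serum 1H-NMR cohort generator.

Spectra are sums of Lorentzian multiplets rendered from the metabolite
library, with the nuisance structure the downstream analysis has to cope
with: per-subject concentration variability, class-dependent fold changes
on marker metabolites, per-sample dilution (log-normal), per-metabolite
chemical-shift jitter, linear baseline drift, additive Gaussian noise, a
broad residual-water hump near 4.70 ppm and broad lipid resonances near
0.88/1.28/5.27 ppm.  Ground truth (concentrations, dilutions, planted
shifts, marker variables) is stored on the dataset for oracle-based tests.

The generator is deterministic: identical (library, config) pairs produce
bit-identical datasets.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dataset import SpectraDataset, make_sample_table
from .library import DEFAULT_FREQUENCY_MHZ, MetaboliteLibrary, MultipletSpec

CLASS_CASE = "Schizophrenia"
CLASS_CONTROL = "Control"

#: broad background resonances: (center ppm, linewidth Hz, relative area)
WATER_HUMP = (4.70, 60.0, 40.0)
LIPID_HUMPS = ((0.88, 25.0, 6.0), (1.28, 25.0, 8.0), (5.27, 25.0, 3.0))
#: very broad protein/lipoprotein envelope dominating 1D serum spectra;
#: class-independent, with strong between-subject variability
PROTEIN_HUMPS = (
    (0.90, 120.0, 25.0),
    (1.30, 120.0, 30.0),
    (2.05, 150.0, 15.0),
    (2.80, 150.0, 8.0),
    (3.21, 180.0, 12.0),
    (3.80, 200.0, 10.0),
    (7.20, 300.0, 8.0),
)

#: line-position offsets (in units of J) and relative weights per pattern
_PATTERN_LINES = {
    "s": ((0.0,), (1.0,)),
    "d": ((-0.5, 0.5), (0.5, 0.5)),
    "t": ((-1.0, 0.0, 1.0), (0.25, 0.5, 0.25)),
    "q": ((-1.5, -0.5, 0.5, 1.5), (0.125, 0.375, 0.375, 0.125)),
}


def lorentzian(grid: np.ndarray, center: float, hwhm: float, area: float) -> np.ndarray:
    """Lorentzian line with unit-area normalization: area·(γ/π)/((x−x0)²+γ²)."""
    return area * (hwhm / np.pi) / ((grid - center) ** 2 + hwhm**2)


def render_multiplet(
    spec: MultipletSpec,
    grid: np.ndarray,
    linewidth: float,
    frequency: float = DEFAULT_FREQUENCY_MHZ,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Render one multiplet as a sum of Lorentzians on a ppm grid.

    Splitting patterns expand into the first-order line trees (d: two lines
    at ±J/2; t: 1:2:1 spaced J; q: 1:3:3:1 spaced J; dd: four equal lines
    from the two couplings).  Unresolved multiplets ('m') are rendered as a
    single line with 3x the linewidth.  Couplings are converted from Hz to
    ppm by J/frequency; the integrated area is amplitude x proton_count.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be a strictly increasing 1-D ppm vector")
    if linewidth <= 0:
        raise ValueError("linewidth must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")

    hwhm = 0.5 * linewidth / frequency  # ppm
    total_area = amplitude * spec.proton_count
    out = np.zeros_like(grid)
    if amplitude == 0:
        return out

    if spec.pattern == "m":
        out += lorentzian(grid, spec.center_shift, 3.0 * hwhm, total_area)
        return out

    if spec.pattern == "dd":
        j1, j2 = (j / frequency for j in spec.couplings)
        offsets = [s1 * j1 / 2 + s2 * j2 / 2 for s1 in (-1, 1) for s2 in (-1, 1)]
        weights = [0.25] * 4
    else:
        rel, weights = _PATTERN_LINES[spec.pattern]
        j = spec.couplings[0] / frequency if spec.couplings else 0.0
        offsets = [r * j for r in rel]
    for off, w in zip(offsets, weights):
        out += lorentzian(grid, spec.center_shift + off, hwhm, w * total_area)
    return out


def render_spectrum(
    library: MetaboliteLibrary,
    grid: np.ndarray,
    concentrations: dict[str, float],
    linewidth: float,
    shift_offsets: dict[str, float] | None = None,
) -> np.ndarray:
    """Noise-free spectrum for one sample: Σ_m c_m · multiplets(m)."""
    out = np.zeros_like(np.asarray(grid, dtype=float))
    shift_offsets = shift_offsets or {}
    for name, conc in concentrations.items():
        delta = shift_offsets.get(name, 0.0)
        for spec in library.multiplets(name):
            shifted = dataclasses.replace(spec, center_shift=spec.center_shift + delta)
            out += render_multiplet(
                shifted, grid, linewidth, library.spectrometer_frequency, conc
            )
    return out


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the emulated study: 51 case and 39 control subjects,
    three replicate spectra each, a 0-10 ppm grid of 16384 points (the
    32K-point/12 kHz acquisition at desk scale), ~1.2 Hz linewidth, and
    class-dependent fold changes on a subset of marker metabolites.
    """

    n_subjects_per_class: tuple[int, int] = (51, 39)  # (case, control)
    replicates_per_subject: int = 3
    grid: tuple[float, float, int] = (0.0, 10.0, 16384)
    linewidth: float = 2.0  # Hz; serum lines are macromolecule-broadened
    noise_sd: float = 0.5
    baseline_slope_range: tuple[float, float] = (-2.0, 2.0)  # intensity per ppm
    baseline_offset_range: tuple[float, float] = (-5.0, 5.0)
    # between-sample chemical-shift scatter; kept below the linewidth
    # (0.0015 ppm = 0.75 Hz at 500 MHz), as for pH-buffered serum
    shift_jitter_sd: float = 0.0015  # ppm, independent per metabolite
    # whole-spectrum referencing/field drift, shared by every resonance of a
    # sample; the first (global) alignment stage exists to remove this
    global_shift_sd: float = 0.002  # ppm
    dilution_log_sd: float = 0.15
    # default panel: 8 low-to-mid-abundance markers, so the changed signal
    # stays a minority of total intensity (the regime quotient
    # normalization assumes); high-abundance markers (e.g. glucose) can be
    # configured explicitly
    marker_fold_changes: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "lactate": 1.5,
            "alanine": 1.5,
            "glycine": 1.5,
            "glutamine": 1.5,
            "valine": 1.5,
            "isoleucine": 1.5,
            "citrate": 1.5,
            "3-hydroxybutyrate": 1.5,
        }
    )
    concentration_cv: float = 0.15
    include_water_hump: bool = True
    include_lipid_humps: bool = True
    # optional extra nuisance beyond the standard condition set: a broad
    # class-independent protein/lipoprotein envelope whose subject-level
    # amplitude variation deliberately stresses quotient normalization
    include_protein_background: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sd", "shift_jitter_sd", "global_shift_sd",
                     "dilution_log_sd", "concentration_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(f <= 0 for f in self.marker_fold_changes.values()):
            raise ValueError("fold changes must be positive")
        if self.grid[2] < 256:
            raise ValueError("grid must have at least 256 points")
        if self.replicates_per_subject < 1:
            raise ValueError("need at least one replicate per subject")

    def ppm_axis(self) -> np.ndarray:
        lo, hi, n = self.grid
        return np.linspace(lo, hi, n)


def simulate_cohort(
    library: MetaboliteLibrary, config: SimulationConfig
) -> SpectraDataset:
    """Simulate a two-class replicate cohort from the library.

    Per subject: concentrations drawn log-normally around library defaults
    with coefficient of variation ``concentration_cv``, multiplied by the
    marker fold changes for the case class.  Per sample: global log-normal
    dilution, per-metabolite shift jitter, linear baseline, Gaussian noise,
    optional water/lipid humps.  All randomness flows from ``config.seed``.
    """
    n_case, n_control = config.n_subjects_per_class
    rng = np.random.default_rng(config.seed)
    ppm = config.ppm_axis()
    names = library.metabolite_names

    subject_ids = [f"S{i:03d}" for i in range(1, n_case + 1)] + [
        f"C{i:03d}" for i in range(1, n_control + 1)
    ]
    class_labels = [CLASS_CASE] * n_case + [CLASS_CONTROL] * n_control
    samples = make_sample_table(subject_ids, class_labels, config.replicates_per_subject)

    # log-normal with exact coefficient of variation around the library mean
    cv = config.concentration_cv
    sigma_c = np.sqrt(np.log1p(cv**2))
    base = np.array([library.concentration(m) for m in names])

    conc_by_subject: dict[str, np.ndarray] = {}
    for subj, cls in zip(subject_ids, class_labels):
        mult = np.ones(len(names))
        if cls == CLASS_CASE:
            for i, m in enumerate(names):
                mult[i] = config.marker_fold_changes.get(m, 1.0)
        draw = rng.lognormal(mean=-0.5 * sigma_c**2, sigma=sigma_c, size=len(names))
        conc_by_subject[subj] = base * mult * draw

    n_total = len(samples)
    X = np.empty((n_total, ppm.size))
    dilutions = np.empty(n_total)
    shifts = np.zeros((n_total, len(names)))
    baselines = np.empty((n_total, 2))  # (slope, offset)

    bg_scale_by_subject = {
        subj: rng.lognormal(0.0, 0.25) for subj in subject_ids
    }
    # lipoprotein content is a subject property, constant across replicates
    lipid_scale_by_subject = {
        subj: rng.lognormal(0.0, 0.3) for subj in subject_ids
    }
    global_shifts = np.zeros(n_total)

    for row, rec in enumerate(samples.itertuples(index=False)):
        conc = dict(zip(names, conc_by_subject[rec.subject_id]))
        g = rng.normal(0.0, config.global_shift_sd) if config.global_shift_sd else 0.0
        global_shifts[row] = g
        jitter = g + rng.normal(0.0, config.shift_jitter_sd, size=len(names))
        shifts[row] = jitter
        spectrum = render_spectrum(
            library, ppm, conc, config.linewidth, dict(zip(names, jitter))
        )
        if config.include_protein_background:
            bg = bg_scale_by_subject[rec.subject_id]
            for c, lw, area in PROTEIN_HUMPS:
                spectrum += lorentzian(
                    ppm, c + g, 0.5 * lw / library.spectrometer_frequency,
                    area * bg,
                )
        if config.include_water_hump:
            # fixed amplitude: the hump exists for the water-window
            # exclusion to remove, and its wide tails should not act as an
            # extra normalization nuisance
            c, lw, area = WATER_HUMP
            spectrum += lorentzian(ppm, c, 0.5 * lw / library.spectrometer_frequency, area)
        if config.include_lipid_humps:
            lipid_scale = lipid_scale_by_subject[rec.subject_id]
            for c, lw, area in LIPID_HUMPS:
                spectrum += lorentzian(
                    ppm, c, 0.5 * lw / library.spectrometer_frequency,
                    area * lipid_scale,
                )
        dil = rng.lognormal(mean=0.0, sigma=config.dilution_log_sd) if config.dilution_log_sd else 1.0
        dilutions[row] = dil
        slope = rng.uniform(*config.baseline_slope_range)
        offset = rng.uniform(*config.baseline_offset_range)
        baselines[row] = (slope, offset)
        noise = rng.normal(0.0, config.noise_sd, size=ppm.size) if config.noise_sd else 0.0
        X[row] = dil * spectrum + slope * ppm + offset + noise

    truth = {
        "dilution_factors": dilutions,
        "shift_jitter": shifts,
        "global_shifts": global_shifts,
        "background_scales": bg_scale_by_subject,
        "baselines": baselines,
        "concentrations": conc_by_subject,
        "metabolite_names": names,
        "marker_metabolites": sorted(
            m for m, f in config.marker_fold_changes.items() if f != 1.0
        ),
        "marker_shifts": {
            m: library.shifts(m)
            for m in config.marker_fold_changes
            if config.marker_fold_changes[m] != 1.0
        },
        "linewidth_ppm": config.linewidth / library.spectrometer_frequency,
        "config": config,
    }
    ds = SpectraDataset(ppm=ppm, intensities=X, samples=samples, truth=truth)
    ds.log_step(
        "simulate",
        seed=config.seed,
        n_subjects_per_class=config.n_subjects_per_class,
        replicates=config.replicates_per_subject,
    )
    return ds
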