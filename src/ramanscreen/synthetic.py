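"""Synthetic Raman cohort generator.

Because no in vivo melanoma Raman dataset of this design is publicly
deposited, every downstream stage is exercised on simulated cohorts whose
statistical structure mirrors the clinical study: ~52 patients carrying 53
benign pigmented lesions (~158 measurements) and 7 melanomas
(~27 measurements), spectra on a 1980-point grid spanning 800–1790 cm⁻¹.

A spectrum is rendered as a non-negative mixture of eight tissue-constituent
basis spectra (lipids: triolein, ceramide; proteins: collagen, keratin,
elastin, melanin; DNA; water), each a sum of Gaussian bands at standard
Raman shifts, normalized to unit area. The class effect is carried by the
constituent weights: melanomas get more collagen and less triolein (a
reduced CH2/CH3 lipid band near 1440 cm⁻¹) plus a small shift of the
collagen Amide III band near 1250 cm⁻¹. On top of the mixture the generator
plants exactly the artifacts preprocessing must remove: a slowly varying
fifth-order polynomial fluorescence baseline, i.i.d. Gaussian noise, and
rare single-point cosmic-ray spikes.

Weights are hierarchical — drawn once per lesion around the class mean,
then jittered per measurement — so that repeated measurements of one lesion
co-vary, as repeated biopsies of one tumour do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset_io import Label, LesionRecord, SpectraDataset, SpectrumRecord, Stage
from .errors import ConfigError

__all__ = [
    "ConstituentBasis",
    "SyntheticConfig",
    "GroundTruth",
    "DEFAULT_BASES",
    "build_constituent_bases",
    "sample_lesion",
    "render_raw_measurement",
    "generate_cohort",
    "null_config",
]


@dataclass(frozen=True)
class ConstituentBasis:
    """A tissue constituent's Raman signature: Gaussian bands on the grid.

    ``peaks`` is a list of (center cm⁻¹, sigma cm⁻¹, relative amplitude ≥ 0).
    Rendered rows are non-negative and normalized to unit trapezoid area.
    """

    name: str
    peaks: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(tuple(p) for p in self.peaks))
        if not self.peaks:
            raise ConfigError(f"constituent {self.name!r}: empty peak list")
        for c, s, a in self.peaks:
            if not (700.0 <= c <= 1900.0):
                raise ConfigError(f"{self.name}: peak center {c} outside [700, 1900]")
            if s <= 0 or a < 0:
                raise ConfigError(f"{self.name}: invalid peak (sigma {s}, amplitude {a})")


# Band positions follow standard skin/tissue Raman assignments: CH2/CH3
# deformation ~1440–1450 (lipids), Amide III ~1245–1270 and 855/940
# (collagen), 1003 phenylalanine, Amide I ~1650–1665, broad melanin
# 1380/1580 and water OH-bend ~1640 bands.
DEFAULT_BASES: tuple[ConstituentBasis, ...] = (
    ConstituentBasis("collagen", ((855, 9, 0.7), (940, 9, 0.6), (1246, 12, 0.9),
                                  (1450, 12, 0.5), (1661, 14, 0.9))),
    ConstituentBasis("triolein", ((1080, 10, 0.4), (1267, 10, 0.5), (1301, 9, 0.8),
                                  (1440, 12, 1.0), (1654, 10, 0.6), (1747, 10, 0.3))),
    ConstituentBasis("ceramide", ((1062, 9, 0.5), (1128, 9, 0.5), (1296, 10, 0.7),
                                  (1441, 12, 0.9), (1650, 12, 0.4))),
    ConstituentBasis("keratin", ((1003, 6, 0.8), (1245, 14, 0.5), (1450, 12, 0.7),
                                 (1655, 13, 1.0))),
    ConstituentBasis("elastin", ((1004, 7, 0.4), (1104, 10, 0.3), (1254, 13, 0.6),
                                 (1450, 12, 0.7), (1664, 13, 0.8))),
    ConstituentBasis("melanin", ((1380, 40, 0.8), (1580, 40, 1.0))),
    ConstituentBasis("DNA", ((1094, 10, 0.6), (1340, 12, 0.5), (1578, 10, 0.7))),
    ConstituentBasis("water", ((1640, 45, 1.0),)),
)

CONSTITUENT_NAMES = tuple(b.name for b in DEFAULT_BASES)

# Mean mixing weights per class. Melanoma: collagen up, triolein down
# (reduced CH2/CH3 lipid contribution), slight melanin/DNA increase. The
# shifts are 1.3–2 lesion-level standard deviations at the default
# weight_cv, i.e. overlapping class distributions (a moderate effect), not
# perfect separation.
_PIGMENTED_MEANS = {
    "collagen": 1.0, "triolein": 1.0, "ceramide": 0.4, "keratin": 0.8,
    "elastin": 0.5, "melanin": 0.6, "DNA": 0.3, "water": 0.5,
}
_MELANOMA_MEANS = {
    "collagen": 1.2, "triolein": 0.7, "ceramide": 0.38, "keratin": 0.8,
    "elastin": 0.5, "melanin": 0.72, "DNA": 0.36, "water": 0.5,
}

# Fluorescence baseline coefficient ranges, orders 0..5, in the wavenumber
# coordinate rescaled to [-1, 1]. The constant term dominates (baseline
# several-fold above the ~0.005 mean Raman signal of a unit-area mixture).
_DEFAULT_BASELINE_RANGES = (
    (0.02, 0.05), (-0.010, 0.010), (-0.008, 0.008),
    (-0.006, 0.006), (-0.004, 0.004), (-0.003, 0.003),
)


@dataclass
class SyntheticConfig:
    """Cohort-level simulation parameters (defaults emulate the clinical study)."""

    n_pigmented_lesions: int = 53
    n_melanoma_lesions: int = 7
    n_patients: int = 52
    measurements_range: tuple[int, int] = (2, 6)
    #: per-class mean measurements per lesion; defaults hit the study's
    #: expected totals (158 over 53 pigmented, 27 over 7 melanoma lesions)
    mean_measurements: dict[str, float] = field(
        default_factory=lambda: {"pigmented": 158 / 53, "melanoma": 27 / 7}
    )
    grid_min: float = 800.0
    grid_max: float = 1790.0
    n_points: int = 1980
    bases: tuple[ConstituentBasis, ...] = DEFAULT_BASES
    class_weight_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "pigmented": dict(_PIGMENTED_MEANS),
            "melanoma": dict(_MELANOMA_MEANS),
        }
    )
    weight_cv: float = 0.25
    intra_lesion_cv: float = 0.10
    amideIII_shift: float = 10.0
    baseline_coeff_ranges: tuple[tuple[float, float], ...] = _DEFAULT_BASELINE_RANGES
    noise_sd: float = 4e-4
    cosmic_ray_rate: float = 0.3
    cosmic_ray_amplitude: tuple[float, float] = (5.0, 20.0)
    seed: int = 0

    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_min, self.grid_max, self.n_points)

    def validate(self) -> None:
        if min(self.n_pigmented_lesions, self.n_patients, self.n_points) <= 0:
            raise ConfigError("counts must be positive")
        if self.n_melanoma_lesions < 0:
            raise ConfigError("n_melanoma_lesions must be non-negative")
        n_lesions = self.n_pigmented_lesions + self.n_melanoma_lesions
        if n_lesions > 2 * self.n_patients:
            raise ConfigError(
                f"{n_lesions} lesions cannot be assigned to {self.n_patients} "
                "patients at a maximum of 2 lesions each"
            )
        lo, hi = self.measurements_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"invalid measurements_range {self.measurements_range}")
        if lo < 2:
            raise ConfigError("each lesion needs at least 2 measurements")
        if self.grid_min >= self.grid_max:
            raise ConfigError("grid_min must be below grid_max")
        for cls, means in self.class_weight_means.items():
            for name, w in means.items():
                if w < 0:
                    raise ConfigError(f"negative weight {name}={w} for class {cls}")
        if self.weight_cv < 0 or self.intra_lesion_cv < 0 or self.noise_sd < 0:
            raise ConfigError("dispersions and noise_sd must be non-negative")
        if self.cosmic_ray_rate < 0:
            raise ConfigError("cosmic_ray_rate must be non-negative")
        mel = self.class_weight_means.get("melanoma", {}).get("triolein")
        pig = self.class_weight_means.get("pigmented", {}).get("triolein")
        if mel is not None and pig is not None and not mel <= pig:
            raise ConfigError(
                "melanoma mean triolein weight must not exceed the pigmented "
                f"mean (got {mel} > {pig}); the planted effect direction is a "
                "reduced lipid contribution in melanoma"
            )


def null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A no-effect configuration: identical class means, no Amide III shift.

    Under this configuration the lesion labels are independent of the
    spectra by construction — the null hypothesis of the randomization test.
    """
    cfg = SyntheticConfig(seed=seed, **overrides)
    cfg.class_weight_means = {
        "pigmented": dict(_PIGMENTED_MEANS),
        "melanoma": dict(_PIGMENTED_MEANS),
    }
    cfg.amideIII_shift = 0.0
    return cfg


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    labels: dict[str, str] = field(default_factory=dict)
    lesion_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    lesion_shifts: dict[str, float] = field(default_factory=dict)
    measurement_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    baseline_coeffs: dict[str, list[float]] = field(default_factory=dict)
    spike_positions: dict[str, list[int]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def build_constituent_bases(
    grid: np.ndarray,
    bases: tuple[ConstituentBasis, ...] = DEFAULT_BASES,
    shift_collagen: float = 0.0,
) -> np.ndarray:
    """Render constituent bases on ``grid`` → (n_constituents, n_points).

    Each row is a sum of Gaussian bands, non-negative, normalized to unit
    trapezoid area. ``shift_collagen`` displaces collagen bands in the Amide
    III region (1230–1300 cm⁻¹) by that many cm⁻¹ (the melanoma signature).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size >= 2 and not np.all(np.diff(grid) > 0):
        raise ConfigError("grid must be strictly increasing")
    rows = []
    for basis in bases:
        row = np.zeros_like(grid)
        for center, sigma, amp in basis.peaks:
            if basis.name == "collagen" and 1230.0 <= center <= 1300.0:
                center = center + shift_collagen
            row += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
        area = np.trapezoid(row, grid)
        if area <= 0:
            raise ConfigError(f"constituent {basis.name!r} has zero area on this grid")
        rows.append(row / area)
    return np.vstack(rows)


def sample_lesion(
    label: Label,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    lesion_id: str = "L000",
    patient_id: str = "P000",
) -> tuple[LesionRecord, dict[str, float]]:
    """Draw one lesion: its measurement count and lesion-level weights.

    Weights are Gaussian around the class means with relative dispersion
    ``weight_cv``, truncated at zero.
    """
    cfg.validate()
    means = cfg.class_weight_means[label.value]
    weights = {
        name: max(0.0, rng.normal(mu, cfg.weight_cv * mu)) if mu > 0 else 0.0
        for name, mu in means.items()
    }
    lo, hi = cfg.measurements_range
    span = hi - lo
    target = cfg.mean_measurements.get(label.value, float(lo))
    p = 0.0 if span == 0 else min(1.0, max(0.0, (target - lo) / span))
    n_meas = int(lo + rng.binomial(span, p))
    record = LesionRecord(
        lesion_id=lesion_id,
        patient_id=patient_id,
        label=label,
        measurement_ids=tuple(f"{lesion_id}_m{i + 1}" for i in range(n_meas)),
    )
    return record, weights


def _draw_baseline(cfg: SyntheticConfig, grid: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw order-5 polynomial fluorescence baseline coefficients (in the
    grid coordinate rescaled to [-1, 1]) and evaluate; shifted so min ≥ 0."""
    coeffs = np.array([rng.uniform(lo, hi) for lo, hi in cfg.baseline_coeff_ranges])
    x = 2.0 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1.0
    baseline = np.polynomial.polynomial.polyval(x, coeffs)
    low = baseline.min()
    if low < 0:  # keep it an order-5 polynomial: shift the constant term
        coeffs[0] -= low
        baseline = baseline - low
    return baseline, coeffs


def render_raw_measurement(
    weights: dict[str, float],
    shift: float,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    measurement_id: str = "m1",
    lesion_id: str = "L000",
) -> SpectrumRecord:
    """Render one raw measurement from lesion-level weights."""
    record, _ = _render_with_truth(weights, shift, cfg, rng, measurement_id, lesion_id)
    return record


def _render_with_truth(weights, shift, cfg, rng, measurement_id, lesion_id):
    grid = cfg.grid()
    basis = build_constituent_bases(grid, cfg.bases, shift_collagen=shift)
    names = [b.name for b in cfg.bases]
    w = np.array([weights.get(n, 0.0) for n in names], dtype=float)
    if np.any(w < 0):
        raise ConfigError("constituent weights must be non-negative")
    # measurement-level biological jitter
    if cfg.intra_lesion_cv > 0:
        w = np.maximum(0.0, rng.normal(w, cfg.intra_lesion_cv * w))
    signal = w @ basis

    if any(hi != 0 or lo != 0 for lo, hi in cfg.baseline_coeff_ranges):
        baseline, coeffs = _draw_baseline(cfg, grid, rng)
    else:
        baseline, coeffs = np.zeros_like(grid), np.zeros(len(cfg.baseline_coeff_ranges))

    intensities = signal + baseline
    if cfg.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, cfg.noise_sd, size=grid.size)

    spikes: list[int] = []
    n_spikes = rng.poisson(cfg.cosmic_ray_rate) if cfg.cosmic_ray_rate > 0 else 0
    if n_spikes:
        scale = float(np.max(signal + baseline))
        positions = rng.integers(0, grid.size, size=n_spikes)
        lo_a, hi_a = cfg.cosmic_ray_amplitude
        for pos in positions:
            intensities[pos] += rng.uniform(lo_a, hi_a) * scale
            spikes.append(int(pos))

    record = SpectrumRecord(
        measurement_id=measurement_id,
        lesion_id=lesion_id,
        wavenumbers=grid,
        intensities=intensities,
        stage=Stage.RAW,
    )
    truth = {
        "weights": dict(zip(names, w.tolist())),
        "baseline_coeffs": coeffs.tolist(),
        "spikes": spikes,
    }
    return record, truth


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def _lesion_rng(seed: int, lesion_index: int) -> np.random.Generator:
    # one deterministic sub-stream per lesion index, so a single lesion can
    # be regenerated without replaying the whole cohort
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(lesion_index,)))


def generate_cohort(cfg: SyntheticConfig) -> tuple[SpectraDataset, GroundTruth]:
    """Generate a full raw cohort plus its ground truth.

    Deterministic given ``cfg.seed``. Lesion/label counts equal the config;
    patients are assigned so that a few carry two lesions when there are
    more lesions than patients.
    """
    cfg.validate()
    n_lesions = cfg.n_pigmented_lesions + cfg.n_melanoma_lesions
    root = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(2**20,)))

    labels = [Label.MELANOMA] * cfg.n_melanoma_lesions + [Label.PIGMENTED] * cfg.n_pigmented_lesions
    order = root.permutation(n_lesions)
    labels = [labels[i] for i in order]

    # patients: each lesion gets its own patient until patients run out,
    # then the remainder are second lesions on randomly chosen patients
    patient_ids = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    assignment = list(range(min(n_lesions, cfg.n_patients)))
    if n_lesions > cfg.n_patients:
        extra = root.choice(cfg.n_patients, size=n_lesions - cfg.n_patients, replace=False)
        assignment.extend(int(e) for e in extra)
    root.shuffle(assignment)

    spectra: list[SpectrumRecord] = []
    lesions: list[LesionRecord] = []
    truth = GroundTruth()
    for idx in range(n_lesions):
        rng = _lesion_rng(cfg.seed, idx)
        lesion_id = f"L{idx + 1:03d}"
        label = labels[idx]
        record, weights = sample_lesion(
            label, cfg, rng, lesion_id=lesion_id, patient_id=patient_ids[assignment[idx]]
        )
        shift = cfg.amideIII_shift if label is Label.MELANOMA else 0.0
        truth.labels[lesion_id] = label.value
        truth.lesion_weights[lesion_id] = dict(weights)
        truth.lesion_shifts[lesion_id] = shift
        for mid in record.measurement_ids:
            spec, mtruth = _render_with_truth(weights, shift, cfg, rng, mid, lesion_id)
            spectra.append(spec)
            truth.measurement_weights[mid] = mtruth["weights"]
            truth.baseline_coeffs[mid] = mtruth["baseline_coeffs"]
            truth.spike_positions[mid] = mtruth["spikes"]
        lesions.append(record)

    return SpectraDataset(spectra=spectra, lesions=lesions), truth
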