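"""Cohort data model and tabular I/O.

A cohort is a set of Raman measurements (one spectrum each) grouped into
lesions, which in turn belong to patients. Lesions — not measurements — are
the unit of diagnosis and of cross-validation: a lesion is biopsied or not,
however many spectra were taken on it.

On disk a cohort is two CSV files:

* a *wide* spectra table — header ``measurement_id`` followed by the
  wavenumber grid in cm⁻¹ (written with 4 decimals), one row per measurement;
* a lesion manifest with columns ``measurement_id, lesion_id, patient_id,
  label`` where label is ``melanoma`` or ``pigmented`` (case-insensitive).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, GridError

__all__ = [
    "Label",
    "Stage",
    "SpectrumRecord",
    "LesionRecord",
    "SpectraDataset",
    "read_spectra_table",
    "write_spectra_table",
    "validate_dataset",
]

#: Absolute tolerance on the unit trapezoid area of preprocessed spectra.
AREA_TOL = 1e-9

#: Fingerprint region retained after preprocessing, cm⁻¹.
FINGERPRINT_RANGE = (800.0, 1790.0)


class Label(enum.Enum):
    """Histopathology class of a lesion."""

    MELANOMA = "melanoma"
    PIGMENTED = "pigmented"

    @classmethod
    def parse(cls, text: str) -> "Label":
        try:
            return cls(str(text).strip().lower())
        except ValueError:
            raise FormatError(
                f"unknown lesion label {text!r}; expected 'melanoma' or 'pigmented'"
            ) from None


class Stage(enum.Enum):
    """Processing state of a spectrum."""

    RAW = "raw"
    PREPROCESSED = "preprocessed"


@dataclass(frozen=True)
class SpectrumRecord:
    """One Raman measurement: a wavenumber grid and intensities.

    Raw intensities are detector counts (arbitrary scale); preprocessed
    intensities are fluorescence-subtracted and scaled to unit area under
    the curve on the 800–1790 cm⁻¹ fingerprint region.
    """

    measurement_id: str
    lesion_id: str
    wavenumbers: np.ndarray
    intensities: np.ndarray
    stage: Stage = Stage.RAW

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", it)
        if wn.ndim != 1 or it.ndim != 1 or wn.shape != it.shape:
            raise GridError(
                f"{self.measurement_id}: wavenumbers and intensities must be "
                f"1-D and equal length, got {wn.shape} vs {it.shape}"
            )
        if wn.size >= 2 and not np.all(np.diff(wn) > 0):
            raise GridError(
                f"{self.measurement_id}: wavenumber grid is not strictly increasing"
            )

    def area(self) -> float:
        """Trapezoid area under the intensities."""
        return float(np.trapezoid(self.intensities, self.wavenumbers))

    def with_intensities(
        self, intensities: np.ndarray, stage: Stage | None = None
    ) -> "SpectrumRecord":
        return replace(
            self,
            intensities=np.asarray(intensities, dtype=float),
            stage=self.stage if stage is None else stage,
        )


@dataclass(frozen=True)
class LesionRecord:
    """One lesion: its patient, class label, and measurement ids."""

    lesion_id: str
    patient_id: str
    label: Label
    measurement_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurement_ids", tuple(self.measurement_ids))


@dataclass
class SpectraDataset:
    """A cohort: spectra plus the lesion manifest.

    Every measurement id must appear exactly once in the manifest and once in
    the spectra collection, and all spectra must share one wavenumber grid
    before any matrix-level analysis.
    """

    spectra: list[SpectrumRecord] = field(default_factory=list)
    lesions: list[LesionRecord] = field(default_factory=list)

    # -- convenience accessors -------------------------------------------

    def spectrum(self, measurement_id: str) -> SpectrumRecord:
        for s in self.spectra:
            if s.measurement_id == measurement_id:
                return s
        raise KeyError(measurement_id)

    def lesion(self, lesion_id: str) -> LesionRecord:
        for l in self.lesions:
            if l.lesion_id == lesion_id:
                return l
        raise KeyError(lesion_id)

    @property
    def lesion_ids(self) -> list[str]:
        return [l.lesion_id for l in self.lesions]

    def labels(self) -> dict[str, Label]:
        return {l.lesion_id: l.label for l in self.lesions}

    def n_measurements(self) -> int:
        return len(self.spectra)

    def grid(self) -> np.ndarray:
        """The shared wavenumber grid (raises GridError if grids differ)."""
        if not self.spectra:
            raise GridError("empty dataset has no grid")
        g0 = self.spectra[0].wavenumbers
        for s in self.spectra[1:]:
            if s.wavenumbers.shape != g0.shape or not np.array_equal(s.wavenumbers, g0):
                raise GridError(
                    f"grids differ between {self.spectra[0].measurement_id} "
                    f"and {s.measurement_id}"
                )
        return g0

    def intensity_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Stack intensities into (n_measurements, n_wavenumbers); also the
        row order of measurement ids."""
        self.grid()
        ids = [s.measurement_id for s in self.spectra]
        return np.vstack([s.intensities for s in self.spectra]), ids

    def class_counts(self) -> dict[Label, int]:
        counts = {Label.MELANOMA: 0, Label.PIGMENTED: 0}
        for l in self.lesions:
            counts[l.label] += 1
        return counts


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ("measurement_id", "lesion_id", "patient_id", "label")


def read_spectra_table(spectra_path, manifest_path) -> SpectraDataset:
    """Read a cohort from a wide spectra CSV and a lesion manifest CSV.

    Raises FormatError for malformed files, ConsistencyError when the two
    files disagree about which measurements exist, GridError for a
    non-monotone wavenumber header.
    """
    spectra_df = pd.read_csv(spectra_path, dtype={0: str})
    if spectra_df.columns[0] != "measurement_id":
        raise FormatError(
            f"{spectra_path}: first column must be 'measurement_id', "
            f"got {spectra_df.columns[0]!r}"
        )
    try:
        grid = np.array([float(c) for c in spectra_df.columns[1:]])
    except ValueError as exc:
        raise FormatError(f"{spectra_path}: non-numeric wavenumber column: {exc}") from None
    if grid.size >= 2 and not np.all(np.diff(grid) > 0):
        raise GridError(f"{spectra_path}: wavenumber header is not strictly increasing")

    manifest_df = pd.read_csv(manifest_path, dtype=str)
    for col in _MANIFEST_COLUMNS:
        if col not in manifest_df.columns:
            raise FormatError(f"{manifest_path}: missing required column {col!r}")

    meas_to_lesion = dict(zip(manifest_df["measurement_id"], manifest_df["lesion_id"]))
    spectra_ids = list(spectra_df["measurement_id"])

    only_in_spectra = sorted(set(spectra_ids) - set(meas_to_lesion))
    only_in_manifest = sorted(set(meas_to_lesion) - set(spectra_ids))
    if only_in_spectra or only_in_manifest:
        raise ConsistencyError(
            "measurement ids disagree between files: "
            f"only in spectra table: {only_in_spectra}; "
            f"only in manifest: {only_in_manifest}"
        )

    values = spectra_df.iloc[:, 1:].to_numpy(dtype=float)
    spectra = [
        SpectrumRecord(
            measurement_id=mid,
            lesion_id=meas_to_lesion[mid],
            wavenumbers=grid,
            intensities=values[i],
        )
        for i, mid in enumerate(spectra_ids)
    ]

    lesions: list[LesionRecord] = []
    for lesion_id, group in manifest_df.groupby("lesion_id", sort=False):
        patients = group["patient_id"].unique()
        labels = {Label.parse(t) for t in group["label"]}
        if len(patients) != 1:
            raise ConsistencyError(
                f"lesion {lesion_id!r} mapped to multiple patients: {sorted(patients)}"
            )
        if len(labels) != 1:
            raise ConsistencyError(f"lesion {lesion_id!r} has conflicting labels")
        lesions.append(
            LesionRecord(
                lesion_id=str(lesion_id),
                patient_id=str(patients[0]),
                label=labels.pop(),
                measurement_ids=tuple(group["measurement_id"]),
            )
        )
    return SpectraDataset(spectra=spectra, lesions=lesions)


def write_spectra_table(ds: SpectraDataset, spectra_path, manifest_path) -> None:
    """Write a cohort to the documented CSV pair.

    Intensities are emitted at full double precision (repr round-trip), the
    wavenumber header with 4 decimals; ``read_spectra_table`` recovers the
    dataset with intensities equal within 1e-12.
    """
    if ds.spectra:
        grid = ds.grid()  # raises GridError on mixed grids
        header = ["measurement_id"] + [f"{w:.4f}" for w in grid]
        matrix, ids = ds.intensity_matrix()
        df = pd.DataFrame(matrix, columns=header[1:])
        df.insert(0, "measurement_id", ids)
    else:
        df = pd.DataFrame(columns=["measurement_id"])
    df.to_csv(spectra_path, index=False, float_format="%.17g")

    rows = [
        {
            "measurement_id": mid,
            "lesion_id": lesion.lesion_id,
            "patient_id": lesion.patient_id,
            "label": lesion.label.value,
        }
        for lesion in ds.lesions
        for mid in lesion.measurement_ids
    ]
    pd.DataFrame(rows, columns=list(_MANIFEST_COLUMNS)).to_csv(manifest_path, index=False)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_dataset(ds: SpectraDataset) -> list[str]:
    """Check every dataset invariant; return human-readable violations.

    Never raises: an empty return value means the dataset is valid.
    """
    violations: list[str] = []

    manifest_ids: list[str] = []
    for lesion in ds.lesions:
        if not lesion.measurement_ids:
            violations.append(f"lesion {lesion.lesion_id}: empty measurement list")
        manifest_ids.extend(lesion.measurement_ids)

    if len(set(manifest_ids)) != len(manifest_ids):
        dupes = sorted({m for m in manifest_ids if manifest_ids.count(m) > 1})
        violations.append(f"duplicate measurement ids in manifest: {dupes}")

    spectra_ids = [s.measurement_id for s in ds.spectra]
    if len(set(spectra_ids)) != len(spectra_ids):
        dupes = sorted({m for m in spectra_ids if spectra_ids.count(m) > 1})
        violations.append(f"duplicate measurement ids in spectra: {dupes}")

    missing = sorted(set(manifest_ids) - set(spectra_ids))
    extra = sorted(set(spectra_ids) - set(manifest_ids))
    if missing:
        violations.append(f"manifest measurements missing from spectra: {missing}")
    if extra:
        violations.append(f"spectra not referenced by any lesion: {extra}")

    if ds.spectra:
        g0 = ds.spectra[0].wavenumbers
        ref_id = ds.spectra[0].measurement_id
        for s in ds.spectra[1:]:
            if s.wavenumbers.shape != g0.shape or not np.array_equal(s.wavenumbers, g0):
                violations.append(
                    f"grid mismatch between measurements {ref_id} and {s.measurement_id}"
                )

    lo, hi = FINGERPRINT_RANGE
    for s in ds.spectra:
        if s.stage is Stage.PREPROCESSED:
            if s.wavenumbers.size and (
                s.wavenumbers[0] < lo - 1e-9 or s.wavenumbers[-1] > hi + 1e-9
            ):
                violations.append(
                    f"measurement {s.measurement_id}: preprocessed grid outside "
                    f"[{lo}, {hi}] cm⁻¹"
                )
            if abs(s.area() - 1.0) > AREA_TOL:
                violations.append(
                    f"measurement {s.measurement_id}: preprocessed area "
                    f"{s.area():.3e} != 1"
                )
    return violations
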