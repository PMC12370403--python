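"""Synthetic multi-center mammography exposure cohorts with a known DRL surface.

The generator emulates the structure of a national screening dose survey:
nine centers of very different sizes, compressed breast thickness roughly
truncated-normal around 58 ± 12 mm, and AGD rising steeply with CBT. Each
examination contributes four records (CC/MLO × L/R); the two views of one
breast share a CBT draw. Doses are generated as

    AGD = truth(view, CBT) × center_factor × lognormal noise (median 1),

so the per-center median AGD equals truth × center_factor analytically and
the implied 75th-percentile-of-center-medians DRL curve is available in
closed form for end-to-end recovery checks. A configurable fraction of exams
is contaminated with rule-violating exposure values to exercise the
exclusion filter. The model is statistical, not dosimetric: no target/filter
physics, no Dance/Wu conversion factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .curves import FAMILIES
from .records import CohortTable, FIELDS

#: Per-center examination counts of a large nine-center screening survey.
DEFAULT_EXAMS_PER_CENTER: tuple[int, ...] = (
    38028, 31092, 24000, 60899, 15584, 16321, 628, 493, 660,
)

#: Bi-exponential ground-truth CC median-dose curve, rate form
#: a·exp(b·t) + c·exp(d·t) with t in mm (amplitudes mGy).
DEFAULT_TRUTH_CC: tuple[float, float, float, float] = (
    0.94, 1.0 / 118.65, 7.30e-4, 1.0 / 15.85,
)

_CONTAMINATION_KINDS = ("cf_zero", "cf_high", "low_mas", "zero_kvp", "cbt_high")

_VENDORS = (
    ("VendorA MammoUnit", "VendorA", "W", "Rh"),
    ("VendorB DigitalMammo", "VendorB", "W", "Ag"),
    ("VendorC ScreenStation", "VendorC", "Mo", "Mo"),
)


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_centers: int = 9
    n_exams_per_center: tuple[int, ...] = DEFAULT_EXAMS_PER_CENTER
    size_factor: float = 1.0
    cbt_mean: float = 58.0
    cbt_sd: float = 12.0
    cbt_bounds: tuple[float, float] = (13.0, 100.0)
    age_mean: float = 50.0
    age_sd: float = 8.0
    age_bounds: tuple[float, float] = (30.0, 90.0)
    truth_cc: tuple[float, float, float, float] = DEFAULT_TRUTH_CC
    mlo_factor: float = 1.12
    center_log_sd: float = 0.10
    record_log_sd: float = 0.25
    contamination: float = 0.01
    cbt_jitter_sd: float = 0.0  # per-view CBT jitter, mm (0: views share the draw)
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_centers < 1:
            problems.append("n_centers must be >= 1")
        if len(self.n_exams_per_center) != self.n_centers:
            problems.append("n_exams_per_center length must equal n_centers")
        for name in ("cbt_sd", "age_sd", "center_log_sd", "record_log_sd"):
            if getattr(self, name) <= 0 and name in ("cbt_sd", "age_sd"):
                problems.append(f"{name} must be > 0")
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        for name in ("cbt_bounds", "age_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                problems.append(f"{name} must be ordered")
        if not 0 <= self.contamination <= 0.5:
            problems.append("contamination must be in [0, 0.5]")
        if self.size_factor <= 0:
            problems.append("size_factor must be > 0")
        if problems:
            raise ValueError("invalid SynthConfig: " + "; ".join(problems))

    def exam_counts(self) -> list[int]:
        return [max(1, int(round(n * self.size_factor))) for n in self.n_exams_per_center]


@dataclass
class GroundTruth:
    """The generative median-dose surface and its implied DRL curve."""

    truth_cc: tuple[float, float, float, float]
    mlo_factor: float
    center_factors: dict[str, float]

    def median_curve(self, view: str, cbt) -> np.ndarray:
        base = FAMILIES["exp2"](np.asarray(cbt, dtype=float), np.asarray(self.truth_cc))
        return base * (self.mlo_factor if view == "MLO" else 1.0)

    def drl_factor(self) -> float:
        """75th percentile (linear interpolation) of the center factors."""
        return float(np.percentile(list(self.center_factors.values()), 75))


def analytic_drl(truth: GroundTruth, view: str, cbt) -> np.ndarray | float:
    """Closed-form DRL implied by the generative model (no sampling).

    With multiplicative median-1 noise, each center's median AGD at a given
    CBT is truth × its factor, so the 75th-percentile-of-medians DRL is
    truth × the 75th percentile of the factors.
    """
    val = truth.median_curve(view, cbt) * truth.drl_factor()
    return float(val) if np.ndim(cbt) == 0 else val


def _truncnorm(rng: np.random.Generator, mean, sd, bounds, size) -> np.ndarray:
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(cfg: SynthConfig) -> tuple[CohortTable, GroundTruth]:
    """Generate a multi-center cohort and its ground truth, deterministically.

    Each exam yields 4 records (CC/MLO × L/R); each breast's CC and MLO
    records share one CBT draw (plus optional jitter). A ``contamination``
    fraction of exams receives one rule-violating record, with the violation
    type drawn uniformly over zero/extreme compression force, sub-threshold
    mAs, zero kVp, and out-of-range CBT.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = cfg.exam_counts()
    center_ids = [f"C{i + 1}" for i in range(cfg.n_centers)]
    center_factors = {
        c: float(np.exp(rng.normal(0.0, cfg.center_log_sd))) for c in center_ids
    }
    truth = GroundTruth(
        truth_cc=cfg.truth_cc, mlo_factor=cfg.mlo_factor, center_factors=center_factors
    )

    frames = []
    for c, n_exams in zip(center_ids, counts):
        n_breasts = 2 * n_exams
        cbt_breast = _truncnorm(rng, cfg.cbt_mean, cfg.cbt_sd, cfg.cbt_bounds, n_breasts)
        age = np.round(_truncnorm(rng, cfg.age_mean, cfg.age_sd, cfg.age_bounds, n_exams))
        vendor = _VENDORS[(center_ids.index(c)) % len(_VENDORS)]

        # order: exam-major, then (L-CC, L-MLO, R-CC, R-MLO)
        exam_idx = np.repeat(np.arange(n_exams), 4)
        breast_idx = 2 * np.repeat(np.arange(n_exams), 4) + np.tile([0, 0, 1, 1], n_exams)
        view = np.tile(np.array(["CC", "MLO"]), 2 * n_exams)
        lat = np.tile(np.array(["L", "L", "R", "R"]), n_exams)
        cbt = cbt_breast[breast_idx]
        if cfg.cbt_jitter_sd > 0:
            cbt = np.clip(
                cbt + rng.normal(0, cfg.cbt_jitter_sd, size=len(cbt)), *cfg.cbt_bounds
            )
        base = FAMILIES["exp2"](cbt, np.asarray(cfg.truth_cc))
        base = np.where(view == "MLO", base * cfg.mlo_factor, base)
        noise = np.exp(rng.normal(0.0, cfg.record_log_sd, size=len(cbt)))
        agd = base * center_factors[c] * noise

        mas = np.clip(rng.normal(74, 31, size=len(cbt)), 11, 404)
        kvp = np.clip(np.round(rng.normal(29, 1, size=len(cbt))), 23, 40)
        cf = np.clip(rng.normal(135, 37, size=len(cbt)), 14, 200)

        df = pd.DataFrame(
            {
                "center_id": c,
                "exam_id": [f"{c}-E{i:06d}" for i in exam_idx],
                "patient_age": age[exam_idx],
                "view": view,
                "laterality": lat,
                "cbt": cbt,
                "mas": mas,
                "kvp": kvp,
                "compression_force": cf,
                "implant_present": False,
                "agd": agd,
                "exposure_control_mode": "AUTOMATIC",
                "anode_target": vendor[2],
                "filter_material": vendor[3],
                "manufacturer": vendor[1],
                "model_name": vendor[0],
            }
        )

        if cfg.contamination > 0:
            hit_exams = np.nonzero(rng.random(n_exams) < cfg.contamination)[0]
            for e in hit_exams:
                row = 4 * e + rng.integers(0, 4)
                kind = _CONTAMINATION_KINDS[rng.integers(0, len(_CONTAMINATION_KINDS))]
                if kind == "cf_zero":
                    df.loc[row, "compression_force"] = 0.0
                elif kind == "cf_high":
                    df.loc[row, "compression_force"] = float(rng.uniform(201, 300))
                elif kind == "low_mas":
                    df.loc[row, "mas"] = float(rng.uniform(0, 9.5))
                elif kind == "zero_kvp":
                    df.loc[row, "kvp"] = 0.0
                else:
                    df.loc[row, "cbt"] = float(rng.uniform(101, 140))
        frames.append(df)

    df = pd.concat(frames, ignore_index=True)[list(FIELDS)]
    table = CohortTable(
        df,
        provenance=f"synthetic: seed={cfg.seed}, exams={sum(counts)}, "
        f"contamination={cfg.contamination}",
    )
    return table, truth


def write_dicom_fixtures(table: CohortTable, out_dir: str | Path, limit: int | None = None) -> list[Path]:
    """Write header-only DICOM files for the first ``limit`` records.

    Organ dose is stored in dGy per the DICOM attribute definition. Intended
    for testing DICOM extraction without patient data; files carry no pixel
    data.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    rows = table.df if limit is None else table.df.head(limit)
    for i, row in rows.iterrows():
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.DigitalMammographyXRayImageStorageForPresentation
        meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[str(i)])
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.InstitutionName = row["center_id"]
        ds.AccessionNumber = str(row["exam_id"])[:16]
        ds.PatientID = str(row["exam_id"])[:16]
        ds.PatientAge = f"{int(row['patient_age']):03d}Y" if pd.notna(row["patient_age"]) else ""
        ds.ViewPosition = row["view"]
        ds.ImageLaterality = row["laterality"]
        ds.BodyPartThickness = float(row["cbt"])
        ds.Exposure = int(round(row["mas"])) if pd.notna(row["mas"]) else None
        ds.KVP = float(row["kvp"]) if pd.notna(row["kvp"]) else None
        ds.CompressionForce = float(row["compression_force"]) if pd.notna(row["compression_force"]) else None
        ds.BreastImplantPresent = "YES" if row["implant_present"] else "NO"
        ds.OrganDose = float(row["agd"]) / 100.0  # mGy -> dGy
        ds.ExposureControlMode = row["exposure_control_mode"]
        ds.AnodeTargetMaterial = str(row["anode_target"]).upper()  # CS VR: uppercase
        ds.FilterMaterial = str(row["filter_material"]).upper()
        ds.Manufacturer = row["manufacturer"]
        ds.ManufacturerModelName = row["model_name"]
        path = out_dir / f"rec{i:06d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
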