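"""Synthetic whole-body scintigram phantoms and clinical cohorts.

No public bone-scintigraphy dataset with recurrence labels exists, so this
module generates one at any scale: a parametric whole-body silhouette
(composed ellipses and bars) rendered as expected tracer counts, focal
Gaussian "hot-spot" lesions, an optional off-body catheter streak touching
the image border, and Poisson count noise.  A clinical cohort is drawn
from distributions shaped like a real localized / locally-advanced
prostate-cancer population, with the recurrence label generated by a
logistic model on the clinical covariates plus an unexplained latent term.

The same latent risk that drives the label also scales the expected
number of focal lesions (``image_coupling``), so image texture carries
label signal beyond the clinical features — the property the downstream
model comparison exercises.  Every generated quantity is recorded (lesion
ledger, latent risks), so tests can check the pipeline against the
generator's own bookkeeping.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.special import expit

from .segmentation import RawScintigram

log = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "SyntheticPatient",
    "ScintigramPair",
    "DEFAULT_CLINICAL_EFFECTS",
    "simulate_cohort",
    "simulate_scintigram_pair",
    "render_cohort_images",
    "cohort_to_frame",
    "write_fixture_set",
    "read_fixture_set",
]

#: Log-odds coefficients of the latent recurrence risk, one per centered
#: covariate transform.  Directions follow the clinical picture: recurrence
#: is more likely with advanced T stage, nodal involvement, high initial
#: PSA, high Gleason primary pattern and prostatectomy as index treatment,
#: and less likely when radiotherapy was the index treatment.
DEFAULT_CLINICAL_EFFECTS = {
    "t_stage_ge3": 1.1,
    "n_stage": 0.6,
    "log_psa_sd": 0.55,
    "gleason_primary": 0.8,
    "rp": 0.9,
    "rt": -0.7,
}

T_STAGES = ("T1", "T2", "T3", "T4")
GRADE_GROUPS = ("I", "II", "III", "IV", "V")
RISK_CLASSES = ("low", "intermediate", "high")

CLINICAL_COLUMNS = (
    "patient_id",
    "age",
    "initial_psa",
    "gleason_primary",
    "gleason_secondary",
    "grade_group",
    "t_stage",
    "n_stage",
    "risk_class",
    "rp",
    "rt",
    "adt",
    "hifu",
    "cryotherapy",
    "active_surveillance",
    "diabetes",
    "chronic_pulmonary_disease",
    "cerebrovascular_disease",
    "peptic_ulcer_disease",
    "label",
)


class ConfigurationError(ValueError):
    """Invalid generator specification."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of one synthetic scintigram view.

    ``background_level`` must lie below the raw-count mask threshold of 2
    while ``body_level`` must lie at or above it, so the thresholding
    stage of the segmentation pipeline is well posed.  Pixel values are
    Poisson counts on the expected-count image.
    """

    rows: int = 1024
    cols: int = 256
    background_level: float = 0.3
    body_level: float = 40.0
    lesion_count_mean: float = 2.5
    lesion_intensity: float = 3.0
    catheter_probability: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.rows < 64 or self.cols < 24:
            raise ConfigurationError(
                "geometry too small to render the body silhouette "
                f"(need rows >= 64, cols >= 24; got {self.rows} x {self.cols})"
            )
        if not (0 <= self.background_level < 2.0 <= self.body_level):
            raise ConfigurationError(
                "need background_level < 2 <= body_level so the raw-count "
                "threshold separates body from background"
            )
        if self.lesion_count_mean < 0 or self.lesion_intensity < 1:
            raise ConfigurationError("lesion parameters out of range")
        if not 0 <= self.catheter_probability <= 1:
            raise ConfigurationError("catheter_probability must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Size, prevalence and effect structure of a synthetic cohort.

    ``clinical_effects`` are log-odds coefficients on centered covariate
    transforms; ``latent_noise_sd`` is the standard deviation of the
    unexplained risk term shared between the label and the images;
    ``image_coupling`` scales how strongly that latent risk drives the
    expected lesion count.
    """

    n_patients: int = 354
    prevalence: float = 0.2853
    clinical_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_EFFECTS)
    )
    image_coupling: float = 1.0
    latent_noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ConfigurationError("prevalence must lie strictly inside (0, 1)")
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        unknown = set(self.clinical_effects) - set(DEFAULT_CLINICAL_EFFECTS)
        if unknown:
            raise ConfigurationError(f"unknown clinical effects: {sorted(unknown)}")
        if self.latent_noise_sd < 0:
            raise ConfigurationError("latent_noise_sd must be >= 0")
        if (
            self.image_coupling > 0
            and not any(self.clinical_effects.values())
            and self.latent_noise_sd == 0
        ):
            raise ConfigurationError(
                "image_coupling > 0 requires a nonzero effect or latent noise"
            )


@dataclass
class ScintigramPair:
    """Both rendered views of one patient, with ground truth."""

    anterior: RawScintigram
    posterior: RawScintigram
    mask_anterior: np.ndarray
    mask_posterior: np.ndarray
    ledger: dict


@dataclass
class SyntheticPatient:
    patient_id: str
    clinical: dict
    label: int
    latent_risk: float
    images: ScintigramPair | None = None


@lru_cache(maxsize=8)
def _silhouette(rows: int, cols: int) -> np.ndarray:
    """Parametric whole-body silhouette on a rows x cols grid.

    Head, neck, torso, pelvis, arms and legs composed from ellipses and
    bars in normalized coordinates; verified to form a single 4-connected
    component.
    """
    yy = (np.arange(rows)[:, None] + 0.5) / rows
    xx = (np.arange(cols)[None, :] + 0.5) / cols

    def ellipse(cy, cx, ry, rx):
        return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    def bar(y0, y1, x0, x1):
        return (yy >= y0) & (yy <= y1) & (xx >= x0) & (xx <= x1)

    body = (
        ellipse(0.08, 0.50, 0.055, 0.16)      # head
        | bar(0.12, 0.17, 0.42, 0.58)         # neck
        | ellipse(0.30, 0.50, 0.16, 0.30)     # torso
        | ellipse(0.47, 0.50, 0.08, 0.26)     # pelvis
        | ellipse(0.30, 0.17, 0.15, 0.10)     # left arm
        | ellipse(0.30, 0.83, 0.15, 0.10)     # right arm
        | bar(0.50, 0.93, 0.28, 0.44)         # left leg
        | bar(0.50, 0.93, 0.56, 0.72)         # right leg
    )
    _, n = ndimage.label(body, structure=ndimage.generate_binary_structure(2, 1))
    if n != 1:
        raise ConfigurationError(
            f"geometry {rows} x {cols} renders a disconnected silhouette"
        )
    return body


def _isup_grade_group(primary: int, secondary: int) -> str:
    total = primary + secondary
    if total <= 6:
        return "I"
    if total == 7:
        return "II" if primary == 3 else "III"
    if total == 8:
        return "IV"
    return "V"


def _risk_class(psa: float, grade_group: str, t_stage: str) -> str:
    # Simplified three-tier rule in the spirit of D'Amico stratification.
    if psa > 20 or grade_group in ("IV", "V") or t_stage in ("T3", "T4"):
        return "high"
    if psa < 10 and grade_group == "I" and t_stage == "T1":
        return "low"
    return "intermediate"


def _draw_clinical(rng: np.random.Generator) -> dict:
    age = float(np.clip(np.round(rng.normal(70.0, 7.5), 1), 45.0, 92.0))
    log_psa = rng.normal(np.log(11.0), 0.55)
    psa = float(np.clip(np.round(np.exp(log_psa), 2), 0.5, 250.0))
    gleason_primary = int(rng.choice((2, 3, 4, 5), p=(0.02, 0.31, 0.61, 0.06)))
    gleason_secondary = int(rng.choice((2, 3, 4, 5), p=(0.02, 0.35, 0.50, 0.13)))
    grade_group = _isup_grade_group(gleason_primary, gleason_secondary)
    t_stage = str(rng.choice(T_STAGES, p=(0.10, 0.54, 0.33, 0.03)))
    n_stage = "N1" if rng.random() < (0.05 + 0.15 * (t_stage in ("T3", "T4"))) else "N0"
    rp = bool(rng.random() < 0.62)
    rt = bool(rng.random() < (0.12 if rp else 0.65))
    adt = bool(rng.random() < 0.15)
    hifu = bool((not rp) and rng.random() < 0.01)
    cryo = bool((not rp) and rng.random() < 0.02)
    surveillance = not (rp or rt or adt or hifu or cryo)
    return {
        "age": age,
        "initial_psa": psa,
        "gleason_primary": gleason_primary,
        "gleason_secondary": gleason_secondary,
        "grade_group": grade_group,
        "t_stage": t_stage,
        "n_stage": n_stage,
        "risk_class": _risk_class(psa, grade_group, t_stage),
        "rp": rp,
        "rt": rt,
        "adt": adt,
        "hifu": hifu,
        "cryotherapy": cryo,
        "active_surveillance": surveillance,
        "diabetes": bool(rng.random() < 0.16),
        "chronic_pulmonary_disease": bool(rng.random() < 0.14),
        "cerebrovascular_disease": bool(rng.random() < 0.13),
        "peptic_ulcer_disease": bool(rng.random() < 0.21),
    }


def _covariates(record: dict) -> dict:
    """Centered covariate transforms entering the latent risk."""
    return {
        "t_stage_ge3": 1.0 if record["t_stage"] in ("T3", "T4") else 0.0,
        "n_stage": 1.0 if record["n_stage"] == "N1" else 0.0,
        "log_psa_sd": (np.log(record["initial_psa"]) - np.log(11.0)) / 0.55,
        "gleason_primary": record["gleason_primary"] - 3.5,
        "rp": (1.0 if record["rp"] else 0.0) - 0.5,
        "rt": (1.0 if record["rt"] else 0.0) - 0.5,
    }


def simulate_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Draw clinical records, latent risks and recurrence labels.

    The label is Bernoulli with ``P = expit(alpha + latent_risk)`` where
    ``latent_risk`` is the clinical linear predictor plus Gaussian noise
    and the intercept ``alpha`` is solved so the expected prevalence of
    the realized cohort equals ``spec.prevalence``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    records = [_draw_clinical(rng) for _ in range(spec.n_patients)]
    eta = np.array(
        [
            sum(
                spec.clinical_effects.get(k, 0.0) * v
                for k, v in _covariates(r).items()
            )
            for r in records
        ]
    )
    latent = eta + rng.normal(0.0, spec.latent_noise_sd, size=spec.n_patients)

    def mean_prob(alpha):
        return expit(alpha + latent).mean() - spec.prevalence

    alpha = brentq(mean_prob, -30.0, 30.0)
    labels = rng.binomial(1, expit(alpha + latent))

    patients = []
    width = max(4, len(str(spec.n_patients)))
    for i, rec in enumerate(records):
        patients.append(
            SyntheticPatient(
                patient_id=f"P{i + 1:0{width}d}",
                clinical=rec,
                label=int(labels[i]),
                latent_risk=float(latent[i]),
            )
        )
    return patients


def _patient_rng(spec: PhantomSpec, patient_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec.seed, patient_index)))


def simulate_scintigram_pair(
    patient: SyntheticPatient,
    spec: PhantomSpec,
    image_coupling: float = 1.0,
    patient_index: int | None = None,
) -> ScintigramPair:
    """Render one patient's anterior/posterior count images.

    The expected lesion count is ``lesion_count_mean *
    exp(0.4 * image_coupling * latent_risk)`` (clipped), so lesion burden
    rises monotonically with latent risk when coupling is positive.
    Lesions appear at mirrored positions in the two views; both views get
    independent Poisson noise.  The ground-truth mask is the noise-free
    silhouette; a catheter streak, when present, lies off-body and
    touches the bottom image border.
    """
    if patient_index is None:
        patient_index = int(patient.patient_id.lstrip("P"))
    rng = _patient_rng(spec, patient_index)
    body = _silhouette(spec.rows, spec.cols)
    expected = np.where(body, spec.body_level, spec.background_level).astype(np.float64)

    rate = spec.lesion_count_mean * np.exp(
        0.4 * image_coupling * patient.latent_risk
    )
    rate = float(np.clip(rate, 0.0, 25.0))
    n_lesions = int(rng.poisson(rate))

    body_idx = np.argwhere(body)
    ledger: dict = {"n_lesions": n_lesions, "lesions": [], "catheter": None}
    rr = np.arange(spec.rows)[:, None]
    cc = np.arange(spec.cols)[None, :]
    bump_total = np.zeros_like(expected)
    for _ in range(n_lesions):
        cy, cx = body_idx[rng.integers(len(body_idx))]
        sigma = float(rng.uniform(1.0, 3.0))
        amp = (
            spec.body_level
            * (spec.lesion_intensity - 1.0)
            * float(rng.uniform(0.7, 1.3))
        )
        bump = amp * np.exp(-(((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * sigma**2)))
        bump_total += bump
        ledger["lesions"].append(
            {"row": int(cy), "col": int(cx), "sigma": sigma, "amplitude": amp}
        )
    expected += np.where(body, bump_total, 0.0)

    if rng.random() < spec.catheter_probability:
        width = int(rng.integers(1, 4))
        c0 = int(rng.uniform(0.02, 0.08) * spec.cols)
        length = int(rng.uniform(0.15, 0.30) * spec.rows)
        r0 = spec.rows - length
        expected[r0:, c0 : c0 + width] = spec.body_level * 0.8
        ledger["catheter"] = {
            "col_start": c0,
            "width": width,
            "row_start": r0,
        }

    posterior_expected = expected[:, ::-1]
    ant = rng.poisson(expected).astype(np.int64)
    post = rng.poisson(posterior_expected).astype(np.int64)
    return ScintigramPair(
        anterior=RawScintigram(ant, view="anterior"),
        posterior=RawScintigram(post, view="posterior"),
        mask_anterior=body.copy(),
        mask_posterior=body[:, ::-1].copy(),
        ledger=ledger,
    )


def render_cohort_images(
    patients: list[SyntheticPatient],
    spec: PhantomSpec,
    image_coupling: float = 1.0,
) -> list[SyntheticPatient]:
    """Attach rendered image pairs to every patient (in place)."""
    for i, p in enumerate(patients):
        p.images = simulate_scintigram_pair(
            p, spec, image_coupling=image_coupling, patient_index=i + 1
        )
    return patients


def cohort_to_frame(patients: list[SyntheticPatient]) -> pd.DataFrame:
    """Clinical table of the cohort, one row per patient, fixed column order."""
    rows = []
    for p in patients:
        row = {"patient_id": p.patient_id, **p.clinical, "label": p.label}
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(CLINICAL_COLUMNS))
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].astype(int)
    return df.set_index("patient_id")


def write_fixture_set(
    patients: list[SyntheticPatient], directory: str | Path
) -> dict:
    """Write a cohort to disk: 16-bit PNGs, clinical CSV and a manifest.

    Images must already be rendered.  Returns the manifest (also written
    as ``manifest.json``); re-reading with :func:`read_fixture_set`
    reproduces pixel grids and clinical values exactly.
    """
    from . import io as scio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for p in patients:
        if p.images is None:
            raise ValueError(f"patient {p.patient_id} has no rendered images")
        for view, img, mask in (
            ("anterior", p.images.anterior, p.images.mask_anterior),
            ("posterior", p.images.posterior, p.images.mask_posterior),
        ):
            img_path = directory / f"{p.patient_id}_{view}.png"
            scio.write_image_png(img.pixels, img_path)
            mask_path = directory / f"{p.patient_id}_{view}_mask.png"
            scio.write_mask_png(mask, mask_path)
            files.extend([img_path.name, mask_path.name])

    csv_path = directory / "clinical.csv"
    cohort_to_frame(patients).to_csv(csv_path)
    files.append(csv_path.name)

    manifest = {
        "n_patients": len(patients),
        "files": files,
        "patients": [
            {
                "patient_id": p.patient_id,
                "label": p.label,
                "latent_risk": p.latent_risk,
                "ledger": p.images.ledger if p.images else None,
            }
            for p in patients
        ],
        "checksum": None,
    }
    payload = json.dumps(manifest, sort_keys=True).encode()
    manifest["checksum"] = hashlib.sha256(payload).hexdigest()
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_fixture_set(directory: str | Path) -> list[SyntheticPatient]:
    """Load a cohort written by :func:`write_fixture_set`."""
    from . import io as scio

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    clinical = pd.read_csv(directory / "clinical.csv", index_col="patient_id")
    patients = []
    for entry in manifest["patients"]:
        pid = entry["patient_id"]
        rec = clinical.loc[pid].to_dict()
        label = int(rec.pop("label"))
        ant = scio.read_image(directory / f"{pid}_anterior.png", view="anterior")
        post = scio.read_image(directory / f"{pid}_posterior.png", view="posterior")
        mask_a = scio.read_mask_png(directory / f"{pid}_anterior_mask.png")
        mask_p = scio.read_mask_png(directory / f"{pid}_posterior_mask.png")
        patients.append(
            SyntheticPatient(
                patient_id=pid,
                clinical=rec,
                label=label,
                latent_risk=float(entry["latent_risk"]),
                images=ScintigramPair(
                    anterior=ant,
                    posterior=post,
                    mask_anterior=mask_a,
                    mask_posterior=mask_p,
                    ledger=entry["ledger"],
                ),
            )
        )
    return patients
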