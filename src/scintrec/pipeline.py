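"""End-to-end pipeline: simulate -> segment -> extract -> prep -> evaluate.

A single master seed fans out to independent per-stage seeds through
``numpy.random.SeedSequence(master_seed).generate_state``, so each stage
is reproducible on its own and the whole run is bit-identical under the
same configuration.  Every run writes a manifest with the configuration
hash, stage seeds, timings and output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import run_experiment, write_report
from .radiomics import extract_features
from .resampling import SmoteConfig
from .segmentation import MorphologyConfig, SegmentationError, create_body_mask
from .synthetic import (
    CohortSpec,
    PhantomSpec,
    cohort_to_frame,
    render_cohort_images,
    simulate_cohort,
)
from .tabular import DEFAULT_SCHEMA, assemble

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_all", "extract_cohort_features"]

STAGES = ("cohort", "images", "segmentation", "radiomics", "prep", "evaluation")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _strict_kwargs(cls, block: dict, name: str) -> dict:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown keys in config block {name!r}: {sorted(unknown)}")
    return block


@dataclass(frozen=True)
class PipelineConfig:
    """Strictly parsed stage configuration for a full synthetic run."""

    master_seed: int = 0
    n_patients: int = 354
    prevalence: float = 0.2853
    image_coupling: float = 1.0
    phantom: dict = field(default_factory=lambda: {"rows": 256, "cols": 64})
    segmentation: dict = field(default_factory=dict)
    bin_count: int = 32
    resampling: dict = field(default_factory=dict)
    k_folds: int = 5
    schema_version: str = DEFAULT_SCHEMA.version

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        # Validate nested blocks eagerly so errors surface before running.
        _strict_kwargs(PhantomSpec, cfg.phantom, "phantom")
        _strict_kwargs(MorphologyConfig, cfg.segmentation, "segmentation")
        _strict_kwargs(SmoteConfig, cfg.resampling, "resampling")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    stage_seeds: dict
    software_version: str
    timings: dict
    outputs: list


def _stage_seeds(master_seed: int) -> dict:
    state = np.random.SeedSequence(master_seed).generate_state(len(STAGES))
    return {stage: int(s % (2**31)) for stage, s in zip(STAGES, state)}


def extract_cohort_features(
    patients,
    morphology: MorphologyConfig | None = None,
    bin_count: int = 32,
) -> pd.DataFrame:
    """Segment both views of every patient and extract the 128 features."""
    morphology = morphology or MorphologyConfig()
    rows = {}
    for p in patients:
        if p.images is None:
            raise PipelineError("segmentation", f"patient {p.patient_id} has no images")
        try:
            seg_a = create_body_mask(p.images.anterior, morphology)
            seg_p = create_body_mask(p.images.posterior, morphology)
        except SegmentationError as err:
            raise PipelineError(
                "segmentation", f"patient {p.patient_id}: {err}"
            ) from err
        rows[p.patient_id] = extract_features(
            p.images.anterior.pixels,
            p.images.posterior.pixels,
            seg_a.mask,
            seg_p.mask,
            bin_count=bin_count,
        )
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df


def run_all(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Run the full synthetic pipeline and write all report artifacts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.master_seed)
    timings: dict = {}
    outputs: list[str] = []

    def _timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[stage] = round(time.perf_counter() - self.t0, 3)
                return False

        return _T()

    with _timed("cohort"):
        cohort_spec = CohortSpec(
            n_patients=config.n_patients,
            prevalence=config.prevalence,
            image_coupling=config.image_coupling,
            seed=seeds["cohort"],
        )
        patients = simulate_cohort(cohort_spec)
        clinical = cohort_to_frame(patients)
        clinical.to_csv(out_dir / "clinical.csv")
        outputs.append("clinical.csv")

    with _timed("images"):
        phantom_spec = PhantomSpec(seed=seeds["images"], **config.phantom)
        render_cohort_images(
            patients, phantom_spec, image_coupling=config.image_coupling
        )

    with _timed("radiomics"):
        morphology = MorphologyConfig(**config.segmentation)
        radiomics = extract_cohort_features(
            patients, morphology, bin_count=config.bin_count
        )
        radiomics.to_csv(out_dir / "features.csv")
        outputs.append("features.csv")

    with _timed("prep"):
        designs = {
            fs: assemble(clinical, radiomics, feature_set=fs)
            for fs in ("damico", "tnm", "clinical", "clinical_radiomics")
        }

    with _timed("evaluation"):
        smote = SmoteConfig(seed=seeds["evaluation"], **config.resampling)
        report = run_experiment(
            designs, k=config.k_folds, seed=seeds["evaluation"], smote=smote
        )
        outputs += write_report(report, out_dir)

    manifest = RunManifest(
        config_hash=config.hash(),
        master_seed=config.master_seed,
        stage_seeds=seeds,
        software_version=__version__,
        timings=timings,
        outputs=outputs,
    )
    (out_dir / "run_manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2)
    )
    return manifest
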