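"""End-to-end orchestration: phantoms -> preprocessing -> [GLCM -> MLP] and
[CNN] -> Dempster-Shafer fusion -> cross-validated report.

Configuration is a YAML/JSON document validated against typed dataclasses
(unknown keys are rejected with their paths).  Every stage writes its
artifact in an open format (PGM, CSV, JSON) under the output directory and
is skipped on rerun if the artifact already exists, so a run is resumable
from any stage.  A single master seed is fanned out per stage via a fixed
name-based derivation, making every output a pure function of config + seed.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifiers import MLPConfig
from .cnn import CNNConfig
from .errors import ConfigurationError
from .evaluation import EvalReport, run_cv_experiment
from .fusion import Frame
from .glcm import GLCMSpec, features_for_dataset
from .image import GrayImage, read_image
from .phantom import CLASSES, PhantomSpec, generate_phantom_dataset, write_dataset
from .preprocess import equalize, extract_roi, median_filter

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("mldstnet")


@dataclass(frozen=True)
class PreprocessOptions:
    median_window: int = 3
    equalize: bool = True
    roi: bool = False


@dataclass(frozen=True)
class SyntheticOptions:
    n_per_class: int = 50
    image_size: int = 128
    mass_radius: float = 14.0
    spicule_count: int = 8
    noise_salt_pepper_frac: float = 0.01
    noise_gaussian_sigma: float = 4.0
    background_texture_scale: float = 8.0


@dataclass(frozen=True)
class PipelineConfig:
    """Validated, fully-defaulted pipeline configuration."""

    data_dir: str | None = None          # directory of images + labels.csv; None -> synthetic
    out_dir: str = "mldst_out"
    synthetic: SyntheticOptions = field(default_factory=SyntheticOptions)
    preprocess: PreprocessOptions = field(default_factory=PreprocessOptions)
    glcm: GLCMSpec = field(default_factory=GLCMSpec)
    mlp: MLPConfig = field(default_factory=MLPConfig)
    # desk-scale CNN: same four-block architecture, 32 px input with
    # proportionally smaller kernels, so a full CV run stays in minutes
    cnn: CNNConfig = field(
        default_factory=lambda: CNNConfig(
            input_size=32, kernel_sizes=(7, 5, 3, 3), epochs=25,
            learning_rate=0.02, batch_size=8,
        )
    )
    fusion_variant: str = "disjoint_singleton"
    cv_folds: int = 5
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        Frame(self.fusion_variant)  # validates the variant name
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if self.data_dir is None and self.synthetic.n_per_class < self.cv_folds:
            raise ConfigurationError(
                f"cv_folds={self.cv_folds} needs at least that many samples per "
                f"class; synthetic.n_per_class={self.synthetic.n_per_class}"
            )


_SECTION_TYPES = {
    "synthetic": SyntheticOptions,
    "preprocess": PreprocessOptions,
    "glcm": GLCMSpec,
    "mlp": MLPConfig,
    "cnn": CNNConfig,
}


def _build_section(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(f'{path}.{k}' for k in unknown)}"
        )
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


def validate_config(raw_text: str) -> PipelineConfig:
    """Parse and validate a YAML/JSON config document.

    An empty document yields all defaults; unknown keys are rejected with
    their full key path.
    """
    data = yaml.safe_load(raw_text) if raw_text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ConfigurationError(f"unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigurationError(f"section {key!r} must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def _child_seed(master: int, stage: str) -> int:
    """Stable per-stage seed derivation from the master seed."""
    return int(
        np.random.SeedSequence([master, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31)
    )


def _load_labelled_dir(data_dir: Path) -> tuple[list[GrayImage], list[str]]:
    table = pd.read_csv(data_dir / "labels.csv")
    images = [read_image(data_dir / fn) for fn in table["filename"]]
    return images, list(table["label"])


def run_pipeline(config: PipelineConfig) -> tuple[EvalReport, dict[str, Path]]:
    """Execute the full flow; returns the report and the artifact paths.

    Stage artifacts (phantom images + labels, preprocessed images, feature
    CSV, report JSON) live under ``config.out_dir`` and are reused when
    already present, making reruns idempotent and resumable.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # --- stage: data -------------------------------------------------------
    phantom_dir = out / "phantoms"
    if config.data_dir is not None:
        images, labels = _load_labelled_dir(Path(config.data_dir))
        log.info("stage=data source=%s images=%d", config.data_dir, len(images))
    elif (phantom_dir / "labels.csv").exists():
        images, labels = _load_labelled_dir(phantom_dir)
        log.info("stage=data resumed from %s images=%d", phantom_dir, len(images))
    else:
        syn = config.synthetic
        template = PhantomSpec(
            image_size=syn.image_size,
            mass_radius=syn.mass_radius,
            spicule_count=syn.spicule_count,
            noise_salt_pepper_frac=syn.noise_salt_pepper_frac,
            noise_gaussian_sigma=syn.noise_gaussian_sigma,
            background_texture_scale=syn.background_texture_scale,
        )
        ds = generate_phantom_dataset(
            syn.n_per_class, template, _child_seed(config.seed, "phantoms")
        )
        write_dataset(ds, phantom_dir)
        images, labels = ds.images, ds.labels
        log.info("stage=data generated images=%d", len(images))
    artifacts["data"] = phantom_dir if config.data_dir is None else Path(config.data_dir)

    # --- stage: preprocess + features -------------------------------------
    features_csv = out / "features.csv"
    pre = config.preprocess
    if features_csv.exists():
        # feature extraction skipped; preprocessing is still recomputed (it is
        # deterministic and cheap next to training) because the CNN consumes
        # the preprocessed images directly
        features = pd.read_csv(features_csv)
        log.info("stage=features resumed rows=%d", len(features))
        processed = [_preprocess_one(img, pre) for img in images]
    else:
        processed = [_preprocess_one(img, pre) for img in images]
        log.info("stage=preprocess images=%d window=%d equalize=%s roi=%s",
                 len(processed), pre.median_window, pre.equalize, pre.roi)
        features = features_for_dataset(processed, labels, config.glcm)
        features.to_csv(features_csv, index=False)
        log.info("stage=features rows=%d cols=%d", *features.shape)
    artifacts["features"] = features_csv

    # --- stage: cross-validated training + fusion --------------------------
    report = run_cv_experiment(
        processed,
        labels,
        mlp_config=config.mlp,
        cnn_config=config.cnn,
        glcm_spec=config.glcm,
        frame=Frame(config.fusion_variant),
        k=config.cv_folds,
        seed=_child_seed(config.seed, "cv"),
        features=features,
    )
    log.info(
        "stage=cv folds=%d images=%d fused_rows=%d",
        config.cv_folds, len(images), report.counts["fused_rows"],
    )

    report_json = out / "report.json"
    report_json.write_text(report.to_json())
    artifacts["report"] = report_json
    return report, artifacts


def _preprocess_one(img: GrayImage, pre: PreprocessOptions) -> GrayImage:
    out = median_filter(img, pre.median_window)
    if pre.equalize:
        out = equalize(out)
    if pre.roi:
        out, _ = extract_roi(out)
    return out
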