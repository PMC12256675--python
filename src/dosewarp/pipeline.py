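"""End-to-end orchestration: simulate -> train -> register -> accumulate -> evaluate.

``run_pipeline`` drives the whole study on synthetic data at a configurable
(desk) scale and persists every artifact: the simulated course, both trained
models, the registration metric table (two-stratum layout), the DVH report
for the DA / VoA / MA addition strategies, and a manifest with SHA-256 hashes
of every output.  With a fixed seed the CSV reports are byte-identical across
reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dwio
from .dose import dir_addition, direct_addition_course
from .evaluate import evaluate_courses, summarize
from .grids import Course
from .registration.training import TrainConfig, register, save_model, train
from .synthetic import CourseSpec, DeformSpec, PhantomSpec, generate_course, generate_pairs

log = logging.getLogger("dosewarp")


@dataclass
class RunConfig:
    """Merged settings for the end-to-end run; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "dosewarp_run"
    grid_shape: tuple = (48, 48, 32)
    spacing: tuple = (2.0, 2.0, 4.0)
    amplitude: float = 4.0
    smoothness_sigma: float = 12.0
    n_train_pairs: int = 20
    n_eval_courses: int = 1
    n_icbt: int = 5
    epochs: int = 60
    folds: int = 1
    learning_rate: float = 1e-3  # desk-scale rate; see docs/methods.md
    embed_dim: int = 256
    lambda_smooth: float = 1.0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def train_config(self, model: str) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            max_epochs=self.epochs,
            seed=self.seed,
            folds=self.folds,
            embed_dim=self.embed_dim,
            lambda_smooth=self.lambda_smooth,
            model=model,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.8g")


def compute_method_fields(course: Course, models: dict[str, object]) -> dict[str, dict]:
    fields = {}
    fixed = course.fixed_frame
    for name, model in models.items():
        fields[name] = {}
        for idx in course.moving_indices:
            field, _ = register(model, fixed.image, course.frames[idx].image)
            fields[name][idx] = field
    return fields


def dvh_report(course: Course, models: dict[str, object]) -> pd.DataFrame:
    """DA plus one deformation-based row per model, per organ."""
    organs = sorted(course.fixed_frame.masks)
    rows = []
    da = direct_addition_course(course, organs)
    for organ in organs:
        p = da[organ]
        rows.append({"method": "DA", "organ": organ, "d2cc": p.d2cc, "d1cc": p.d1cc,
                     "d01cc": p.d01cc, "v50": p.v50})
    for name, model in models.items():
        params = dir_addition(course, model=model, organs=organs)
        for organ in organs:
            p = params[organ]
            rows.append({"method": name, "organ": organ, "d2cc": p.d2cc, "d1cc": p.d1cc,
                         "d01cc": p.d01cc, "v50": p.v50})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full study; returns the artifact directory."""
    logging.basicConfig(
        level=getattr(logging, config.verbosity.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    phantom_spec = PhantomSpec(grid_shape=tuple(config.grid_shape), spacing=tuple(config.spacing))
    deform_spec = DeformSpec(amplitude=config.amplitude, smoothness_sigma=config.smoothness_sigma)

    stage = "simulate"
    try:
        log.info("simulating %d training pairs and %d courses", config.n_train_pairs,
                 config.n_eval_courses)
        pairs = generate_pairs(config.n_train_pairs, phantom_spec, deform_spec,
                               seed=int(rng.integers(2**31)))
        courses = [
            generate_course(CourseSpec(n_icbt=config.n_icbt), phantom_spec, deform_spec,
                            seed=int(rng.integers(2**31)))
            for _ in range(config.n_eval_courses)
        ]
        for i, course in enumerate(courses):
            dwio.write_course(course, out / f"course{i:02d}")

        stage = "train"
        models = {}
        for name, kind in (("MA", "mtdir"), ("VoA", "cnn")):
            log.info("training %s (%s) for %d epochs", name, kind, config.epochs)
            models[name] = train(pairs, config.train_config(kind))
            save_model(models[name], out / f"model_{name}")

        stage = "register"
        fields_per_course = [compute_method_fields(c, models) for c in courses]

        stage = "evaluate"
        rows = evaluate_courses(courses, fields_per_course)
        _write_csv(rows, out / "metrics.csv")
        _write_csv(summarize(rows), out / "metrics_summary.csv")

        stage = "accumulate"
        reports = []
        for i, course in enumerate(courses):
            rep = dvh_report(course, models)
            rep.insert(0, "case", i)
            reports.append(rep)
        _write_csv(pd.concat(reports, ignore_index=True), out / "report.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {exc}") from exc

    manifest = {
        "config": asdict(config),
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "run_manifest.json"
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %s", out)
    return out
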