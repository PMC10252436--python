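"""End-to-end orchestration: simulate → preprocess → index → grade →
forecast → combine → evaluate, under one configuration and one seed.

Every stage writes its tabular output to the run directory as headered
CSV (or JSON for models/reports), and a ``manifest.json`` records the
configuration hash, the seed, per-stage timings and package versions.
Each stage draws its randomness from a seed derived by hashing the stage
name into the global seed, so stages are reproducible independently of
one another and a rerun with the same configuration and seed regenerates
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .combiner import combine_predictions
from .evaluation import EvaluationReport, evaluate_pipeline
from .exceptions import StageError
from .forecasting import ForecastConfig, LstmConfig, XgbConfig, forecast_all
from .grading import RiskGrader
from .indices import IlcrParams, MoeParams, NipiParams, compute_triples
from .preprocessing import CensoringPolicy, substitute_nondetects, summarize
from .synthetic import SyntheticConfig, generate, read_sampling, write_outputs

STAGES = (
    "simulate",
    "preprocess",
    "index",
    "grade",
    "forecast",
    "combine",
    "evaluate",
)


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed: stage name hashed into the global seed (< 2**31)."""
    return (zlib.crc32(stage.encode()) ^ (seed & 0x7FFFFFFF)) % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything one run needs; nested stage configurations."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    censoring: CensoringPolicy = field(default_factory=CensoringPolicy)
    ilcr: IlcrParams = field(default_factory=IlcrParams)
    moe: MoeParams = field(default_factory=MoeParams)
    nipi: NipiParams = field(default_factory=NipiParams)
    forecast: ForecastConfig = field(default_factory=ForecastConfig)
    k: int | str = "auto"
    k_range: tuple[int, int] = (1, 8)
    combine_mode: str = "rolling"
    combine_window: int = 7
    tune_xgb: bool = False
    seed: int = 42
    # optional external inputs (same schema as the synthetic writer);
    # when set, the simulate stage is skipped
    sampling_path: str | None = None
    consumption_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("synthetic", SyntheticConfig),
            ("censoring", CensoringPolicy),
            ("ilcr", IlcrParams),
            ("moe", MoeParams),
            ("nipi", NipiParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if "forecast" in kwargs and isinstance(kwargs["forecast"], dict):
            fc = dict(kwargs["forecast"])
            if "lstm" in fc and isinstance(fc["lstm"], dict):
                if "units" in fc["lstm"]:
                    fc["lstm"]["units"] = tuple(fc["lstm"]["units"])
                fc["lstm"] = LstmConfig(**fc["lstm"])
            if "xgb" in fc and isinstance(fc["xgb"], dict):
                fc["xgb"] = XgbConfig(**fc["xgb"])
            kwargs["forecast"] = ForecastConfig(**fc)
        if "k_range" in kwargs:
            kwargs["k_range"] = tuple(kwargs["k_range"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_all(cfg: RunConfig, out_dir: str | Path, verbose: bool = False) -> EvaluationReport:
    """Execute all stages; returns the final report.

    Artifacts written to ``out_dir``: sampling.csv, consumption.csv,
    truth.csv, summaries.csv, indicators.csv, grade_model.json,
    levels.csv, predictions.csv, combined.csv, report.json, report.md,
    manifest.json.  On stage failure a :class:`StageError` names the
    stage; outputs of completed stages are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def log(msg: str) -> None:
        if verbose:
            print(f"[oilrisk] {msg}")

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                log(f"stage {name} ...")
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise StageError(name, exc) from exc

        return _Timer()

    truth = None
    with stage("simulate"):
        if cfg.sampling_path is None:
            syn = dataclasses.replace(
                cfg.synthetic, seed=derive_seed(cfg.seed, "simulate")
            )
            sampling, consumption, truth = generate(syn)
            write_outputs(sampling, consumption, truth, out)
        else:
            for path, what in (
                (cfg.sampling_path, "sampling"),
                (cfg.consumption_path, "consumption"),
            ):
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"{what} file not found: {path}")
            sampling = read_sampling(cfg.sampling_path)
            consumption = pd.read_csv(cfg.consumption_path)

    with stage("preprocess"):
        valued = substitute_nondetects(sampling, cfg.censoring)
        summaries = summarize(valued)
        summaries.to_csv(out / "summaries.csv", index=False)

    with stage("index"):
        triples = compute_triples(summaries, consumption, cfg.ilcr, cfg.moe, cfg.nipi)
        triples.to_csv(out / "indicators.csv", index=False)

    with stage("grade"):
        grader = RiskGrader(
            k=cfg.k,
            k_range=range(cfg.k_range[0], cfg.k_range[1] + 1),
            random_state=derive_seed(cfg.seed, "grade"),
        ).fit(triples)
        (out / "grade_model.json").write_text(json.dumps(grader.to_dict(), indent=2))
        levels = triples[["city", "week"]].copy()
        levels["level"] = grader.labels_
        levels.to_csv(out / "levels.csv", index=False)

    with stage("forecast"):
        predictions = forecast_all(
            triples, cfg.forecast, seed=derive_seed(cfg.seed, "forecast"),
            tune_xgb=cfg.tune_xgb,
        )
        predictions.to_csv(out / "predictions.csv", index=False)

    with stage("combine"):
        combined = combine_predictions(
            predictions, mode=cfg.combine_mode, window=cfg.combine_window
        )
        combined.to_csv(out / "combined.csv", index=False)

    with stage("evaluate"):
        report = evaluate_pipeline(combined, grader)
        report.to_json(out / "report.json")
        (out / "report.md").write_text(report.to_markdown())

    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stage_seeds": {s: derive_seed(cfg.seed, s) for s in STAGES},
        "timings_s": timings,
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log("done")
    return report


def _versions() -> dict[str, str]:
    import numpy
    import sklearn
    import xgboost

    return {
        "oilrisk": __version__,
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
    }
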