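"""Declarative run configuration (YAML) and the end-to-end pipeline.

A run config names the inputs (series/calendar CSVs, or a synthetic
block to simulate them), the split geometry, the learner zoo with
grids, the tuning method and the stacking options. ``run_pipeline``
executes simulate -> features -> backtest -> tune -> stack -> report
and writes every artifact, stamped with the config hash and seed so
runs are auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .learners import LearnerSpec, default_spec
from .model import DemandForecaster
from .series import CovariateCalendar, DemandSeries, ValidationError
from .synthetic import SyntheticConfig, generate
from .tuning import SelectionRule

ALLOWED_HORIZONS = (1, 3, 7)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    series_csv: str | None = None
    calendar_csv: str | None = None
    synthetic: dict | None = None
    output_dir: str = "demandcast_out"
    horizons: tuple[int, ...] = (1,)
    train_length: int = 1460
    val_length: int = 730
    test_length: int = 730
    learners: list = field(default_factory=lambda: ["lm", "glmnet", "knn"])
    method: str = "batch"
    rule: SelectionRule = field(default_factory=lambda: SelectionRule("validation_average"))
    period: int = 7
    stack: bool = True
    ridge: float = 0.0
    importance: bool = False
    importance_repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        self.horizons = tuple(int(h) for h in self.horizons)
        bad = [h for h in self.horizons if h not in ALLOWED_HORIZONS]
        if bad:
            raise ValidationError(f"unsupported horizon(s) {bad}; allowed: {ALLOWED_HORIZONS}")
        if self.method not in ("batch", "online"):
            raise ValidationError("method must be 'batch' or 'online'")
        if (self.series_csv is None) != (self.calendar_csv is None):
            raise ValidationError("series_csv and calendar_csv must be given together")
        specs = []
        for item in self.learners:
            if isinstance(item, LearnerSpec):
                specs.append(item)
            elif isinstance(item, str):
                specs.append(default_spec(item))
            else:
                item = dict(item)
                specs.append(LearnerSpec(item["name"], item.get("grid")))
        if not specs:
            raise ValidationError("at least one learner required")
        self.learners = specs

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "rule" in raw and not isinstance(raw["rule"], SelectionRule):
            r = dict(raw["rule"]) if isinstance(raw["rule"], dict) else {"kind": raw["rule"]}
            raw["rule"] = SelectionRule(
                r.get("kind", "validation_average"),
                n=int(r.get("n", 7)),
                alpha=float(r.get("alpha", 0.1)),
            )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def load_inputs(self) -> tuple[DemandSeries, CovariateCalendar]:
        if self.series_csv is not None:
            series = DemandSeries.from_csv(self.series_csv)
            calendar = CovariateCalendar.from_csv(self.calendar_csv)
            if not calendar.aligned_with(series):
                raise ValidationError("series and calendar CSVs cover different spans")
            return series, calendar
        syn = dict(self.synthetic or {})
        syn.setdefault("seed", self.seed)
        return generate(SyntheticConfig(**syn))


def _stamp(path: Path, frame, config_hash: str, seed: int) -> None:
    """Write a CSV with an audit comment line (config hash + seed)."""
    with open(path, "w") as fh:
        fh.write(f"# demandcast config={config_hash} seed={seed}\n")
        frame.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns {horizon: ForecastResults}.

    Artifacts written under ``config.output_dir``: the (possibly
    simulated) inputs, per-learner forecast logs and selection traces,
    the stacked log, stack weights, the scoreboard, optional importance
    reports, and ``metadata.json`` recording every default left open
    (rule parameters, grids, clamps) plus the config hash and seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, calendar = config.load_inputs()
    series.to_csv(out / "series.csv")
    calendar.to_csv(out / "calendar.csv")
    results = {}
    metadata = {"horizons": {}, "seed": config.seed}
    for horizon in config.horizons:
        model = DemandForecaster(
            series,
            calendar,
            horizon=horizon,
            learners=config.learners,
            method=config.method,
            rule=config.rule,
            period=config.period,
            train_length=config.train_length,
            val_length=config.val_length,
            test_length=config.test_length,
            stack=config.stack,
            ridge=config.ridge,
            seed=config.seed,
        )
        chash = model.config_hash()
        try:
            res = model.fit()
        except ValidationError as exc:
            raise ValidationError(f"horizon {horizon}: {exc}") from exc
        results[horizon] = res
        hdir = out / f"h{horizon}"
        hdir.mkdir(exist_ok=True)
        for name, log in res.test_logs.items():
            _stamp(hdir / f"log_{name}.csv", log, chash, config.seed)
            _stamp(hdir / f"trace_{name}.csv", res.traces[name], chash, config.seed)
        if res.stack_log is not None:
            _stamp(hdir / "log_stack.csv", res.stack_log, chash, config.seed)
            (hdir / "stack_weights.json").write_text(
                json.dumps(
                    {
                        "config": chash,
                        "seed": config.seed,
                        "weights": res.stack_weights.weights,
                        "n_rows_used": res.stack_weights.n_rows_used,
                        "n_rows_dropped": res.stack_weights.n_rows_dropped,
                    },
                    indent=2,
                )
            )
        _stamp(hdir / "scoreboard.csv", res.scoreboard, chash, config.seed)
        if config.importance:
            for spec in config.learners:
                if spec.family == "ml":
                    rep = res.importance(spec.name, repeats=config.importance_repeats)
                    _stamp(hdir / f"importance_{spec.name}.csv", rep, chash, config.seed)
        metadata["horizons"][str(horizon)] = {
            "config_hash": chash,
            "config": model.config_dict(),
        }
    (out / "metadata.json").write_text(json.dumps(metadata, indent=2, default=str))
    return results
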