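"""End-to-end pipeline: classify -> preprocess -> validate/fit -> excess ->
aggregate, driven by a single declarative config."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import exposure, io, preprocess
from .countmodel import FitConfig, enumerate_specs
from .ensemble import ExcessDeathEnsemble

log = logging.getLogger("stormexcess")


@dataclass
class PipelineConfig:
    deaths: str = "deaths.csv"
    population: str = "population.csv"
    temperature: str = "temperature.csv"
    wind: str = "wind.csv"
    svi: str | None = None
    state_map: str | None = None
    output_dir: str = "out"
    gale_threshold: float = 34.0
    hurricane_threshold: float = 64.0
    draw_cap: int = 1000
    probability_filter: float = 0.95
    seed: int = 0
    model_ids: list | None = None
    validation_windows: list | None = None
    fit: dict = field(default_factory=dict)
    groupings: list = field(
        default_factory=lambda: [["county", "year"], ["national", "year"]]
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.gale_threshold < self.hurricane_threshold:
            raise ValueError("wind thresholds must be strictly increasing")
        if not 0 < self.draw_cap <= 10000:
            raise ValueError("draw cap out of range")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the result bundle and writes the
    report CSVs under config.output_dir."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = dict(config.__dict__)

    log.info("stage: classify")
    wind = io.read_table(config.wind, "wind")
    deaths = io.read_table(config.deaths, "deaths")
    span = (int(deaths["year"].min()), 1), (int(deaths["year"].max()), 12)
    if (deaths["year"].max() - deaths["year"].min() + 1) * 12 < 24:
        raise ValueError("study window must cover at least 24 months")
    calendar = exposure.build_calendar(
        wind, span[0], span[1], config.gale_threshold, config.hurricane_threshold
    )
    io.write_calendar(calendar, outdir / "calendar.csv", outdir / "targets.csv")

    log.info("stage: preprocess")
    panel = preprocess.build_panel(
        deaths,
        io.read_table(config.population, "population"),
        io.read_table(config.temperature, "temperature"),
    )
    panel.to_csv(outdir / "panel.csv", index=False)

    state_map = io.read_table(config.state_map, "state_map") if config.state_map else None
    svi = io.read_table(config.svi, "svi") if config.svi else None

    log.info("stage: fit")
    specs = enumerate_specs()
    if config.model_ids:
        specs = [s for s in specs if s.model_id in set(config.model_ids)]
    fit_config = FitConfig(**{"n_draws": config.draw_cap, **config.fit})
    windows = None
    if config.validation_windows:
        windows = [[tuple(m) for m in w] for w in config.validation_windows]
    ens = ExcessDeathEnsemble(
        panel, calendar, specs=specs, fit_config=fit_config,
        state_map=state_map, svi=svi,
    )
    results = ens.fit(seed=config.seed, windows=windows)
    results.validation_table().to_csv(outdir / "validation.csv", index=False)
    io.save_draws(
        outdir / "excess_draws.npz", results.excess.index, results.excess.draws
    )

    log.info("stage: aggregate")
    tally = exposure.tally_county_months(calendar)
    tally.to_csv(outdir / "tally.csv", index=False)
    summaries = {}
    for grouping in config.groupings:
        grouping = list(grouping)
        if "tertile" in grouping and svi is None:
            log.warning("skipping tertile grouping: no SVI table configured")
            continue
        if "state" in grouping and state_map is None:
            log.warning("skipping state grouping: no state map configured")
            continue
        name = "-".join(grouping)
        df = results.by(grouping, probability_filter=config.probability_filter)
        df.to_csv(outdir / f"excess_by_{name}.csv", index=False)
        summaries[name] = df

    io.write_manifest(outdir / "manifest.json", cfg_dict, config.seed, "pipeline")
    (outdir / "summary.txt").write_text(results.summary() + "\n")
    return {
        "results": results,
        "calendar": calendar,
        "panel": panel,
        "tally": tally,
        "summaries": summaries,
    }
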