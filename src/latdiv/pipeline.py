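"""Pipeline orchestration: stages, run configuration and the manifest.

Each stage reads its inputs from ``out_dir`` (or the configured paths),
writes its artifacts there, and appends row-count deltas and warnings to a
run manifest so headline bookkeeping numbers (cells retained, unique bands,
estimates computed) are auditable after the fact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import latdiv
from latdiv.banding import (
    apply_species_filters,
    build_cells,
    multispecies_band_filter,
    sample_size_qc,
)
from latdiv.diversity import estimate_all
from latdiv.mixedmodel import parametric_bootstrap, r2_nakagawa, DesignSpec
from latdiv.selection import driver_analysis, intraspecific_trends, polynomial_ladder
from latdiv.seqdata import read_records
from latdiv.synthetic import SimConfig, simulate_env_fields, simulate_sequences

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat run configuration; defaults are the analysis' standard values."""

    fasta: str | None = None
    metadata: str | None = None
    env: str | None = None
    out_dir: str = "latdiv_out"
    min_n: int = 3
    min_bands: int = 4
    r_max: float = 0.7
    vif_max: float = 5.0
    delta_aic: float = 2.0
    delta_aicc: float = 2.0
    ci_level: float = 0.95
    bootstrap_B: int = 1000
    qc_outlier_threshold: float = 3.0
    absolute_bands: bool = False
    seed: int = 0
    plots: bool = False
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("min_n", "min_bands", "bootstrap_B"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("r_max", "vif_max", "delta_aic", "delta_aicc",
                     "ci_level", "qc_outlier_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (tuple, set)):
        return list(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(data: dict, path: Path) -> None:
    path.write_text(json.dumps(data, indent=1, default=_jsonable, sort_keys=True))


class Manifest:
    def __init__(self, config: RunConfig):
        self.data = {
            "version": latdiv.__version__,
            "config": dataclasses.asdict(config),
            "config_hash": config.hash(),
            "seed": config.seed,
            "stages": {},
            "warnings": [],
        }

    def record(self, stage: str, **info) -> None:
        self.data["stages"].setdefault(stage, {}).update(info)

    def warn(self, message: str) -> None:
        self.data["warnings"].append(message)
        logger.warning(message)

    def write(self, out_dir: Path) -> None:
        _write_json(self.data, out_dir / "manifest.json")


def stage_simulate(config: RunConfig, manifest: Manifest) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = SimConfig(**config.sim)
    dataset = simulate_sequences(sim_cfg, config.seed)
    paths = dataset.write(out)
    env = simulate_env_fields(sim_cfg, config.seed + 1,
                              bands=dataset.metadata["band"].unique())
    env_path = out / "env.csv"
    with open(env_path, "w") as fh:
        fh.write(f"# cfg={sim_cfg.hash()} seed={config.seed + 1}\n")
        env.to_csv(fh, index=False)
    config.fasta = str(paths["fasta"])
    config.metadata = str(paths["metadata"])
    config.env = str(env_path)
    manifest.record(
        "simulate",
        n_sequences=len(dataset.records),
        n_species=dataset.metadata["species_id"].nunique(),
        sim_config_hash=sim_cfg.hash(),
        files={k: str(v) for k, v in paths.items()} | {"env": str(env_path)},
    )


def stage_diversity(config: RunConfig, manifest: Manifest) -> pd.DataFrame:
    if not config.fasta or not config.metadata:
        raise ValueError("diversity stage requires fasta and metadata paths")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_records(config.fasta, config.metadata)
    cells = build_cells(records, absolute=config.absolute_bands)
    retained, report = apply_species_filters(
        cells, min_n=config.min_n, min_bands=config.min_bands
    )
    if not retained:
        raise ValueError("inclusion filters left no cells")
    estimates = estimate_all(retained, records)
    estimates.to_csv(out / "diversity.tsv", sep="\t", index=False)
    _write_json(dataclasses.asdict(report), out / "filter_report.json")
    manifest.record(
        "diversity",
        n_records=len(records),
        n_cells_input=len(cells),
        n_cells_retained=report.retained_cells,
        n_species_retained=estimates["species_id"].nunique(),
        unique_bands=report.unique_bands,
        n_rows=len(estimates),
        n_estimates=2 * len(estimates),
    )
    return estimates


def _load_estimates(config: RunConfig) -> pd.DataFrame:
    path = Path(config.out_dir) / "diversity.tsv"
    if not path.exists():
        raise ValueError(f"missing diversity table {path}; run the diversity stage")
    return pd.read_csv(path, sep="\t")


def stage_total_trend(config: RunConfig, manifest: Manifest) -> dict:
    out = Path(config.out_dir)
    estimates = _load_estimates(config)
    pooled = multispecies_band_filter(estimates)
    if pooled.empty:
        raise ValueError("multispecies filter left no data")
    result: dict = {"n_rows_pooled": len(pooled)}
    for metric in ("pi", "hd"):
        qc = sample_size_qc(pooled, metric,
                            outlier_threshold=config.qc_outlier_threshold)
        ladder = polynomial_ladder(
            pooled[metric].to_numpy(), pooled["band"].to_numpy(),
            groups=pooled["species_id"].to_numpy(), delta=config.delta_aic,
        )
        fit = ladder.fits[ladder.selected_order]
        r2 = r2_nakagawa(fit, _ladder_design(ladder, pooled))
        spec = DesignSpec(
            pooled[metric].to_numpy(),
            _ladder_design(ladder, pooled),
            pooled["species_id"].to_numpy(),
            list(fit.names),
        )
        boot = parametric_bootstrap(fit, spec, B=config.bootstrap_B,
                                    seed=config.seed)
        if boot.unreliable:
            manifest.warn(f"total-trend {metric}: bootstrap unreliable "
                          f"({boot.n_failed}/{boot.B} failures)")
        result[metric] = {
            "qc": dataclasses.asdict(qc),
            "ladder": ladder.rows.to_dict(orient="records"),
            "selected_order": ladder.selected_order,
            "selection_reason": ladder.selection_reason,
            "coefficients": dict(zip(fit.names, fit.beta)),
            "se": dict(zip(fit.names, fit.se_beta)),
            "t_values": dict(zip(fit.names, fit.t_values)),
            "sigma2_alpha": fit.sigma2_alpha,
            "sigma2_eps": fit.sigma2_eps,
            "loglik": fit.loglik,
            "k": fit.k,
            "N": fit.N,
            **r2,
            "bootstrap": dataclasses.asdict(boot),
        }
        if config.plots:
            from latdiv.plots import plot_trend
            plot_trend(pooled[metric].to_numpy(), pooled["band"].to_numpy(),
                       ladder, out / f"trend_{metric}.svg", metric)
    _write_json(result, out / "total_trend.json")
    manifest.record("total_trend",
                    n_rows_pooled=len(pooled),
                    selected_order_pi=result["pi"]["selected_order"],
                    selected_order_hd=result["hd"]["selected_order"])
    return result


def _ladder_design(ladder, pooled) -> np.ndarray:
    from latdiv.mixedmodel import polynomial_design

    if ladder.selected_order == 0 or ladder.scale is None:
        return np.ones((len(pooled), 1))
    z = ladder.scale.transform(pooled["band"].to_numpy(dtype=float))
    return polynomial_design(z, ladder.selected_order)


def stage_drivers(config: RunConfig, manifest: Manifest) -> dict:
    out = Path(config.out_dir)
    estimates = _load_estimates(config)
    if not config.env:
        raise ValueError("drivers stage requires an env table path")
    env = pd.read_csv(config.env, comment="#")
    pooled = multispecies_band_filter(estimates)
    if pooled.empty:
        raise ValueError("multispecies filter left no data")
    result = {}
    for metric in ("pi", "hd"):
        report = driver_analysis(
            pooled, env, metric,
            r_max=config.r_max, vif_max=config.vif_max,
            delta_aic=config.delta_aic, delta_aicc=config.delta_aicc,
        )
        result[metric] = {
            "thresholds": report.thresholds,
            "vif": report.screen.vif,
            "flagged_pairs": report.screen.flagged_pairs,
            "candidate_sets": report.screen.candidate_sets,
            "global_fits": report.global_fits,
            "retained_sets": report.retained_sets,
            "rankings": {
                name: r.table.assign(
                    terms=r.table["terms"].map(list)
                ).to_dict(orient="records")
                for name, r in report.rankings.items()
            },
            "averaged": {
                name: a.table.to_dict(orient="records")
                for name, a in report.averaged.items()
            },
        }
    _write_json(result, out / "drivers.json")
    manifest.record("drivers", metrics=list(result))
    return result


def stage_intraspecific(config: RunConfig, manifest: Manifest) -> pd.DataFrame:
    out = Path(config.out_dir)
    estimates = _load_estimates(config)
    trends = intraspecific_trends(estimates, delta=config.delta_aic)
    trends.to_csv(out / "intraspecific_trends.tsv", sep="\t", index=False)
    manifest.record("intraspecific", n_fits=len(trends))
    return trends


STAGES = {
    "simulate": stage_simulate,
    "diversity": stage_diversity,
    "total-trend": stage_total_trend,
    "drivers": stage_drivers,
    "intraspecific": stage_intraspecific,
}

_ALL_ORDER = ["simulate", "diversity", "total-trend", "drivers", "intraspecific"]


def run(command: str, config: RunConfig) -> Manifest:
    """Run one stage or the whole chain; writes the manifest either way."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config)
    stages = _ALL_ORDER if command == "all" else [command]
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown command {stage!r}")
        try:
            STAGES[stage](config, manifest)
        except Exception as exc:
            manifest.warn(f"stage {stage} failed: {exc}")
            manifest.write(out)
            raise
    manifest.write(out)
    return manifest
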