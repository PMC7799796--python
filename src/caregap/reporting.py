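"""Pipeline orchestration: dataset -> reachability -> indicators ->
gap classes -> TOPSIS -> correlations, with all file I/O and a run report.

Every stage writes a documented CSV so stages can also be run (and
tested) independently via the CLI.  Export precision follows the study's
reporting conventions: coverage percentages with one decimal, closeness
scores with three; full precision is kept internally.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, classification, indicators, topsis, travel
from .io import load_dataset, write_dataset
from .synthetic import DrawSpec, RegionConfig, generate_region

__all__ = ["RunConfig", "RunReport", "run_full_analysis", "write_reachability",
           "read_reachability", "scale_tables"]

ANALYSIS_FILES = (
    "reachability.csv",
    "indicators.csv",
    "gap_classes.csv",
    "scale_table.csv",
    "topsis_scores.csv",
    "topsis_summary.csv",
    "correlations.csv",
)


@dataclass
class RunConfig:
    """Everything one full analysis run needs.

    Either ``generator`` (a synthetic study area) or ``dataset_dir``
    (CSV inputs) must be provided.  ``seed`` overrides the generator and
    bootstrap seeds so one flag controls all randomness of a run.
    """

    generator: RegionConfig | None = field(default_factory=RegionConfig)
    dataset_dir: str | None = None
    access: travel.AccessConfig = field(default_factory=travel.AccessConfig)
    rule: classification.ScaleRule = field(default_factory=classification.ScaleRule)
    weights: topsis.WeightScheme = field(default_factory=topsis.WeightScheme)
    bootstrap: association.BootstrapConfig = field(
        default_factory=association.BootstrapConfig
    )
    cumulative_bands: bool = True
    geojson: bool = False
    seed: int | None = None

    def resolved(self) -> "RunConfig":
        if self.seed is None:
            return self
        out = RunConfig(**{**self.__dict__})
        if out.generator is not None:
            out.generator = RegionConfig(**{**out.generator.__dict__, "seed": self.seed})
        out.bootstrap = association.BootstrapConfig(
            n_resamples=out.bootstrap.n_resamples,
            confidence=out.bootstrap.confidence,
            seed=self.seed,
            degenerate_policy=out.bootstrap.degenerate_policy,
        )
        return out

    def to_dict(self) -> dict:
        def spec(s: DrawSpec) -> dict:
            return {"dist": s.dist, "params": dict(s.params)}

        out: dict = {
            "dataset_dir": self.dataset_dir,
            "cumulative_bands": self.cumulative_bands,
            "geojson": self.geojson,
            "seed": self.seed,
        }
        if self.generator is not None:
            g = self.generator
            out["generator"] = {
                "n_regions": g.n_regions,
                "districts_per_region": list(g.districts_per_region),
                "municipalities_per_district": list(g.municipalities_per_district),
                "recipients_per_municipality": spec(g.recipients_per_municipality),
                "facility_density": dict(g.facility_density),
                "capacity_spec": {k: spec(v) for k, v in g.capacity_spec.items()},
                "road_edge_minutes": spec(g.road_edge_minutes),
                "transit_coverage": g.transit_coverage,
                "seed": g.seed,
            }
        a = self.access
        out["access"] = {
            "bands": list(a.bands),
            "arrival_times": {k: list(v) for k, v in a.arrival_times.items()},
            "weekday": a.weekday,
            "pt_max_minutes": a.pt_max_minutes,
            "pt_max_transfers": a.pt_max_transfers,
            "pt_max_distance_km": a.pt_max_distance_km,
            "arrival_tolerance_min": a.arrival_tolerance_min,
            "weighing_weights": a.weights.as_dict(),
            "it_target": a.it_target,
        }
        out["scale"] = {
            "good_min_cov30": self.rule.good_min_cov30,
            "lowered_min_cov30": self.rule.lowered_min_cov30,
            "poor_max_cov60": self.rule.poor_max_cov60,
            "basis": self.rule.basis,
        }
        out["weights"] = {k: list(v) for k, v in self.weights.group_weights.items()}
        out["bootstrap"] = {
            "n_resamples": self.bootstrap.n_resamples,
            "confidence": self.bootstrap.confidence,
            "seed": self.bootstrap.seed,
            "degenerate_policy": self.bootstrap.degenerate_policy,
        }
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def spec(d: dict) -> DrawSpec:
            return DrawSpec(d["dist"], dict(d["params"]))

        kwargs: dict = {}
        if data.get("generator") is not None:
            g = data["generator"]
            kwargs["generator"] = RegionConfig(
                n_regions=g.get("n_regions", 13),
                districts_per_region=tuple(g.get("districts_per_region", (3, 12))),
                municipalities_per_district=tuple(
                    g.get("municipalities_per_district", (6, 12))
                ),
                recipients_per_municipality=(
                    spec(g["recipients_per_municipality"])
                    if "recipients_per_municipality" in g
                    else RegionConfig().recipients_per_municipality
                ),
                facility_density=g.get(
                    "facility_density", RegionConfig().facility_density
                ),
                capacity_spec=(
                    {k: spec(v) for k, v in g["capacity_spec"].items()}
                    if "capacity_spec" in g
                    else RegionConfig().capacity_spec
                ),
                road_edge_minutes=(
                    spec(g["road_edge_minutes"])
                    if "road_edge_minutes" in g
                    else RegionConfig().road_edge_minutes
                ),
                transit_coverage=g.get("transit_coverage", 0.35),
                seed=g.get("seed", 0),
            )
        elif data.get("dataset_dir"):
            kwargs["generator"] = None
        kwargs["dataset_dir"] = data.get("dataset_dir")
        if "access" in data:
            a = data["access"]
            kwargs["access"] = travel.AccessConfig(
                bands=tuple(a.get("bands", (30.0, 60.0))),
                arrival_times={
                    k: tuple(v) for k, v in a.get(
                        "arrival_times",
                        {"residential": (840,), "clinic": (420, 480)},
                    ).items()
                },
                weekday=a.get("weekday", "Tuesday"),
                pt_max_minutes=a.get("pt_max_minutes", 90.0),
                pt_max_transfers=a.get("pt_max_transfers", 5),
                pt_max_distance_km=a.get("pt_max_distance_km", 150.0),
                arrival_tolerance_min=a.get("arrival_tolerance_min", 0),
                weights=travel.WeighingWeights(
                    **a.get("weighing_weights", {})
                ),
                it_target=a.get("it_target", "municipality"),
            )
        if "scale" in data:
            kwargs["rule"] = classification.ScaleRule(**data["scale"])
        if "weights" in data:
            kwargs["weights"] = topsis.WeightScheme(
                {k: tuple(v) for k, v in data["weights"].items()}
            )
        if "bootstrap" in data:
            kwargs["bootstrap"] = association.BootstrapConfig(**data["bootstrap"])
        kwargs["cumulative_bands"] = data.get("cumulative_bands", True)
        kwargs["geojson"] = data.get("geojson", False)
        kwargs["seed"] = data.get("seed")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class RunReport:
    manifest: dict[str, str]
    seed: int | None
    config_hash: str
    timings: dict[str, float]
    warnings: list[str]

    def to_dict(self) -> dict:
        return {
            "manifest": self.manifest,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "timings": self.timings,
            "warnings": self.warnings,
        }


def write_reachability(reach: pd.DataFrame, path: str | Path) -> None:
    out = reach.copy()
    out["minutes"] = out["minutes"].map(
        lambda v: "" if math.isinf(v) else f"{v:.3f}".rstrip("0").rstrip(".")
    )
    out.to_csv(path, index=False)


def read_reachability(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["minutes"] = pd.to_numeric(df["minutes"], errors="coerce").fillna(math.inf)
    for col in df.columns:
        if col.startswith("within"):
            df[col] = df[col].astype(bool)
    return df


def scale_tables(class_df: pd.DataFrame, district_region: dict[str, str]) -> pd.DataFrame:
    """Stacked per-(service class, mode) regional scale tables.

    Residential slices round the Total row to one decimal; clinic slices
    to integers, mirroring the published tables.
    """
    blocks = []
    for (cls, mode), sub in class_df.groupby(["service_class", "mode"]):
        decimals = 1 if cls == "residential" else 0
        classes = dict(zip(sub["district_id"], sub["gap_class"]))
        regions = {d: district_region[d] for d in classes}
        tbl = classification.aggregate_scale_table(classes, regions, decimals=decimals)
        tbl = tbl.reset_index()
        tbl.insert(0, "service_class", cls)
        tbl.insert(1, "mode", mode)
        blocks.append(tbl)
    return pd.concat(blocks, ignore_index=True)


def run_full_analysis(config: RunConfig, outdir: str | Path) -> RunReport:
    """Execute the three-phase pipeline and write all result tables.

    Stages run in order (reachability, indicators, classification,
    TOPSIS, correlation); a failure aborts with the stage name attached.
    Deterministic given the configured seed.
    """
    config = config.resolved()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    timings: dict[str, float] = {}
    caught: list[str] = []

    def stage(name: str):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                self.ctx = warnings.catch_warnings(record=True)
                self.records = self.ctx.__enter__()
                warnings.simplefilter("always")
                return self

            def __exit__(self, exc_type, exc, tb):
                self.ctx.__exit__(None, None, None)
                timings[name] = time.perf_counter() - self.t0
                for w in self.records:
                    caught.append(f"{name}: {w.message}")
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Stage()

    with stage("dataset"):
        if config.dataset_dir is not None:
            ds = load_dataset(config.dataset_dir)
        elif config.generator is not None:
            ds = generate_region(config.generator)
            for name, path in write_dataset(ds, outdir, geojson=config.geojson).items():
                manifest[name] = str(path)
        else:
            raise ValueError("RunConfig needs a generator or a dataset_dir")

    with stage("travel_access"):
        reach = travel.compute_reachability(ds, config.access)
        path = outdir / "reachability.csv"
        write_reachability(reach, path)
        manifest["reachability.csv"] = str(path)

    with stage("indicators"):
        table = indicators.indicator_table(
            ds, reach, bands=config.access.bands[:2],
            cumulative=config.cumulative_bands,
        )
        path = outdir / "indicators.csv"
        export = table.copy()
        for col in indicators.COVERAGE_COLUMNS:
            export[col] = export[col].round(1)
        export.to_csv(path)
        manifest["indicators.csv"] = str(path)

    with stage("gap_classification"):
        cov = table[indicators.COVERAGE_COLUMNS]
        class_df = classification.classify_dataset(ds, cov, config.rule)
        path = outdir / "gap_classes.csv"
        class_df.to_csv(path, index=False)
        manifest["gap_classes.csv"] = str(path)
        district_region = {d.id: d.region_id for d in ds.districts}
        tables = scale_tables(class_df, district_region)
        path = outdir / "scale_table.csv"
        tables.to_csv(path, index=False)
        manifest["scale_table.csv"] = str(path)

    with stage("topsis_ranking"):
        scores = topsis.group_scores(table, config.weights)
        scores["MTci"] = topsis.mean_total(scores)
        ranks = pd.DataFrame(index=scores.index)
        for col in scores.columns:
            label = col.replace("ci", "") if col != "MTci" else "MT"
            order = sorted(scores.index, key=lambda a: (-scores.at[a, col], str(a)))
            ranks[f"rank_{label}"] = pd.Series(
                {a: i + 1 for i, a in enumerate(order)}
            )
        export = scores.round(3).join(ranks)
        path = outdir / "topsis_scores.csv"
        export.to_csv(path)
        manifest["topsis_scores.csv"] = str(path)
        summary = topsis.summarize_scores(scores)
        path = outdir / "topsis_summary.csv"
        summary.to_csv(path)
        manifest["topsis_summary.csv"] = str(path)

    with stage("association"):
        corr_input = table[["X1", "X2", "X3"]].join(
            scores[[f"{g}ci" for g in indicators.GROUPS]].rename(
                columns={f"{g}ci": g for g in indicators.GROUPS}
            )
        ).dropna()
        constant = [c for c in corr_input.columns if corr_input[c].nunique() <= 1]
        if constant:
            warnings.warn(
                f"dropping zero-variance indicator(s) from the correlation "
                f"matrix: {constant}",
                UserWarning,
            )
            corr_input = corr_input.drop(columns=constant)
        corr = association.correlation_matrix(corr_input, config.bootstrap)
        path = outdir / "correlations.csv"
        corr.to_csv(path, index=False)
        manifest["correlations.csv"] = str(path)

    report = RunReport(
        manifest=manifest,
        seed=config.seed if config.seed is not None else (
            config.generator.seed if config.generator else None
        ),
        config_hash=config.config_hash(),
        timings={k: round(v, 4) for k, v in timings.items()},
        warnings=caught,
    )
    (outdir / "run_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return report
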