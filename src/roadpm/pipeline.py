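"""End-to-end pipeline: data -> weights -> panel models -> GTWR -> attribution."""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .attribution import (
    attributable_deaths,
    contribution,
    propagate_mortality,
)
from .gtwr import GTWR, Bandwidth, STKernelParams
from .lattice import make_lattice, read_geojson, write_geojson
from .panel import (
    FixedEffectsPanel,
    SpatialPanel,
    panel_diagnostics,
    robust_lm_tests,
)
from .panel_data import CountyPanel, ModelSpec, MortalityPanel, read_panel
from .synthetic import DGPParams, simulate_baseline_mortality, simulate_panel
from .weights import queen_contiguity

logger = logging.getLogger("roadpm")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``inputs`` (paths to panel CSV / geometry GeoJSON /
    baseline mortality CSV) or ``synthetic`` (lattice + DGP block) must be
    given. All defaults reproduce the bundled synthetic study: a 10x10
    lattice observed 2003-2016.
    """

    synthetic: dict | None = field(
        default_factory=lambda: {
            "n_rows": 10,
            "n_cols": 10,
            "cell_km": 50.0,
            "year_start": 2003,
            "year_end": 2016,
            "lambda_lag": 0.4,
            "rho_error": 0.3,
            "sigma_nu": 0.8,
            "sigma_alpha": 1.0,
            "beta": [0.646, 0.045, -1.5],
            "regressors": ["co2_per_km2", "developed_open_pct", "pop_density_1k_km2"],
            "mode": "constant",
            "mortality_total": 54730.0,
        }
    )
    inputs: dict | None = None
    spec: dict = field(
        default_factory=lambda: {
            "dependent": "pm25",
            "regressors": ["co2_per_km2", "developed_open_pct", "pop_density_1k_km2"],
        }
    )
    variants: list = field(default_factory=lambda: ["fem", "lag", "error", "sac"])
    gtwr: dict = field(
        default_factory=lambda: {
            "select_bandwidth": False,
            "k": 120,
            "tau": 50.0,
            "k_candidates": [60, 120, 240],
            "tau_candidates": [10.0, 50.0, 200.0],
        }
    )
    attribution: dict = field(
        default_factory=lambda: {
            "cpd": 0.012,
            "anchor_year": 2010,
            "co2_averaging": "yearly",
            "level": "county",
        }
    )
    year_range: list | None = None
    seed: int = 0
    outdir: str = "roadpm_run"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' or 'inputs' must be configured")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; expected {sorted(known)}")
        base = cls() if "synthetic" in raw or "inputs" not in raw else cls(synthetic=None, inputs=raw["inputs"])
        merged = asdict(base)
        for k, v in raw.items():
            if isinstance(v, dict) and isinstance(merged.get(k), dict):
                merged[k] = {**merged[k], **v}
            else:
                merged[k] = v
        if "inputs" in raw and raw["inputs"] is not None:
            merged["synthetic"] = None
        return cls(**merged)

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            dependent=self.spec.get("dependent", "pm25"),
            regressors=list(self.spec["regressors"]),
        )


@dataclass
class RunManifest:
    """Provenance record of a pipeline run."""

    config: dict
    version: str
    seed: int
    stage_seconds: dict
    warnings: list
    outputs: dict  # filename -> sha256
    key_results: dict

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, default=_jsonable)

    def verify(self, outdir) -> bool:
        outdir = Path(outdir)
        for name, digest in self.outputs.items():
            f = outdir / name
            if not f.exists() or _sha256(f) != digest:
                return False
        return True


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and write all artifacts plus a manifest.

    Deterministic: identical configs (including seed) yield byte-identical
    outputs and therefore identical manifest hashes.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_seconds: dict[str, float] = {}
    caught: list[str] = []
    outputs: dict[str, str] = {}
    key_results: dict[str, float] = {}
    manifest = RunManifest(
        config=asdict(config),
        version=__version__,
        seed=config.seed,
        stage_seconds=stage_seconds,
        warnings=caught,
        outputs=outputs,
        key_results=key_results,
    )

    def stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                self_inner.wctx = warnings.catch_warnings(record=True)
                self_inner.records = self_inner.wctx.__enter__()
                warnings.simplefilter("always")
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                stage_seconds[name] = round(time.perf_counter() - self_inner.t0, 4)
                for w in self_inner.records:
                    caught.append(f"{name}: {w.message}")
                self_inner.wctx.__exit__(None, None, None)
                if exc is not None:
                    manifest.to_json(outdir / "manifest.partial.json")
                    raise PipelineError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, stage_seconds[name])
                return False

        return _Ctx()

    def emit(name):
        outputs[name] = _sha256(outdir / name)

    spec = config.model_spec()

    # ---- data ----------------------------------------------------------
    with stage("data"):
        if config.synthetic is not None:
            s = config.synthetic
            geometry = make_lattice(int(s["n_rows"]), int(s["n_cols"]), float(s["cell_km"]))
            weights_raw = queen_contiguity(geometry)
            params = DGPParams(
                beta=s.get("beta", [0.646]),
                regressors=tuple(s.get("regressors", ["co2_per_km2"])),
                lambda_lag=float(s.get("lambda_lag", 0.0)),
                rho_error=float(s.get("rho_error", 0.0)),
                sigma_nu=float(s.get("sigma_nu", 1.0)),
                sigma_alpha=float(s.get("sigma_alpha", 0.5)),
                mode=s.get("mode", "constant"),
                covariate_style=s.get("covariate_style", "realistic"),
                seed=config.seed,
            )
            years = range(int(s["year_start"]), int(s["year_end"]) + 1)
            panel = simulate_panel(geometry, years, params, weights_raw.row_standardize())
            anchor = int(config.attribution.get("anchor_year", panel.years[len(panel.years) // 2]))
            mortality = simulate_baseline_mortality(
                panel, anchor, float(s.get("mortality_total", 54730.0)), seed=config.seed + 1
            )
            write_geojson(geometry, outdir / "geometry.geojson")
            with open(outdir / "dgp_params.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "seed": config.seed,
                        "beta": list(map(float, params.beta)),
                        "regressors": list(params.regressors),
                        "lambda_lag": params.lambda_lag,
                        "rho_error": params.rho_error,
                        "sigma_nu": params.sigma_nu,
                        "sigma_alpha": params.sigma_alpha,
                        "mode": params.mode,
                    },
                    fh,
                    indent=2,
                )
            emit("dgp_params.json")
        else:
            paths = config.inputs
            panel = read_panel(paths["panel_csv"])
            geometry = read_geojson(paths["geometry_geojson"])
            weights_raw = queen_contiguity(geometry)
            mortality = MortalityPanel.from_csv(paths["mortality_csv"])
            write_geojson(geometry, outdir / "geometry.geojson")
        if config.year_range:
            panel = panel.restrict_years(*config.year_range)
        panel.to_csv(outdir / "panel.csv")
        emit("panel.csv")
        emit("geometry.geojson")

    # ---- weights -------------------------------------------------------
    with stage("weights"):
        weights = weights_raw.row_standardize()
        weights_raw.to_gal(outdir / "weights.gal")
        weights.to_triplets(outdir / "weights_row_standardized.csv")
        emit("weights.gal")
        emit("weights_row_standardized.csv")

    # ---- FEM + diagnostics --------------------------------------------
    with stage("fem"):
        fem = FixedEffectsPanel(panel, spec).fit()
        with open(outdir / "fem.json", "w", encoding="utf-8") as fh:
            json.dump(fem.to_dict(), fh, indent=2)
        emit("fem.json")
        key_results["fem_rsquared_within"] = float(fem.rsquared_within)

    with stage("diagnostics"):
        report = panel_diagnostics(panel, spec)
        report = report.merge(robust_lm_tests(fem, weights))
        report.to_frame().to_csv(outdir / "diagnostics.csv", index=False)
        emit("diagnostics.csv")
        key_results["recommended_model"] = report.recommended_model()
        logger.info("recommended model: %s", key_results["recommended_model"])

    # ---- spatial panel fits -------------------------------------------
    with stage("spatial_panels"):
        for variant in config.variants:
            if variant == "fem":
                continue
            fit = SpatialPanel(panel, weights, spec, variant=variant).fit()
            payload = fit.to_dict()
            if fit.lambda_lag is not None:
                imp = fit.impacts(n_terms=500)
                payload["impacts"] = imp.table.to_dict(orient="index")
            with open(outdir / f"spatial_{variant}.json", "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=2)
            emit(f"spatial_{variant}.json")
            if variant == "sac":
                key_results["sac_lambda"] = float(fit.lambda_lag)
                key_results["sac_rho"] = float(fit.rho_error)
                logger.info(
                    "sac fit: lambda=%.4f rho=%.4f", fit.lambda_lag, fit.rho_error
                )

    # ---- GTWR ----------------------------------------------------------
    with stage("gtwr"):
        g = config.gtwr
        model = GTWR(panel, spec)
        if g.get("select_bandwidth", False):
            bw = model.select_bandwidth(g["k_candidates"], g["tau_candidates"])
        else:
            bw = Bandwidth(k=int(g["k"]), params=STKernelParams(1.0, float(g.get("tau", 1.0))))
        gfit = model.fit(bw)
        gfit.to_csv(outdir / "gtwr_local.csv")
        with open(outdir / "gtwr_meta.json", "w", encoding="utf-8") as fh:
            json.dump(gfit.metadata(), fh, indent=2)
        emit("gtwr_local.csv")
        emit("gtwr_meta.json")
        key_results["gtwr_k"] = int(gfit.bandwidth.k)
        key_results["gtwr_tau"] = float(gfit.bandwidth.params.tau)
        key_results["gtwr_rsquared"] = float(gfit.rsquared)
        logger.info(
            "gtwr: k=%d tau=%.3g R2=%.4f",
            gfit.bandwidth.k,
            gfit.bandwidth.params.tau,
            gfit.rsquared,
        )

    # ---- attribution ---------------------------------------------------
    with stage("attribution"):
        a = config.attribution
        surface = contribution(gfit, panel, co2_averaging=a.get("co2_averaging", "yearly"))
        surface.df.to_csv(outdir / "contribution.csv", index=False)
        emit("contribution.csv")
        full_mortality = propagate_mortality(
            mortality,
            panel,
            cpd=float(a.get("cpd", 0.012)),
            anchor_year=a.get("anchor_year"),
            level=a.get("level", "county"),
        )
        full_mortality.to_csv(outdir / "mortality.csv")
        emit("mortality.csv")
        result = attributable_deaths(full_mortality, surface)
        result.county_year.to_csv(outdir / "attribution_county_year.csv", index=False)
        result.yearly.to_csv(outdir / "attribution_yearly.csv", index=False)
        emit("attribution_county_year.csv")
        emit("attribution_yearly.csv")
        key_results["pta_pooled_pct"] = float(result.pta_pooled_pct)
        key_results["mean_contribution_pct"] = float(surface.clamped.mean())
        logger.info("pooled on-road share of deaths: %.2f%%", result.pta_pooled_pct)

    manifest.to_json(outdir / "manifest.json")
    return manifest
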