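"""Run configuration, input validation, and the end-to-end pipeline.

A run is described by a YAML/JSON config (paths, model settings, prior
overrides, seeds, ESDA options).  ``run_pipeline`` chains every stage —
simulate (or load) -> weights -> ESDA -> dispersion screen -> MCMC fits
of the four competing structures -> WAIC/LOO comparison -> relative-risk
map — into one output directory with a provenance manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("spatialnb")

DEFAULT_MODELS = ("glm", "glmm", "icar", "bym")


@dataclass
class RunConfig:
    """Validated settings for a pipeline run."""

    output_dir: str = "run"
    data_path: str | None = None      # None -> simulate
    weights_path: str | None = None
    geometry_path: str | None = None
    models: tuple[str, ...] = DEFAULT_MODELS
    chains: int = 1
    iterations: int = 1000
    warmup: int = 500
    seed: int = 0
    n_regions: int = 11
    clusters_per_region: int = 10
    n_permutations: int = 199
    priors: dict = field(default_factory=dict)
    true_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.iterations <= self.warmup:
            raise ValueError("iterations must exceed warmup")
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        for path in (self.data_path, self.weights_path, self.geometry_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)
        self.models = tuple(self.models)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def validate_inputs(data: pd.DataFrame, W=None) -> list[str]:
    """Check study-table and weight-matrix invariants; return the list of
    violations (empty for a clean input)."""
    problems = []
    required = ["cluster_id", "region_id", "y"]
    for col in required:
        if col not in data.columns:
            problems.append(f"missing column {col!r}")
    if not problems:
        y = data["y"].to_numpy()
        bad = np.flatnonzero((y < 0) | (y != np.round(y)))
        problems.extend(f"row {i}: count y={y[i]} is not a non-negative integer" for i in bad[:20])
        if data["cluster_id"].duplicated().any():
            dup = data.loc[data["cluster_id"].duplicated(), "cluster_id"].tolist()[:10]
            problems.append(f"duplicate cluster_id values: {dup}")
        rid = data["region_id"].to_numpy()
        if (rid < 1).any():
            problems.append("region_id values must be 1-based positive integers")
        if W is not None and rid.max() > W.n:
            problems.append(f"region_id {rid.max()} exceeds weight-matrix order {W.n}")
    if W is not None:
        if not W.standardized and not np.allclose(W.w, W.w.T):
            problems.append("weight matrix is asymmetric")
        if np.diagonal(W.w).any():
            problems.append("weight matrix has nonzero diagonal entries")
        if (W.w < 0).any():
            problems.append("weight matrix has negative entries")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write a provenance manifest.

    Returns the manifest dict; any stage failure raises with the stage
    name attached.
    """
    from . import synthetic, weights as wmod, esda, dispersion, mcmc, evaluation, riskmap

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": [], "seed": int(config.seed), "config": {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()
    }}
    stage = "start"
    try:
        # ------------------------------------------------------------ data
        stage = "simulate"
        if config.data_path is None:
            tp_kwargs = dict(config.true_params)
            tp_kwargs.setdefault("n_regions", config.n_regions)
            tp_kwargs.setdefault("clusters_per_region", config.clusters_per_region)
            tp_kwargs.setdefault("seed", config.seed)
            if "beta" in tp_kwargs:
                tp_kwargs["beta"] = tuple(tp_kwargs["beta"])
            params = synthetic.TrueParams(**tp_kwargs)
            table, W, truth = synthetic.simulate_study(params)
            synthetic.write_study_table(table, out / "study.csv")
            params.to_json(out / "true_params.json")
            wmod.write_edge_list(truth["edges"], out / "region_graph.txt")
        else:
            table = synthetic.read_study_table(config.data_path)
            if config.weights_path is None:
                raise ValueError("weights_path required when loading real data")
            W = wmod.read_weight_matrix(config.weights_path, scheme="queen")
        problems = validate_inputs(table, W)
        if problems:
            raise ValueError(f"input validation failed: {problems}")
        manifest["stages"].append({"name": stage, "n_clusters": len(table), "n_regions": W.n})

        # --------------------------------------------------------- weights
        stage = "weights"
        wmod.write_weight_matrix(W, out / "weights.txt", out / "weights.csv")
        region_y = table.groupby("region_id")["y"].sum().to_numpy(dtype=float)
        manifest["stages"].append({"name": stage, "scheme": W.scheme})

        # ------------------------------------------------------------ esda
        stage = "esda"
        Wstd = wmod.row_standardize(W)
        glob = esda.morans_i_permutation(region_y, Wstd, n_perm=config.n_permutations, seed=config.seed)
        local = esda.local_morans_i(region_y, Wstd, n_perm=config.n_permutations, seed=config.seed)
        gstar = esda.getis_ord_gstar(region_y, Wstd)
        coords = table[["lat", "lon"]].to_numpy()
        center, sdist = esda.mean_center_and_standard_distance(coords, weights=table["y"].to_numpy())
        report = {
            "morans_i": glob.statistic, "p_value": glob.p_value,
            "expected_i": -1.0 / (W.n - 1) if W.n > 1 else None,
            "mean_center": center.tolist(), "standard_distance": sdist,
        }
        (out / "esda.json").write_text(json.dumps(report, indent=2))
        local.join(gstar).to_csv(out / "esda_local.csv")
        manifest["stages"].append({"name": stage, "morans_i": glob.statistic, "p": glob.p_value})

        # ------------------------------------------------------ dispersion
        stage = "dispersion"
        covars = [c for c in table.columns if c not in
                  ("cluster_id", "region_id", "lat", "lon", "y", "intercept")]
        X = np.column_stack([np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in covars])
        disp = {
            fam: dispersion.overdispersion_ratios(table["y"].to_numpy(), X, family=fam).to_dict()
            for fam in ("poisson", "negbin")
        }
        (out / "dispersion.json").write_text(json.dumps(disp, indent=2))
        manifest["stages"].append({"name": stage,
                                   "poisson_ratio": disp["poisson"]["ratio_pearson"]})

        # ------------------------------------------------------------ fits
        stage = "fit"
        prior_cfg = mcmc.PriorConfig(**{k: tuple(v) for k, v in config.priors.items()})
        fits = {}
        for m in config.models:
            spec = mcmc.ModelSpec(structure=m, formula=tuple(covars),
                                  W=W if m in ("icar", "bym", "leroux", "stern_cressie") else None)
            log.info("fitting %s", m)
            fits[m] = mcmc.sample_posterior(
                table, spec, prior_cfg, chains=config.chains,
                iterations=config.iterations, warmup=config.warmup, seed=config.seed,
            )
            summary = mcmc.fit_summary(
                fits[m],
                params=[p for p in fits[m].parameter_names() if not p.startswith(("u[", "phi["))],
            )
            summary.to_csv(out / f"fit_{m}_summary.csv")
            fits[m].to_long_dataframe().to_csv(out / f"fit_{m}_draws.csv", index=False)
        manifest["stages"].append({"name": stage, "models": list(config.models)})

        # --------------------------------------------------------- compare
        stage = "compare"
        comparison = evaluation.compare_models(fits)
        comparison.to_csv(out / "comparison.csv")
        best = comparison.index[0]
        manifest["stages"].append({"name": stage, "best": best,
                                   "waic": {m: float(comparison.loc[m, "waic"]) for m in comparison.index}})

        # ------------------------------------------------------------- map
        stage = "map"
        spatial_fits = [m for m in config.models if m != "glm"]
        map_model = best if best in spatial_fits else (spatial_fits[0] if spatial_fits else None)
        if map_model is not None:
            rr = riskmap.relative_risk(fits[map_model], area_level="region")
            geometry = None
            if config.geometry_path:
                geometry = json.loads(Path(config.geometry_path).read_text())
            riskmap.export_map(rr, geometry, out_prefix=str(out / "risk"))
            eff = riskmap.effect_table(fits[map_model])
            eff.to_csv(out / "effects.csv")
        manifest["stages"].append({"name": stage, "model": map_model})

    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        (out / "failed_stage.json").write_text(json.dumps({"stage": stage, "error": str(exc)}))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["files"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
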