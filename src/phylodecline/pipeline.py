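"""End-to-end pipeline: simulate, summarize, prevalence, impute, fit, select,
ensemble, report — with stage caching, derived per-stage seeds, and fully
serialized configuration so identical config + seed gives identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geo, prevalence as prev_mod, report as report_mod
from .impute import impute as run_impute, loo_validate
from .gridio import read_ascii_grid, write_ascii_grid
from .model import association_test
from .selection import all_subsets_dic, ensemble_fit, select_by_dic
from .synthetic import ClimateWorld, WorldConfig, generate_dataset
from .trees import parse_newick, perturb_topology, write_newick

log = logging.getLogger("phylodecline")

STAGES = [
    "simulate", "summarize", "prevalence", "impute",
    "fit", "select", "ensemble", "report",
]


def stage_seed(master: int, stage: str) -> int:
    """Named sub-seed derived from the master seed (stable across runs)."""
    digest = hashlib.sha256(f"{stage}:{master}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Everything a run needs; defaults give the small demonstration study."""

    out_dir: str = "run"
    seed: int = 0
    # synthetic world
    n_tips: int = 200
    grid_shape: tuple[int, int] = (40, 40)
    beta_true: tuple = None  # type: ignore[assignment]
    sigma2_p_true: float = 1.0
    subcell_fraction: float = 0.05
    frac_unknown: float = 0.25
    frac_increasing: float = 0.005
    # imputation
    k_eigen: int = 30
    impute_max_iter: int = 10
    loo_max_cells: int | None = 30
    loo_max_iter: int = 5
    # chains
    final_chain: dict = field(
        default_factory=lambda: {"iterations": 10_000, "burnin": 2_000, "thin": 8}
    )
    search_chain: dict = field(
        default_factory=lambda: {"iterations": 2_000, "burnin": 400, "thin": 2}
    )
    # selection / ensemble
    selection_policy: str = "parsimony"
    forced_predictors: list = field(default_factory=list)
    n_topologies: int = 3
    # reporting
    min_group: int = 10

    def __post_init__(self):
        if self.beta_true is None:
            from .synthetic import DEFAULT_BETA

            self.beta_true = tuple(DEFAULT_BETA)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.grid_shape = tuple(cfg.grid_shape)
        cfg.beta_true = tuple(cfg.beta_true)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["beta_true"] = list(self.beta_true)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def _encode_cells(cells) -> str:
    return "|".join(f"{r}:{c}" for r, c in cells) if cells else ""


def _decode_cells(text) -> list[tuple[int, int]]:
    if not isinstance(text, str) or not text:
        return []
    return [tuple(int(v) for v in p.split(":")) for p in text.split("|")]


def _summary_frame(results) -> dict:
    df = results.summary()
    return {
        name: {
            "post_mean": float(row.post_mean),
            "post_sd": float(row.post_sd),
            "ci_low": float(row.ci_low),
            "ci_high": float(row.ci_high),
            "ess": float(row.ess),
            "significant": bool(row.significant),
        }
        for name, row in df.iterrows()
    }


class Pipeline:
    """Runs the stages, caching outputs under ``config.out_dir``."""

    def __init__(self, config: RunConfig, force: bool = False):
        self.cfg = config
        self.force = force
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(self.out / "effective_config.yaml")

    # -- cache helpers -------------------------------------------------------

    def _fresh(self, *names: str) -> bool:
        """True if the stage must run (some output missing or forced)."""
        return self.force or not all((self.out / n).exists() for n in names)

    def _run_stage(self, name: str, outputs: list[str], fn) -> bool:
        if not self._fresh(*outputs):
            log.info("stage %-10s cached", name)
            return False
        t0 = time.time()
        fn()
        log.info(
            "stage %-10s seed=%d wall=%.1fs",
            name, stage_seed(self.cfg.seed, name), time.time() - t0,
        )
        return True

    # -- readers -------------------------------------------------------------

    def _read_world(self) -> ClimateWorld:
        meta = json.loads((self.out / "world.json").read_text())
        layers = {}
        for name in ("amt", "tar", "cmi"):
            layers[name], _ = read_ascii_grid(self.out / f"{name}.asc")
        return ClimateWorld(
            cell_area_km2=meta["cell_area_km2"],
            lat_centers=np.array(meta["lat_centers"]),
            layers=layers,
            land_mask=np.isfinite(layers["amt"]),
        )

    def _read_tree(self):
        return parse_newick((self.out / "tree.nwk").read_text())

    def _read_table(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.out / name, sep="\t", index_col="species")

    def _write_table(self, df: pd.DataFrame, name: str) -> None:
        df.to_csv(self.out / name, sep="\t", index_label="species")

    # -- stages --------------------------------------------------------------

    def simulate(self) -> None:
        cfg = self.cfg
        wc = WorldConfig(
            n_tips=cfg.n_tips,
            grid_shape=cfg.grid_shape,
            beta_true=cfg.beta_true,
            sigma2_p_true=cfg.sigma2_p_true,
            subcell_fraction=cfg.subcell_fraction,
            frac_unknown=cfg.frac_unknown,
            frac_increasing=cfg.frac_increasing,
            seed=stage_seed(cfg.seed, "simulate"),
        )
        ds = generate_dataset(wc)
        (self.out / "tree.nwk").write_text(write_newick(ds.tree))
        for name, layer in ds.world.layers.items():
            write_ascii_grid(self.out / f"{name}.asc", layer)
        _write_json(
            self.out / "world.json",
            {
                "cell_area_km2": ds.world.cell_area_km2,
                "lat_centers": [float(v) for v in ds.world.lat_centers],
                "grid_shape": list(ds.world.grid_shape),
            },
        )
        # field data: what a real study observes before raster extraction
        field_tbl = ds.table[
            ["family", "body_size_mm", "trend", "threat_category",
             "range_size_km2", "abs_lat_mid", "range_unresolvable"]
        ].copy()
        field_tbl["range_cells"] = [
            _encode_cells(ds.ranges[sp].cells) for sp in ds.table.index
        ]
        field_tbl["cmi_available"] = ds.table["cmi_mean"].notna()
        self._write_table(field_tbl, "species.tsv")
        (self.out / "truth.json").write_text(ds.truth.to_json() + "\n")
        latent = ds.table[["liability_true", "u_true"]]
        self._write_table(latent, "truth_latent.tsv")

    def summarize(self) -> None:
        world = self._read_world()
        tbl = self._read_table("species.tsv")
        rows = []
        for sp, row in tbl.iterrows():
            cells = _decode_cells(row["range_cells"])
            amt, tar, cmi = geo.climate_means(cells, world)
            rows.append((amt, tar, cmi))
        tbl[["amt_mean", "tar_mean", "cmi_mean"]] = rows
        tbl.loc[~tbl["cmi_available"].astype(bool), "cmi_mean"] = np.nan
        self._write_table(tbl, "summary.tsv")

    def prevalence(self) -> None:
        world = self._read_world()
        tbl = self._read_table("summary.tsv")
        profiles = {}
        for var in ("amt", "cmi"):
            prof = prev_mod.climate_prevalence(
                world.layers[var], world.land_mask, var
            )
            profiles[var] = prof
            (self.out / f"prevalence_{var}.json").write_text(
                prof.to_json() + "\n"
            )
            pd.DataFrame(
                {
                    "bin_low": prof.bin_edges[:-1],
                    "bin_high": prof.bin_edges[1:],
                    "prevalence": prof.prevalence,
                }
            ).to_csv(self.out / f"prevalence_{var}.tsv", sep="\t", index=False)
            tbl[f"prev_{var}"] = [
                prev_mod.species_prevalence(m, prof)
                for m in tbl[f"{var}_mean"]
            ]
        self._write_table(tbl, "with_prevalence.tsv")

    def impute(self) -> None:
        cfg = self.cfg
        tree = self._read_tree()
        tbl = self._read_table("with_prevalence.tsv")
        seed = stage_seed(cfg.seed, "impute")
        # complete polygon-derived fields are auxiliary features: range size
        # and latitude carry most of the decline signal
        tbl["log_range_size"] = np.log(tbl["range_size_km2"])
        fixed = ["log_range_size", "abs_lat_mid"]
        res = run_impute(
            tbl, tree, k_eigen=min(cfg.k_eigen, len(tbl) - 1),
            max_iter=cfg.impute_max_iter, seed=seed, fixed_cols=fixed,
        )
        out = res.table.drop(columns=["log_range_size"])
        # prevalences of imputed climate means, on the stored profiles
        for var in ("amt", "cmi"):
            prof = prev_mod.PrevalenceProfile.from_json(
                (self.out / f"prevalence_{var}.json").read_text()
            )
            out[f"prev_{var}"] = [
                prev_mod.species_prevalence(m, prof)
                for m in out[f"{var}_mean"]
            ]
        self._write_table(out, "imputed.tsv")
        self._write_table(res.provenance, "imputed_provenance.tsv")
        report = loo_validate(
            tbl, tree, k_eigen=min(cfg.k_eigen, len(tbl) - 1),
            max_iter=cfg.loo_max_iter, seed=seed,
            max_cells_per_column=cfg.loo_max_cells, fixed_cols=fixed,
        )
        _write_json(
            self.out / "imputation_validation.json",
            report.to_dict()
            | {"iterations_used": res.iterations_used,
               "converged": bool(res.converged)},
        )

    def fit(self) -> None:
        """Threat-category association on original and imputed datasets."""
        cfg = self.cfg
        tree = self._read_tree()
        seed = stage_seed(cfg.seed, "fit")
        for tag, name in (("original", "with_prevalence.tsv"),
                          ("imputed", "imputed.tsv")):
            tbl = self._read_table(name)
            res = association_test(
                tbl, tree, seed=seed, **cfg.final_chain
            )
            _write_json(
                self.out / f"association_{tag}.json", _summary_frame(res)
            )

    def _dataset_for_model(self, name: str):
        tbl = self._read_table(name)
        filtered, dropped = geo.filter_trends(tbl)
        # scaling constants come from the full table once, so coefficients
        # stay comparable across subsets and datasets
        pm = geo.build_predictors(tbl)
        design = pm.data.loc[filtered.index].copy()
        design["decline"] = filtered["decline"]
        return design, dropped

    def select(self) -> None:
        cfg = self.cfg
        tree = self._read_tree()
        seed = stage_seed(cfg.seed, "select")
        for tag, name in (("original", "with_prevalence.tsv"),
                          ("imputed", "imputed.tsv")):
            design, dropped = self._dataset_for_model(name)
            dics = all_subsets_dic(
                design, "decline", geo.PREDICTOR_ORDER, tree,
                chain=cfg.search_chain, seed=seed,
            )
            sel = select_by_dic(
                dics,
                policy=cfg.selection_policy,
                forced=cfg.forced_predictors or None,
            )
            _write_json(
                self.out / f"selection_{tag}.json",
                sel.to_dict() | {"dropped_trends": dropped},
            )
            sel.records.assign(
                subset=sel.records["subset"].map(lambda s: "+".join(s) or "(intercept)")
            ).to_csv(self.out / f"selection_{tag}.tsv", sep="\t", index=False)

    def ensemble(self) -> None:
        cfg = self.cfg
        tree = self._read_tree()
        seed = stage_seed(cfg.seed, "ensemble")
        trees = perturb_topology(tree, cfg.n_topologies, seed=seed)
        for tag in ("original", "imputed"):
            selected = json.loads(
                (self.out / f"selection_{tag}.json").read_text()
            )["selected"]
            name = "with_prevalence.tsv" if tag == "original" else "imputed.tsv"
            design, _ = self._dataset_for_model(name)
            summ = ensemble_fit(
                design, "decline", selected, trees,
                chain=cfg.final_chain, seed=seed,
            )
            _write_json(self.out / f"ensemble_{tag}.json", summ.to_dict())

    def report(self) -> None:
        cfg = self.cfg
        tbl = self._read_table("with_prevalence.tsv")
        ts = report_mod.trend_summary(tbl, "family", cfg.min_group)
        ts.per_group.to_csv(self.out / "trend_by_family.tsv", sep="\t")
        xtab = report_mod.crosstab_trend_threat(tbl)
        summary = {
            "totals": {k: int(v) for k, v in ts.totals.items()},
            "n_groups_listed": ts.n_groups_listed,
            "n_groups_suppressed": ts.n_groups_suppressed,
            "crosstab_counts": {
                t: {c: int(v) for c, v in row.items()}
                for t, row in xtab["counts"].iterrows()
            },
            "pct_of_declining_by_category": {
                c: float(v) for c, v in xtab["row_pct"].loc["decreasing"].items()
            },
            "pct_declining_within_category": {
                c: float(v) for c, v in xtab["col_pct"].loc["decreasing"].items()
            },
        }
        _write_json(self.out / "report.json", summary)

    # -- driver --------------------------------------------------------------

    STAGE_OUTPUTS = {
        "simulate": ["tree.nwk", "species.tsv", "amt.asc", "tar.asc",
                     "cmi.asc", "world.json", "truth.json"],
        "summarize": ["summary.tsv"],
        "prevalence": ["with_prevalence.tsv", "prevalence_amt.json",
                       "prevalence_cmi.json", "prevalence_amt.tsv",
                       "prevalence_cmi.tsv"],
        "impute": ["imputed.tsv", "imputed_provenance.tsv",
                   "imputation_validation.json"],
        "fit": ["association_original.json", "association_imputed.json"],
        "select": ["selection_original.json", "selection_imputed.json"],
        "ensemble": ["ensemble_original.json", "ensemble_imputed.json"],
        "report": ["report.json", "trend_by_family.tsv"],
    }

    def run(self, stages: list[str] | None = None) -> Path:
        for stage in stages or STAGES:
            fn = getattr(self, stage)
            self._run_stage(stage, self.STAGE_OUTPUTS[stage], fn)
        return self.out


def run_pipeline(config: RunConfig, force: bool = False,
                 stages: list[str] | None = None) -> Path:
    """Execute the pipeline; cached stages are skipped unless ``force``."""
    return Pipeline(config, force=force).run(stages)
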