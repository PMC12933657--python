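"""End-to-end analysis pipeline.

Stages, in dependency order:

1. ``data`` — simulate a synthetic dataset (or load tree + trait table);
2. ``chrom_rates`` — fit the chromosome CTMC and attach per-tip dysploidy
   rates (column ``r_chrom``);
3. ``trait_rates`` — fit per-trait BM shift models and attach ``r_<var>``
   columns for any rate column not already present;
4. ``ppa`` — build the requested model families, rank them by CICc and
   model-average the standardized path coefficients;
5. ``quasse`` — rank trait-dependent diversification models for the
   chromosome-rate column.

Every artifact is written as delimited text under the output directory and
recorded, with SHA-256 checksums and runtimes, in ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chromevol import fit_chrom_model
from .model_sets import (COLUMN_OF, build_combined_models, build_mean_models,
                         build_rate_models, count_regressions)
from .phylo import read_newick, read_trait_table, validate_species
from .ppa import average_models, fit_model_set, model_set_report
from .quasse import fit_quasse
from .simulate import SimConfig, write_fixture
from .trait_rates import fit_bm_regimes

__all__ = ["PipelineConfig", "run_pipeline"]

_FAMILY_BUILDERS = {
    "rates": build_rate_models,
    "means": build_mean_models,
    "combined": build_combined_models,
}


@dataclass
class PipelineConfig:
    """Validated settings for one pipeline run."""

    out_dir: str
    seed: int = 1
    tree_path: str = None          # load these...
    traits_path: str = None
    sim: SimConfig = None          # ...or simulate
    families: tuple = ("rates",)
    ppa_cutoff: float = 2.0
    lambda_mode: str = "fixed1"
    chrom_shifts: bool = True
    chrom_min_clade: int = 10
    chrom_max_regimes: int = 40
    trait_columns: tuple = ("BIO1", "BIO4", "BIO7", "BIO12", "culm", "spike")
    trait_max_shifts: int = 3
    run_quasse: bool = True
    quasse_bins: int = 128
    quasse_candidates: tuple = (("constant", "constant", "bm"),
                                ("hump", "constant", "bm"))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("sim", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg

    def validate(self):
        have_files = self.tree_path is not None and self.traits_path is not None
        if not have_files and self.sim is None:
            raise ValueError("config must give tree+traits paths or a sim block")
        bad = [f for f in self.families if f not in _FAMILY_BUILDERS]
        if bad:
            raise ValueError(f"unknown model families {bad}")


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


class _Manifest:
    def __init__(self, config):
        self.stages = []
        self.artifacts = {}
        self.config = config

    def stage(self, name):
        return _StageTimer(self, name)

    def add(self, name, path):
        self.artifacts[name] = {"path": path, "sha256": _sha256(path)}

    def write(self, out_dir, seed):
        payload = {
            "divpath_version": __version__,
            "seed": seed,
            "stages": self.stages,
            "artifacts": self.artifacts,
        }
        path = os.path.join(out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        return path


class _StageTimer:
    def __init__(self, manifest, name):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        entry = {"stage": self.name,
                 "seconds": round(time.perf_counter() - self.t0, 3),
                 "ok": exc_type is None}
        self.manifest.stages.append(entry)
        if exc_type is not None:
            entry["error"] = str(exc)
        return False


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dictionary.

    Any stage failure aborts the run with the stage name in the exception;
    artifacts from completed stages stay on disk.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    with open(os.path.join(config.out_dir, "config_echo.yaml"), "w") as fh:
        echo = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(config).items() if k != "sim"}
        if config.sim is not None:
            echo["sim"] = {k: v for k, v in vars(config.sim).items()
                           if not hasattr(v, "__dict__")}
        yaml.safe_dump(echo, fh)
    man = _Manifest(config)
    rng = np.random.default_rng(config.seed)

    with man.stage("data"):
        if config.sim is not None:
            paths = write_fixture(config.sim, config.out_dir)
            tree = read_newick(paths["tree"])
            table = read_trait_table(paths["traits"])
            man.add("tree", paths["tree"])
            man.add("traits", paths["traits"])
        else:
            tree = read_newick(config.tree_path)
            table = read_trait_table(config.traits_path)
        diff = validate_species(table, tree)
        if diff["missing_from_table"] or diff["extra_in_table"]:
            raise ValueError(f"tree/table mismatch: {diff}")

    with man.stage("chrom_rates"):
        chrom_fit = fit_chrom_model(
            tree, table["chrom_n"], allow_shifts=config.chrom_shifts,
            min_clade=config.chrom_min_clade,
            max_regimes=config.chrom_max_regimes,
            seed=int(rng.integers(2**31 - 1)),
        )
        table["r_chrom"] = chrom_fit.tip_rates()
        regime_rows = [{"regime": r, **vars(p)} for r, p in chrom_fit.params.items()]
        regimes_path = os.path.join(config.out_dir, "chrom_regimes.csv")
        pd.DataFrame(regime_rows).to_csv(regimes_path, index=False)
        man.add("chrom_regimes", regimes_path)

    with man.stage("trait_rates"):
        for col in config.trait_columns:
            rate_col = f"r_{col}"
            if rate_col in table.columns:
                continue
            model = fit_bm_regimes(tree, table[col], config.trait_max_shifts,
                                   trait=col)
            table[rate_col] = model.tip_rates().to_numpy()
        traits_out = os.path.join(config.out_dir, "traits_with_rates.csv")
        table.to_csv(traits_out)
        man.add("traits_with_rates", traits_out)

    with man.stage("ppa"):
        for family in config.families:
            model_set = _FAMILY_BUILDERS[family]()
            data = pd.DataFrame(
                {node: table[COLUMN_OF[node]] for node in model_set.nodes},
                index=table.index)
            fits = fit_model_set(model_set, data, tree,
                                 lambda_mode=config.lambda_mode)
            report = model_set_report(fits)
            total, unique = count_regressions(model_set)
            rpt_path = os.path.join(config.out_dir, f"ppa_{family}_ranking.csv")
            with open(rpt_path, "w") as fh:
                fh.write(f"# family={family} models={len(model_set)} "
                         f"regressions_total={total} regressions_unique={unique}\n")
                report.to_csv(fh, index=False)
            man.add(f"ppa_{family}_ranking", rpt_path)
            avg = average_models(fits, cutoff=config.ppa_cutoff)
            avg_path = os.path.join(config.out_dir, f"ppa_{family}_averaged.csv")
            avg.edge_table().to_csv(avg_path, index=False)
            man.add(f"ppa_{family}_averaged", avg_path)
            dot_path = os.path.join(config.out_dir, f"ppa_{family}_averaged.dot")
            with open(dot_path, "w") as fh:
                fh.write(avg.to_dot() + "\n")
            man.add(f"ppa_{family}_averaged_dot", dot_path)

    with man.stage("quasse"):
        if config.run_quasse:
            ranked = fit_quasse(tree, table["r_chrom"],
                                candidates=[tuple(c) for c in config.quasse_candidates],
                                n_bins=config.quasse_bins)
            q_path = os.path.join(config.out_dir, "quasse_ranking.csv")
            ranked.drop(columns=["fit"]).to_csv(q_path, index=False)
            man.add("quasse_ranking", q_path)
            # best model's rate functions sampled over the observed range
            best = ranked.iloc[0]["fit"]
            xs = np.linspace(table["r_chrom"].min(), table["r_chrom"].max(), 101)
            curves = pd.DataFrame({"x": xs, "lambda": best.lam(xs),
                                   "mu": best.mu(xs)})
            c_path = os.path.join(config.out_dir, "quasse_rate_curves.csv")
            curves.to_csv(c_path, index=False)
            man.add("quasse_rate_curves", c_path)

    path = man.write(config.out_dir, config.seed)
    out = {"manifest_path": path, "stages": man.stages, "artifacts": man.artifacts}
    return out
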