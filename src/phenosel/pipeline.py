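"""Config-driven orchestration: simulate -> QC -> BLUEs -> reduce ->
evaluate -> report, with manifests for provenance replay.

A study is described by one YAML document (see :class:`StudyConfig`); the
same config and seed always reproduce bit-identical outputs. Stages write
versioned CSVs plus a JSON manifest carrying the config hash and the seeds
consumed; a failing stage halts the run, leaving partial outputs next to a
FAILED marker naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, io, trait_reduction
from .evaluation import MaskingScheme, StudyData
from .simdata import SimConfig, TruthConfig, simulate_study

__all__ = ["StudyConfig", "run_study", "make_fixture"]

_TOP_KEYS = {"seed", "output_dir", "simulate", "qc", "methods", "predictor_sets",
             "schemes", "evaluate", "reduce"}
_SIM_KEYS = {"profile", "n_markers", "lines_per_cross", "n_biparental",
             "n_threeway", "env_corr", "h2", "call_error", "n_reps"}
_SCHEME_KEYS = {"kind", "fractions", "train", "test", "supplement", "unit",
                "n_reps", "id"}


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class StudyConfig:
    """Validated study description (unknown keys are rejected)."""

    seed: int = 0
    output_dir: str = "study_out"
    simulate: dict = field(default_factory=lambda: {"profile": "tiny"})
    qc: dict = field(default_factory=lambda: {"pic": 0.1, "prune_r": 0.9})
    methods: list = field(default_factory=lambda: ["enet"])
    predictor_sets: list = field(default_factory=lambda: ["traits"])
    schemes: list = field(default_factory=list)
    evaluate: dict = field(default_factory=dict)
    reduce: dict = field(default_factory=lambda: {"k": 3})

    @classmethod
    def from_yaml(cls, path_or_str) -> "StudyConfig":
        p = Path(str(path_or_str))
        text = p.read_text() if p.exists() else str(path_or_str)
        raw = yaml.safe_load(text) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = set(cfg.simulate) - _SIM_KEYS
        if bad:
            raise ValueError(f"unknown simulate keys: {sorted(bad)}")
        for s in cfg.schemes:
            bad = set(s) - _SCHEME_KEYS
            if bad:
                raise ValueError(f"unknown scheme keys: {sorted(bad)}")
        for m in cfg.methods:
            if m not in evaluation.METHODS:
                raise ValueError(f"unknown method {m!r}")
        if any(m in ("gblup", "mv_gblup") for m in cfg.methods):
            pass  # genotypes always simulated; real-data path validates below
        return cfg

    def canonical(self) -> str:
        return json.dumps(
            {
                "seed": self.seed, "simulate": self.simulate, "qc": self.qc,
                "methods": self.methods, "predictor_sets": self.predictor_sets,
                "schemes": self.schemes, "evaluate": self.evaluate,
                "reduce": self.reduce,
            },
            sort_keys=True, default=str,
        )

    def hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _sim_config(spec: dict) -> SimConfig:
    profile = spec.get("profile", "tiny")
    cfg = {"tiny": SimConfig.tiny, "demo": SimConfig.demo,
           "full_scale": SimConfig.full_scale}[profile]()
    for key in ("n_markers", "lines_per_cross", "n_biparental", "n_threeway",
                "call_error"):
        if key in spec:
            setattr(cfg, key, spec[key])
    if "h2" in spec or "env_corr" in spec:
        tr = cfg.truth
        cfg.truth = TruthConfig(
            n_qtl=tr.n_qtl,
            h2=spec.get("h2", tr.h2),
            env_corr=spec.get("env_corr", tr.env_corr),
            marker_share=tr.marker_share,
            sigma_block=tr.sigma_block,
            sigma_subblock=tr.sigma_subblock,
            sigma_resid=tr.sigma_resid,
            sigma_meas=tr.sigma_meas,
        )
    return cfg


def _scheme_from_dict(s: dict) -> MaskingScheme:
    kind = s.get("kind", "fraction_grid")
    common = {k: s[k] for k in ("unit", "n_reps", "id") if k in s}
    if kind == "fraction_grid":
        return MaskingScheme.fraction_grid(dict(s["fractions"]), **common)
    if kind == "whole_location":
        return MaskingScheme.whole_location(
            list(s["train"]), s["test"], supplement=s.get("supplement", 0.0), **common
        )
    raise ValueError(f"unknown scheme kind {kind!r}")


def run_study(config: StudyConfig | dict | str, out: str | None = None) -> Path:
    """Execute the full pipeline for one study configuration.

    Returns the output directory, containing the simulated dataset, QC'd
    genotypes and report, BLUEs, component scores, tidy accuracy records
    with a summary, and a provenance manifest.
    """
    if not isinstance(config, StudyConfig):
        config = (StudyConfig.from_dict(config) if isinstance(config, dict)
                  else StudyConfig.from_yaml(config))
    outdir = Path(out or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.hash(), "seed": config.seed, "stages": {}}
    stage = "simulate"
    try:
        sim = simulate_study(_sim_config(config.simulate), config.seed)
        io.write_genotypes_csv(sim.genotypes, outdir / "genotypes.csv")
        io.write_table(sim.design, outdir / "design.csv")
        io.write_table(sim.plots, outdir / "plots.csv")
        io.write_table(sim.panel, outdir / "panel.csv")
        io.write_table(sim.truth.genetic_values, outdir / "truth_genetic_values.csv",
                       index=True)
        manifest["stages"][stage] = ["genotypes.csv", "design.csv", "plots.csv",
                                     "panel.csv", "truth_genetic_values.csv"]

        stage = "qc_blues"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            data = StudyData.from_simulation(
                sim,
                pic_threshold=config.qc.get("pic", 0.1),
                r_threshold=config.qc.get("prune_r", 0.9),
            )
        io.write_genotypes_csv(data.genotypes, outdir / "genotypes_pruned.csv")
        (outdir / "qc_report.json").write_text(
            json.dumps(data.qc_report.counts(), indent=2)
        )
        io.write_table(data.blues, outdir / "blues.csv")
        manifest["stages"][stage] = ["genotypes_pruned.csv", "qc_report.json",
                                     "blues.csv"]

        stage = "reduce"
        k = int(config.reduce.get("k", 3))
        wide = data.blues.groupby("line")[data.trait_ids].mean()
        yline = data.blues.groupby("line")["yield_t_ha"].mean()
        pco = trait_reduction.select_pco(wide, yline.to_numpy(), k=k,
                                         panel=data.panel)
        pls = trait_reduction.pls_components(wide, yline.to_numpy(), k=k,
                                             panel=data.panel)
        comps = pd.concat([pco.scores, pls.scores], axis=1)
        io.write_table(comps, outdir / "components.csv", index=True)
        corr = pd.concat([pco.yield_corr, pls.yield_corr]).rename("yield_corr")
        io.write_table(corr.to_frame(), outdir / "component_yield_corr.csv",
                       index=True)
        manifest["stages"][stage] = ["components.csv", "component_yield_corr.csv"]

        stage = "evaluate"
        ev = dict(config.evaluate)
        all_records = []
        for sdict in config.schemes:
            scheme = _scheme_from_dict(sdict)
            for method in config.methods:
                psets = (["markers"] if method in ("gblup", "mv_gblup")
                         else config.predictor_sets)
                for pset in psets:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        rec = evaluation.run_scheme(
                            data, method, pset, scheme, seed=config.seed, **ev
                        )
                    all_records.append(rec)
        if all_records:
            records = pd.concat(all_records, ignore_index=True)
            io.write_table(records, outdir / "records.csv")
            io.write_table(evaluation.aggregate(records), outdir / "summary.csv")
            manifest["stages"][stage] = ["records.csv", "summary.csv"]
    except Exception as exc:  # halt with the failing stage named
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        raise StageError(stage, exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def make_fixture(profile: str, out_dir, seed: int = 20160901) -> Path:
    """Write a self-contained dataset bundle for a named profile
    (tiny / demo / full_scale) under a fixed seed."""
    cfg = {"tiny": SimConfig.tiny, "demo": SimConfig.demo,
           "full_scale": SimConfig.full_scale}[profile]()
    sim = simulate_study(cfg, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_genotypes_csv(sim.genotypes, out / "genotypes.csv")
    io.write_genotypes_vcf(sim.genotypes, out / "genotypes.vcf")
    io.write_table(sim.design, out / "design.csv")
    io.write_table(sim.plots, out / "plots.csv")
    io.write_table(sim.panel, out / "panel.csv")
    io.write_table(sim.truth.genetic_values, out / "truth_genetic_values.csv",
                   index=True)
    return out
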