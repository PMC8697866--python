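"""End-to-end reproducible runs: simulate -> edit -> fit -> params -> ebv -> validate.

A run is driven by one YAML/dict config with a mandatory master seed; every
stage's seed is derived from it, so a rerun with the same config reproduces
byte-identical outputs.  Each stage writes its artifacts into the run
directory and the manifest records the config hash, per-stage wall time and
an SHA-256 checksum of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from .basis import DimRange
from .components import VarianceComponents
from .ebv import ebv_table
from .editing import EditConfig, apply_edits, write_records
from .model import RemlOptions, build_model_frame, reml_estimate, solve_mme, SolutionSet
from .parameters import correlation_surface, curve_standard_errors, heritability_curve, repeatability_curve
from .pedigree import write_pedigree
from .simulate import SimConfig, simulate_dataset
from .validation import forward_validate

__all__ = ["load_config", "run_full_pipeline", "write_solutions", "read_solutions"]

log = logging.getLogger("rrtdm")


def load_config(source) -> dict:
    """Read a run config from YAML path or pass a dict through; seed mandatory."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    if "seed" not in cfg:
        raise ValueError("run config must set a master seed ('seed')")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dim_range(cfg: dict) -> DimRange:
    basis = cfg.get("basis", {})
    return DimRange(basis.get("first_day", 5), basis.get("last_day", 305))


def write_solutions(path, solutions: SolutionSet) -> None:
    """Persist MME solutions as long-format CSV (block, key, coef, value)."""
    rows = []
    for factor, levels in solutions.fixed.items():
        for level, value in levels.items():
            rows.append({"block": factor, "key": str(level), "coef": "", "value": value})
    for level, value in solutions.htd.items():
        rows.append({"block": "htd", "key": f"{level[0]}|{level[1]}", "coef": "", "value": value})
    for m, animal in enumerate(solutions.animals):
        for t in range(solutions.order + 1):
            rows.append({"block": "additive", "key": animal, "coef": t, "value": solutions.a_hat[m, t]})
    for m, cow in enumerate(solutions.recorded_cows):
        for t in range(solutions.order + 1):
            rows.append({"block": "pe", "key": cow, "coef": t, "value": solutions.pe_hat[m, t]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_solutions(path) -> SolutionSet:
    """Rebuild a SolutionSet (random-effect part) from a solutions CSV."""
    df = pd.read_csv(path, keep_default_na=False)
    add = df[df["block"] == "additive"]
    pe = df[df["block"] == "pe"]
    order = int(pd.to_numeric(add["coef"]).max())
    animals = list(dict.fromkeys(add["key"]))
    cows = list(dict.fromkeys(pe["key"]))
    a_hat = pd.to_numeric(add["value"]).to_numpy().reshape(len(animals), order + 1)
    pe_hat = pd.to_numeric(pe["value"]).to_numpy().reshape(len(cows), order + 1)
    fixed = {}
    for factor in ("herd_year", "dim", "age"):
        sub = df[df["block"] == factor]
        fixed[factor] = dict(zip(sub["key"], pd.to_numeric(sub["value"])))
    htd_sub = df[df["block"] == "htd"]
    htd = dict(zip(htd_sub["key"], pd.to_numeric(htd_sub["value"])))
    return SolutionSet(
        fixed=fixed, htd=htd, a_hat=a_hat, pe_hat=pe_hat,
        animals=animals, recorded_cows=cows, order=order,
    )


def run_full_pipeline(config, out_dir) -> dict:
    """Execute all stages; returns the manifest (also written to manifest.json)."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    file_handler = logging.FileHandler(out / "run.log", mode="w")
    file_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(file_handler)
    cfg_text = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "stages": {},
        "outputs": {},
        "failed_stage": None,
    }
    dim_range = _dim_range(cfg)
    order = cfg.get("basis", {}).get("order", 3)
    dim_width = cfg.get("basis", {}).get("dim_class_width", 1)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start (seed %s)", name, cfg["seed"])
            try:
                result = fn()
            except Exception:
                manifest["failed_stage"] = name
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
                log.exception("stage %s failed", name)
                raise
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
            return result
        return wrap

    # --- simulate -----------------------------------------------------------
    sim_kwargs = dict(cfg.get("sim", {}))
    if isinstance(sim_kwargs.get("varcomp"), dict):
        sim_kwargs["varcomp"] = VarianceComponents.from_dict(sim_kwargs["varcomp"])
    sim_cfg = SimConfig(seed=cfg["seed"], order=order, dim_range=dim_range, **sim_kwargs)

    def _simulate():
        data = simulate_dataset(sim_cfg)
        write_records(out / "records.csv", data.records)
        write_pedigree(out / "pedigree.txt", data.kin)
        data.effects.to_json(out / "true_values.json")
        sim_cfg.varcomp.to_json(out / "true_components.json")
        return data

    data = stage("simulate")(_simulate)

    # --- edit ---------------------------------------------------------------
    def _edit():
        edit_cfg = EditConfig(dim_range=dim_range, **cfg.get("edits", {}))
        edited, report = apply_edits(data.records, edit_cfg)
        write_records(out / "records_edited.csv", edited)
        report.to_json(out / "edit_report.json")
        return edited

    edited = stage("edit")(_edit)

    # --- fit (REML) ---------------------------------------------------------
    reml_cfg = cfg.get("reml", {})

    def _fit():
        frame = build_model_frame(
            edited, data.kin, order=order, dim_range=dim_range, dim_class_width=dim_width
        )
        opts = RemlOptions(
            max_iter=reml_cfg.get("max_iter", 50), tol=reml_cfg.get("tol", 1e-6)
        )
        fit = reml_estimate(frame, data.kin, options=opts)
        with open(out / "fit.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=2)
        solutions = solve_mme(frame, fit.varcomp, data.kin)
        write_solutions(out / "solutions.csv", solutions)
        return fit, solutions

    if reml_cfg.get("enabled", True):
        fit, solutions = stage("fit")(_fit)
        vc_for_eval = fit.varcomp
    else:
        def _solve_only():
            frame = build_model_frame(
                edited, data.kin, order=order, dim_range=dim_range, dim_class_width=dim_width
            )
            solutions = solve_mme(frame, sim_cfg.varcomp, data.kin)
            write_solutions(out / "solutions.csv", solutions)
            return solutions

        fit, solutions = None, stage("fit")(_solve_only)
        vc_for_eval = sim_cfg.varcomp

    # --- genetic parameters -------------------------------------------------
    def _params():
        h2 = heritability_curve(vc_for_eval, dim_range)
        rep = repeatability_curve(vc_for_eval, dim_range)
        if fit is not None:
            h2.se = curve_standard_errors(
                fit, "heritability", dim_range, seed=cfg["seed"]
            ).se
            rep.se = curve_standard_errors(
                fit, "repeatability", dim_range, seed=cfg["seed"] + 1
            ).se
        h2.to_frame().to_csv(out / "heritability.csv", index=False)
        rep.to_frame().to_csv(out / "repeatability.csv", index=False)
        for kind in ("genetic", "phenotypic"):
            correlation_surface(vc_for_eval, kind, dim_range).to_frame().to_csv(
                out / f"correlation_{kind}.csv", index=False
            )

    stage("params")(_params)

    # --- breeding values ----------------------------------------------------
    def _ebv():
        ebv_table(solutions, dim_range).to_csv(out / "ebv.csv", index=False)

    stage("ebv")(_ebv)

    # --- forward validation -------------------------------------------------
    val_cfg = cfg.get("validation", {})

    def _validate():
        sire_of = dict(zip(data.cow_meta["cow"], data.cow_meta["sire"]))
        first_cut = val_cfg.get("first_cut_year", sim_cfg.last_year - 2)
        stats = forward_validate(
            edited,
            data.kin,
            sire_of,
            vc_for_eval,
            first_cut_year=first_cut,
            order=order,
            dim_range=dim_range,
            dim_class_width=dim_width,
            min_daughters=val_cfg.get("min_daughters", 5),
            cohort_rule=val_cfg.get("cohort_rule", "max"),
            n_boot=val_cfg.get("n_boot", 2000),
            seed=cfg["seed"],
        )
        stats.to_csv(out / "validation.csv", index=False)

    if val_cfg.get("enabled", True):
        stage("validate")(_validate)

    # run.log carries timestamps, so it is excluded from the determinism checksums
    for f in sorted(out.glob("*")):
        if f.name not in ("manifest.json", "run.log") and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.removeHandler(file_handler)
    file_handler.close()
    return manifest
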