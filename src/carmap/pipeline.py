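"""End-to-end pipeline: simulate -> adjacency -> tabulate -> expected ->
fit -> diagnose -> surfaces, driven by one YAML config, with a manifest of
every artifact (content hashes, seed, versions) for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (CountTable, ZoneCovariates, descriptive_table,
                     quartile_covariates, tabulate_counts)
from .diagnostics import diagnostics_report
from .expected import ExpectedCounts, expected_counts, expected_frame
from .geo import (queen_adjacency, read_geojson, validate_adjacency,
                  write_neighbor_list, write_weights_csv)
from .mcmc import PosteriorSamples, SamplerConfig, run_mcmc
from .model import ModelSpec
from .simulate import SimulationParams, simulate_dataset
from .surfaces import fixed_effect_table, risk_surface, surface_geojson

log = logging.getLogger("carmap")

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "carmap_run",
    "periods": [2005, 2011, 2016],
    "t_codes": [1.0, 2.0, 3.0],
    "simulate": {"rows": 8, "cols": 9, "children_per_cell": 85},
    "quartiles": {"per_period": True},
    "standardization": {"per_period": False},
    "priors": {"V_beta": 1e6, "tau_shape": 0.5, "tau_rate": 0.0005},
    "model": {"include_u": True, "include_v": True, "include_covariates": True},
    # desk-scale sampler defaults; the survey-fidelity preset is
    # n_burnin: 100000, n_iter: 1000000, thin: 10
    "sampler": {"n_chains": 2, "n_burnin": 5000, "n_iter": 20000, "thin": 10},
    "surfaces": {"threshold": 1.0, "point": "median"},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute all stages in order; returns the run manifest.

    Inputs are either simulated (``simulate`` block) or loaded from the
    ``inputs`` block (geojson + records CSV, or a pre-tabulated counts CSV).
    Each stage writes its artifact; a stage failure aborts with the stage
    named, keeping earlier outputs.  Identical configs reproduce identical
    outputs.
    """
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": config, "stages": {},
                "files": {}}
    stage = "simulate/load"
    try:
        zones, records, counts, covariates = _stage_inputs(config, out)
        manifest["stages"][stage] = "ok"

        stage = "adjacency"
        A = queen_adjacency(zones, tol=float(config.get("tol", 0.0)))
        validate_adjacency(A)
        write_neighbor_list(A, out / "neighbors.txt")
        write_weights_csv(A, out / "adjacency.csv")
        manifest["stages"][stage] = f"{A.n} zones, islands={sorted(A.islands)}"

        stage = "tabulate"
        if records is not None:
            descriptive_table(records).to_csv(out / "descriptive.csv", index=False)
            if counts is None:
                counts = tabulate_counts(records, [z.zone_id for z in zones],
                                         config["periods"])
            if covariates is None:
                covariates = quartile_covariates(
                    records, [z.zone_id for z in zones], config["periods"],
                    per_period=config["quartiles"]["per_period"])
        if counts is None:
            raise ValueError("no counts available: config must provide "
                             "'inputs.records' or 'inputs.counts' or a "
                             "'simulate' block")
        counts.to_frame().to_csv(out / "counts.csv", index=False)
        if covariates is not None:
            covariates.to_frame().to_csv(out / "covariates.csv", index=False)
        manifest["stages"][stage] = "ok"

        stage = "expected"
        E = expected_counts(counts,
                            per_period=config["standardization"]["per_period"])
        expected_frame(counts, E).to_csv(out / "expected.csv", index=False)
        manifest["stages"][stage] = {"reference_rates":
                                     {str(k): v for k, v in
                                      E.reference_rates.items()}}

        stage = "fit"
        spec = ModelSpec(
            adjacency=A,
            covariate_names=covariates.column_names if covariates else [],
            t_codes=np.asarray(config["t_codes"], dtype=float),
            V_beta=config["priors"]["V_beta"],
            tau_shape=config["priors"]["tau_shape"],
            tau_rate=config["priors"]["tau_rate"],
            **config["model"])
        scfg = SamplerConfig(seed=int(config["seed"]), **config["sampler"])
        samples = run_mcmc(spec, counts, E, covariates, scfg)
        samples.save(out / "samples")
        manifest["stages"][stage] = "ok"

        stage = "diagnose"
        report = diagnostics_report(samples, counts, E, covariates, spec)
        report.parameters.to_csv(out / "diagnostics.csv", index=False)
        diag = {"dic": report.dic.as_dict() if report.dic else None,
                "all_converged": report.all_converged()}
        with open(out / "diagnostics.json", "w") as fh:
            json.dump(diag, fh, indent=1)
        manifest["stages"][stage] = diag

        stage = "surfaces"
        surf = risk_surface(samples, counts, E,
                            threshold=config["surfaces"]["threshold"],
                            point=config["surfaces"]["point"])
        surf.to_csv(out / "risk_surface.csv", index=False)
        fixed_effect_table(samples).to_csv(out / "fixed_effects.csv", index=False)
        surface_geojson(surf, zones, out / "risk_surface.geojson")
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        manifest["stages"][stage] = f"FAILED: {exc}"
        _write_manifest(manifest, out)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_manifest(manifest, out)
    return manifest


def _stage_inputs(config: dict, out: Path):
    """Return (zones, records, counts, covariates); simulate when no inputs
    block is given."""
    inputs = config.get("inputs")
    if inputs:
        if "geojson" not in inputs:
            raise ValueError("inputs block requires 'geojson'")
        zones = read_geojson(inputs["geojson"],
                             id_property=inputs.get("id_property", "zone_id"))
        records = counts = covariates = None
        if inputs.get("records"):
            records = pd.read_csv(inputs["records"])
        if inputs.get("counts"):
            counts = CountTable.from_frame(
                pd.read_csv(inputs["counts"]),
                zone_ids=[z.zone_id for z in zones],
                periods=config["periods"])
        if inputs.get("covariates"):
            covariates = ZoneCovariates.from_frame(
                pd.read_csv(inputs["covariates"]),
                zone_ids=[z.zone_id for z in zones],
                periods=config["periods"])
        if records is None and counts is None:
            raise ValueError("inputs block needs 'records' or 'counts'")
        return zones, records, counts, covariates
    sim_cfg = config.get("simulate", {})
    params = SimulationParams(seed=int(config["seed"]),
                              period_labels=tuple(config["periods"]),
                              t_codes=tuple(config["t_codes"]), **sim_cfg)
    sim = simulate_dataset(params)
    sim.write(out / "synthetic")
    return sim.zones, sim.records, sim.counts, sim.covariates


def _write_manifest(manifest: dict, out: Path) -> None:
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
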