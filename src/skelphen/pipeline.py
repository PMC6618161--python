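"""End-to-end pipeline: simulate -> analyse -> bundle directory.

Runs every stage on synthetic data with known ground truth and writes one
bundle directory of per-stage CSV/JSON outputs plus a run log carrying the
seed, config hash and package versions, so provenance is reconstructable
from the bundle alone.  Numeric outputs are written at full precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

import skelphen
from skelphen import biomech, densitometry, distcompare, histomorph, quality, synthetic
from skelphen.config import PipelineConfig, config_hash

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("skelphen")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("quality")
def _run_quality(config: PipelineConfig, seeds, out: Path) -> dict:
    sim = config.simulate
    model = synthetic.cohort_model_from_cvs(
        n=sim.cohort_n,
        bmc_mean=sim.bmc_mean,
        bmc_cv=sim.bmc_cv,
        bmc_correlation=sim.bmc_correlation,
        seed=int(seeds["cohort"]),
    )
    cohort = synthetic.gen_reference_cohort(model)
    cohort.table.to_csv(out / "reference_cohort.csv", index=False)
    ref = quality.fit_reference(cohort.table)
    ref.to_json(out / "reference_model.json")
    groups = {}
    truth = {}
    for i, spec in enumerate(sim.groups):
        g = synthetic.gen_mutant_group(
            model, spec.deficit_sd, spec.n, seed=int(seeds["groups"]) + i,
            genotype=spec.name,
        )
        g.table.to_csv(out / f"group_{spec.name}.csv", index=False)
        groups[spec.name] = g.table
        truth[spec.name] = spec.deficit_sd
    report = quality.quality_report(ref, groups)
    report.to_csv(out / "quality_scores.csv", index=False)
    recovered = {
        name: {
            p: float(
                report.loc[
                    (report["group"] == name) & (report["parameter"] == p), "score_sd"
                ].iloc[0]
            )
            for p in synthetic.BIOMECH_PARAMETERS
        }
        for name in groups
    }
    return {"injected_deficits": truth, "recovered_scores": recovered}


@_stage("biomech")
def _run_biomech(config: PipelineConfig, seeds, out: Path) -> dict:
    sim = config.simulate
    bm = config.biomech
    bconfig = biomech.BiomechConfig(**dataclasses.asdict(bm))
    rng = np.random.default_rng(int(seeds["curves"]))
    rows = []
    for i in range(sim.n_curves):
        params = synthetic.CurveParams(
            stiffness=float(rng.uniform(80, 140)),
            yield_load=float(rng.uniform(8, 12)),
            max_load=float(rng.uniform(13, 18)),
            fracture_fraction=float(rng.uniform(0.5, 0.9)),
            hardening_ratio=float(rng.uniform(0.05, 0.25)),
            noise_sd=sim.curve_noise_sd,
        )
        sc = synthetic.gen_load_displacement(
            params, seed=int(seeds["curves"]) + 1 + i, specimen_id=f"curve_{i:03d}"
        )
        extracted = biomech.extract_biomech_params(sc.curve, bconfig)
        rows.append(
            {
                "specimen_id": sc.curve.specimen_id,
                "yield_load": extracted.yield_load,
                "max_load": extracted.max_load,
                "fracture_load": extracted.fracture_load,
                "stiffness": extracted.stiffness,
                "r_squared": extracted.r_squared,
                "flags": ";".join(extracted.flags),
                "true_yield_load": params.yield_load,
                "true_max_load": params.max_load,
                "true_fracture_load": params.fracture_load,
                "true_stiffness": params.stiffness,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out / "biomech_params.csv", index=False)
    rel_err = np.abs(table["stiffness"] / table["true_stiffness"] - 1)
    return {"n_curves": sim.n_curves, "median_stiffness_rel_err": float(np.median(rel_err))}


@_stage("densitometry")
def _run_densitometry(config: PipelineConfig, seeds, out: Path) -> dict:
    sim = config.simulate
    dens = config.densitometry
    standards = list(dens.standards)
    fields = {
        "wt": synthetic.gen_gray_field(
            sim.bone_density_mean, sim.bone_density_sd, standards,
            size=tuple(sim.gray_field_size), seed=int(seeds["gray"]),
        ),
        "mut": synthetic.gen_gray_field(
            sim.bone_density_mean * (1 + sim.mutant_density_shift),
            sim.bone_density_sd, standards,
            size=tuple(sim.gray_field_size), seed=int(seeds["gray"]) + 1,
        ),
    }
    hists = {}
    for name, fld in fields.items():
        densitometry.write_gray_field(fld, out / f"gray_{name}")
        cmap = densitometry.calibrate_gray(fld)
        hist = densitometry.qbse_histogram(fld, cmap, n_bins=dens.n_bins_qbse)
        pd.DataFrame(
            {"bin_lo": hist.edges[:-1], "bin_hi": hist.edges[1:], "freq": hist.frequencies}
        ).to_csv(out / f"qbse_hist_{name}.csv", index=False)
        hists[name] = hist
    ks = distcompare.ks_histogram_percent(hists["wt"], hists["mut"])
    summary = {
        "d_percent": ks.d_percent,
        "n1": ks.n1,
        "n2": ks.n2,
        "critical_percent": {str(a): c for a, c in ks.critical_percent.items()},
        "crossed_levels": list(ks.crossed_levels),
    }
    (out / "ks_wt_vs_mut.json").write_text(json.dumps(summary, indent=2))
    return summary


@_stage("histomorph")
def _run_histomorph(config: PipelineConfig, seeds, out: Path) -> dict:
    sim = config.simulate
    hconfig = synthetic.HistomorphSimConfig(
        zone_jitter=2.0, interlabel_jitter=0.4, trace_jitter=0.1
    )
    records = []
    gp_rows = []
    for i in range(sim.n_histomorph_sections):
        rec, gp = synthetic.gen_histomorph_tables(hconfig, seed=int(seeds["histomorph"]) + i)
        records.append(rec)
        res = histomorph.growth_plate_heights(gp)
        gp_rows.append({"section": i, "total_um": res.total_um, **{
            f"{z}_um": res.heights_um[z] for z in histomorph.ZONES}})
    pd.DataFrame(gp_rows).to_csv(out / "growth_plate.csv", index=False)
    animal = histomorph.average_records(records)
    (out / "histomorph_summary.json").write_text(json.dumps(animal, indent=2))
    return animal


def run_pipeline(
    config: PipelineConfig, out_dir: Path, seed: Optional[int] = None
) -> dict:
    """Execute all configured stages and write the bundle directory.

    Returns the summary dict that is also written to ``summary.json``.
    A stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = config.seed
    chash = config_hash(config)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(5)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(["cohort", "groups", "curves", "gray", "histomorph"], children)
    }

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("pipeline start: seed=%d config_hash=%s version=%s",
                 seed, chash, skelphen.__version__)
        summary = {
            "seed": seed,
            "config_hash": chash,
            "versions": {
                "skelphen": skelphen.__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "python": sys.version.split()[0],
            },
            "stages": {},
        }
        summary["stages"]["quality"] = _run_quality(config, seeds, out)
        summary["stages"]["biomech"] = _run_biomech(config, seeds, out)
        summary["stages"]["densitometry"] = _run_densitometry(config, seeds, out)
        summary["stages"]["histomorph"] = _run_histomorph(config, seeds, out)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2, default=list))
        log.info("pipeline complete")
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
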