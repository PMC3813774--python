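"""End-to-end orchestration: simulate → clearance → centiles → doppler →
stats → report.

The pipeline is fully reproducible from its configuration: every stochastic
stage derives its stream from the single config seed, and the numeric
report is byte-identical across reruns of the same config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import centiles as _centiles
from . import clearance as _clearance
from . import doppler as _doppler
from . import stats as _stats
from . import tables as _tables
from .synthetic import CellMeans, GeneratorConfig, generate_cohort, attach_tracer_data, generate_traces

logger = logging.getLogger("fgrtools")


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    outdir: str = "fgr_out"
    z_critical: float = _centiles.Z_FIFTH_CENTILE
    bin_width: float = _centiles.DEFAULT_BIN_WIDTH
    centile_method: str = "histogram_nls"
    reference: tuple[str, str] = ("WT", "water")
    r2_min: float = _clearance.DEFAULT_R2_MIN
    plateau: bool = False
    n_perm: int = 999
    stats_seed: int | None = None  # defaults to generator.seed + 1
    endpoints: tuple[str, ...] = ("fetal_weight", "placental_weight")
    make_figure: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen_raw = raw.pop("generator", {})
        if "group_means" in gen_raw:
            gm = {}
            for key, vals in gen_raw["group_means"].items():
                genotype, treatment = key.split(":")
                gm[(genotype, treatment)] = CellMeans(**vals)
            gen_raw["group_means"] = gm
        gen = GeneratorConfig(**gen_raw)
        if "reference" in raw and isinstance(raw["reference"], str):
            raw["reference"] = tuple(raw["reference"].split(":"))
        cfg = cls(generator=gen, **raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["group_means"] = {
            f"{g}:{t}": dataclasses.asdict(m) if dataclasses.is_dataclass(m) else m
            for (g, t), m in self.generator.group_means.items()
        }
        d["reference"] = ":".join(self.reference)
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain in the out directory."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all tables plus report.{json,txt} under
    ``config.outdir``.  Returns the report dictionary."""
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {
        "config": config.to_dict(),
        "seed": config.generator.seed,
        "stages": {},
    }

    def _stage(name):
        logger.info("stage %s: start", name)
        return name

    def _out(name):
        return os.path.join(config.outdir, name)

    # --- simulate -----------------------------------------------------
    stage = _stage("simulate")
    try:
        litters, fetuses = generate_cohort(config.generator)
        plasma = attach_tracer_data(litters, fetuses, config.generator)
        traces = generate_traces(config.generator)
        _tables.write_table(_tables.litters_to_frame(litters), _out("litters.csv"))
        _tables.write_table(_tables.fetuses_to_frame(fetuses), _out("fetuses.csv"))
        _tables.write_table(_tables.plasma_to_frame(plasma), _out("plasma.csv"))
        _tables.write_table(_tables.traces_to_frame(traces), _out("traces.csv"))
        report["stages"]["simulate"] = {
            "n_litters": len(litters),
            "n_fetuses": len(fetuses),
            "n_plasma_samples": len(plasma),
            "n_traces": len(traces),
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(f"stage {stage} failed: {exc}") from exc

    # --- clearance ----------------------------------------------------
    stage = _stage("clearance")
    try:
        fit = _clearance.fit_disappearance(
            plasma, pooled=True, r2_min=config.r2_min, plateau=config.plateau
        )
        results, errors = _clearance.compute_cohort_kmf(
            fetuses, fit, r2_min=config.r2_min
        )
        import pandas as pd

        res_df = pd.DataFrame([vars(r) for r in results])
        _tables.write_table(res_df, _out("clearance.csv"))
        report["stages"]["clearance"] = {
            "fit": {"C0": fit.C0, "k": fit.k, "r2": fit.r2,
                    "n_samples": fit.n_samples, "qc_pass": fit.r2 > config.r2_min},
            "n_results": len(results),
            "n_errors": len(errors),
            "mean_kmf_per_g_placenta": float(res_df["kmf_per_g_placenta"].mean()),
            "mean_kmf_per_g_fetus": float(res_df["kmf_per_g_fetus"].mean()),
            "mean_clearance_total": float(res_df["clearance_total"].mean()),
        }
    except Exception as exc:
        raise StageError(f"stage {stage} failed: {exc}") from exc

    # --- centiles -----------------------------------------------------
    stage = _stage("centiles")
    try:
        rep = _centiles.centile_report(
            fetuses,
            reference=config.reference,
            z_critical=config.z_critical,
            method=config.centile_method,
            bin_width=config.bin_width,
        )
        _tables.write_table(rep.table, _out("centiles.csv"))
        if config.make_figure:
            _centiles.plot_weight_distributions(
                fetuses, rep.threshold, _out("weight_distributions.png"),
                bin_width=config.bin_width,
            )
        cells = {
            f"{r.genotype}:{r.treatment}": {
                "n": int(r.n),
                "frac_below": float(r.frac_below),
                "frac_above": float(r.frac_above),
            }
            for r in rep.table.itertuples(index=False)
        }
        report["stages"]["centiles"] = {
            "threshold_g": rep.threshold,
            "z_critical": rep.z_critical,
            "reference": ":".join(rep.reference),
            "cells": cells,
        }
    except Exception as exc:
        raise StageError(f"stage {stage} failed: {exc}") from exc

    # --- doppler ------------------------------------------------------
    stage = _stage("doppler")
    try:
        import pandas as pd

        measures, skipped = [], []
        for tr in traces:
            try:
                measures.append(vars(_doppler.aggregate_trace(tr)))
            except _doppler.TooFewCyclesError as exc:
                skipped.append(str(exc))
        mdf = pd.DataFrame(measures)
        _tables.write_table(mdf, _out("doppler.csv"))
        report["stages"]["doppler"] = {
            "n_traces": len(measures),
            "n_skipped": len(skipped),
            "mean_pi": float(mdf["pi"].mean()) if len(mdf) else None,
            "mean_psv": float(mdf["psv"].mean()) if len(mdf) else None,
            "mean_mdv": float(mdf["mdv"].mean()) if len(mdf) else None,
        }
    except Exception as exc:
        raise StageError(f"stage {stage} failed: {exc}") from exc

    # --- stats --------------------------------------------------------
    stage = _stage("stats")
    try:
        import pandas as pd

        stats_seed = (
            config.stats_seed
            if config.stats_seed is not None
            else config.generator.seed + 1
        )
        stats_report = {}
        all_contrasts = []
        for endpoint in config.endpoints:
            cmp_ = _stats.compare_groups(
                fetuses, endpoint, n_perm=config.n_perm, seed=stats_seed
            )
            stats_report[endpoint] = {
                "cells": {
                    f"{r.genotype}:{r.treatment}": {
                        "mean": float(r.mean),
                        "sem": float(r.sem),
                        "n_litters": int(r.n_litters),
                        "n_pups": int(r.n_pups),
                    }
                    for r in cmp_.cells.itertuples(index=False)
                },
                "p_genotype": cmp_.p_genotype,
                "p_treatment": cmp_.p_treatment,
                "p_interaction": cmp_.p_interaction,
                "contrasts": cmp_.contrasts.to_dict("records"),
            }
            all_contrasts.append(cmp_.contrasts.assign(endpoint=endpoint))
        _per_pup, fp_cells = _stats.fetal_placental_ratio(fetuses)
        stats_report["fp_ratio_cells"] = {
            f"{r.genotype}:{r.treatment}": {"mean": float(r.mean), "sem": float(r.sem)}
            for r in fp_cells.itertuples(index=False)
        }
        _tables.write_table(
            pd.concat(all_contrasts, ignore_index=True), _out("stats_contrasts.csv")
        )
        report["stages"]["stats"] = {"seed": stats_seed, "n_perm": config.n_perm,
                                     **stats_report}
    except Exception as exc:
        raise StageError(f"stage {stage} failed: {exc}") from exc

    # --- report -------------------------------------------------------
    with open(_out("report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    with open(_out("report.txt"), "w") as fh:
        fh.write(render_report(report))
    logger.info("pipeline complete: %s", config.outdir)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def render_report(report: dict) -> str:
    """Human-readable summary with fixed 6-decimal formatting (so reruns are
    byte-identical)."""
    lines = [
        "fgrtools pipeline report",
        f"seed: {report['seed']}",
        "",
    ]
    sim = report["stages"]["simulate"]
    lines.append(
        f"simulate: {sim['n_litters']} litters, {sim['n_fetuses']} fetuses, "
        f"{sim['n_plasma_samples']} plasma samples, {sim['n_traces']} traces"
    )
    cl = report["stages"]["clearance"]
    lines.append(
        "clearance: fit C0=%.6f dpm/ul k=%.6f /min r2=%.6f; "
        "mean Kmf/g placenta=%.6f ul/min/g; mean total=%.6f ul/min"
        % (
            cl["fit"]["C0"], cl["fit"]["k"], cl["fit"]["r2"],
            cl["mean_kmf_per_g_placenta"], cl["mean_clearance_total"],
        )
    )
    ce = report["stages"]["centiles"]
    lines.append(
        "centiles: threshold=%.6f g (z=%.3f, reference %s)"
        % (ce["threshold_g"], ce["z_critical"], ce["reference"])
    )
    for cell, v in sorted(ce["cells"].items()):
        lines.append(
            "  %-9s n=%-4d below=%.4f above=%.4f"
            % (cell, v["n"], v["frac_below"], v["frac_above"])
        )
    do = report["stages"]["doppler"]
    if do["mean_pi"] is not None:
        lines.append(
            "doppler: %d traces, mean PSV=%.6f MDV=%.6f PI=%.6f"
            % (do["n_traces"], do["mean_psv"], do["mean_mdv"], do["mean_pi"])
        )
    st = report["stages"]["stats"]
    for endpoint in (k for k in st if isinstance(st[k], dict) and "cells" in st[k]):
        e = st[endpoint]
        lines.append(
            f"stats[{endpoint}]: p_genotype={e['p_genotype']:.6f} "
            f"p_treatment={e['p_treatment']:.6f} "
            f"p_interaction={e['p_interaction']:.6f}"
        )
        for cell, v in sorted(e["cells"].items()):
            lines.append(
                "  %-9s mean=%.6f sem=%.6f (litters=%d, pups=%d)"
                % (cell, v["mean"], v["sem"], v["n_litters"], v["n_pups"])
            )
        for c in e["contrasts"]:
            lines.append(
                "  %-20s raw_p=%.6f adj_p=%.6f"
                % (c["contrast"], c["raw_p"], c["adj_p"])
            )
    return "\n".join(lines) + "\n"
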