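"""End-to-end orchestration: generate/ingest -> filter -> cluster -> rank
-> occupancy -> SPR fit -> report.

A run is driven by a single :class:`RunConfig` (loadable from YAML/JSON).
Each stage writes its artifact into the output directory, stamped with the
configuration hash and seed, so any stage can be re-run from persisted
inputs and reproduce downstream outputs byte-identically. Stages are
optional: a config without an SPR section yields a report with the
filtering/clustering sections only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from hsascreen import clustering, ligand_filter, occupancy, spr, synthetic

logger = logging.getLogger("hsascreen")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name. Partial outputs are kept."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "hsascreen_run"
    # ligand stage: either a path to a CSV table or generator settings
    ligand_table: str | None = None
    n_ligands: int = 200
    filter_pass_fractions: dict[str, float] | None = None
    thresholds: dict[str, Any] = field(default_factory=dict)
    # clustering stage
    sites_path: str | None = None
    n_clusters: int = 5
    sites_per_cluster: int = 10
    site_jitter: int = 1
    k: int = 5
    linkage: str = "average"
    top_m: int = 4
    run_clustering: bool = True
    # occupancy stage: list of {name, K, ligand_conc, [hsa_conc, n_sites]}
    occupancy_specs: list[dict[str, Any]] = field(default_factory=list)
    # SPR stage
    run_spr: bool = False
    spr_baseline: dict[str, float] | None = None  # ka1, kd1, ka2, kd2
    spr_ligand: dict[str, float] | None = None
    spr_rmax: float = 100.0
    spr_noise_sd: float = 0.0
    analyte_concs: list[float] = field(
        default_factory=lambda: [2.5e-6, 5e-6, 10e-6, 20e-6, 40e-6]
    )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig(**raw)


def _stamp(cfg: RunConfig) -> dict:
    return {"seed": cfg.seed, "config_hash": cfg.config_hash()}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order; return the summary report.

    Artifacts land in ``cfg.out_dir``; a stage failure raises
    :class:`PipelineError` naming the stage, retaining prior artifacts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"stamp": _stamp(cfg)}

    # --- filtering -------------------------------------------------------
    try:
        thr = ligand_filter.FilterThresholds(**cfg.thresholds)
        if cfg.ligand_table:
            records = ligand_filter.read_ligand_table(cfg.ligand_table)
        else:
            gen_cfg = synthetic.GeneratorConfig(
                seed=cfg.seed,
                n_ligands=cfg.n_ligands,
                **(
                    {"filter_pass_fractions": cfg.filter_pass_fractions}
                    if cfg.filter_pass_fractions
                    else {}
                ),
            )
            records = synthetic.gen_ligand_table(gen_cfg, thr)
            ligand_filter.write_ligand_table(records, out / "ligand_table.csv")
        filt = ligand_filter.apply_filters(records, thr)
        filt_dict = filt.to_dict() | _stamp(cfg)
        (out / "filter_report.json").write_text(json.dumps(filt_dict, indent=2))
        report["filtering"] = {
            "n_input": filt.n_input,
            "survivors_after_stage": filt.survivors_after_stage,
            "n_passing": len(filt.passing_ids),
        }
        logger.info(
            "filter: %d records in, %d passing", filt.n_input, len(filt.passing_ids)
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("filter", exc) from exc

    # --- clustering + ranking -------------------------------------------
    if cfg.run_clustering:
        try:
            if cfg.sites_path:
                sites = synthetic.read_binding_sites_json(cfg.sites_path)
            else:
                gen_cfg = synthetic.GeneratorConfig(
                    seed=cfg.seed,
                    n_clusters=cfg.n_clusters,
                    sites_per_cluster=cfg.sites_per_cluster,
                    site_jitter=cfg.site_jitter,
                )
                sites = synthetic.gen_binding_sites(gen_cfg)
                synthetic.write_binding_sites_json(sites, out / "sites.json")
            model = clustering.hierarchical_cluster(sites, cfg.k, method=cfg.linkage)
            ranks = clustering.rank_all(model)
            top = {
                c: [
                    {"ligand_id": e.ligand_id, "R": e.R}
                    for e in clustering.select_representatives(r, cfg.top_m)
                ]
                for c, r in ranks.items()
            }
            model_dict = model.to_dict() | _stamp(cfg)
            (out / "cluster_model.json").write_text(json.dumps(model_dict, indent=2))
            (out / "ranks.json").write_text(
                json.dumps({str(c): t for c, t in top.items()}, indent=2)
            )
            sizes = {c: st.n for c, st in model.cluster_stats.items()}
            report["clustering"] = {"k": model.k, "cluster_sizes": sizes, "top": top}
            logger.info("cluster: %d sites into %d clusters %s", len(sites), model.k, sizes)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("cluster", exc) from exc

    # --- occupancy -------------------------------------------------------
    if cfg.occupancy_specs:
        try:
            rows = []
            for entry in cfg.occupancy_specs:
                name = entry.get("name", "?")
                K = float(entry["K"])
                L = float(entry["ligand_conc"])
                if entry.get("hsa_conc"):
                    spec = occupancy.OccupancySpec(
                        K, L, float(entry["hsa_conc"]), int(entry.get("n_sites", 1))
                    )
                    theta = occupancy.occupancy_depletion(spec)
                    model_used = "depletion"
                else:
                    theta = occupancy.occupancy_simple(K, L)
                    model_used = "simple"
                rows.append(
                    {
                        "name": name,
                        "model": model_used,
                        "occupancy_percent": occupancy.to_percent(theta),
                    }
                )
            (out / "occupancy.json").write_text(json.dumps(rows, indent=2))
            report["occupancy"] = rows
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("occupancy", exc) from exc

    # --- SPR -------------------------------------------------------------
    if cfg.run_spr:
        try:
            if not cfg.spr_baseline:
                raise ValueError("run_spr requires spr_baseline rates")
            base_kp = spr.KineticParams(**cfg.spr_baseline)
            fitted = {}
            for label, kp_true in (
                ("baseline", base_kp),
                ("ligand", spr.KineticParams(**cfg.spr_ligand) if cfg.spr_ligand else None),
            ):
                if kp_true is None:
                    continue
                sgs = [
                    synthetic.gen_sensorgram(
                        kp_true, cfg.spr_rmax, cfg.spr_rmax, c,
                        noise_sd=cfg.spr_noise_sd, seed=cfg.seed + i,
                    )
                    for i, c in enumerate(cfg.analyte_concs)
                ]
                avg, _per = spr.fit_heterogeneous(sgs)
                fitted[label] = avg
            spr_report: dict[str, Any] = {
                k: v.to_dict() for k, v in fitted.items()
            }
            if "ligand" in fitted:
                fc1, fc2 = spr.fold_change(fitted["ligand"], fitted["baseline"])
                ddg = spr.delta_delta_g(fitted["ligand"], fitted["baseline"])
                spr_report["fold_change"] = {
                    "site1": {"ratio": fc1[0], "direction": fc1[1]},
                    "site2": {"ratio": fc2[0], "direction": fc2[1]},
                }
                spr_report["delta_delta_g_kJ_mol"] = {"site1": ddg[0], "site2": ddg[1]}
            (out / "spr_report.json").write_text(
                json.dumps(spr_report, indent=2, default=float)
            )
            report["spr"] = spr_report
            logger.info("spr: fitted %s condition(s)", list(fitted))
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("spr", exc) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
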