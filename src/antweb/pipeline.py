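"""End-to-end orchestration of the multilayer network analysis.

``run_pipeline`` reproduces the full analysis sequence on one event table:

1. build the five resource layers and the pooled multilayer matrix;
2. per-layer metric significance against Patefield nulls (specialization
   H2', weighted nestedness WNODF, Morisita-Horn overlap among ants) and
   standardized modularity Q;
3. pairwise Monte-Carlo comparisons of H2' and WNODF among the feeding
   layers (fruit excluded by default: its networks are too small for
   size-sensitive metrics);
4. site-level descriptors (size, richness, frequency) with Poisson-GLM
   tests of a resource effect;
5. per-site core extraction, PERMANOVA on core composition (ants and
   plants separately), and NMDS ordination.

The run is a pure function of (events, config): every stochastic stage
draws its seed deterministically from the master seed, and the JSON report
is written with sorted keys and no timestamps so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .community_stats import (
    build_core_incidence,
    core_distance_matrix,
    descriptor_table,
    extract_core,
    nmds,
    permanova,
    poisson_glm_test,
)
from .errors import AntwebError, DegenerateDesignError, EmptyLayerError, UndefinedMetricError
from .metrics import h2prime, horn_overlap, wnodf
from .modularity import AnnealingConfig
from .network_model import (
    MULTILAYER,
    InteractionEvent,
    build_layer,
    build_multilayer,
    export_pajek,
    read_events,
)
from .resampling import layer_difference_test, metric_significance, standardized_Q

logger = logging.getLogger(__name__)

COMPARISON_LAYERS = ("EFN", "trophobiont", "flower")

METRIC_FNS = {"H2": h2prime, "WNODF": wnodf, "Horn": horn_overlap}
METRIC_SIDEDNESS = {"H2": "greater", "WNODF": "greater", "Horn": "two-sided"}


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of one pipeline run (JSON-serializable)."""

    n_null: int = 999  # Patefield nulls per metric and per comparison
    n_null_q: int = 1000  # nulls for standardized Q
    best_of_iters: int = 1000  # annealing restarts for observed Q
    n_perm: int = 999  # PERMANOVA permutations
    nmds_starts: int = 20
    alpha: float = 0.05
    include_fruit_in_comparisons: bool = False
    core_per_guild: bool = False
    distance: str = "jaccard"
    comparison_metrics: tuple[str, ...] = ("H2", "WNODF")
    write_matrices: bool = True
    seed: int = 0
    annealing: AnnealingConfig = field(default_factory=AnnealingConfig)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        ann = AnnealingConfig(**raw.pop("annealing", {}))
        if "comparison_metrics" in raw:
            raw["comparison_metrics"] = tuple(raw["comparison_metrics"])
        return cls(annealing=ann, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["comparison_metrics"] = list(d["comparison_metrics"])
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    canonical = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _report_value(x: float) -> float:
    return round(float(x), 10)


def run_pipeline(
    events: "Sequence[InteractionEvent] | str | Path",
    config: Optional[PipelineConfig] = None,
    out_dir: "str | Path | None" = None,
) -> dict:
    """Run the full analysis; return (and optionally write) the report."""
    cfg = config or PipelineConfig()
    if isinstance(events, (str, Path)):
        events = read_events(events)
    events = list(events)
    rng = np.random.default_rng(cfg.seed)

    t_start = time.perf_counter()
    net = build_multilayer(events)
    layers = {MULTILAYER: net.pooled, **{r: m for r, m in net.layers.items()}}

    report: dict = {
        "meta": {
            "antweb_version": __version__,
            "config": cfg.to_dict(),
            "config_hash": _config_hash(cfg),
            "n_events": len(events),
            "n_sites": len({e.site_id for e in events}),
            "pooled_shape": list(net.pooled.shape),
            "pooled_total": net.pooled.F,
        },
        "layers": {},
        "comparisons": [],
        "descriptors": {},
        "cores": {},
        "warnings": [],
    }

    # ---- stage 1: per-layer metrics with null significance
    for name, layer in layers.items():
        entry: dict = {}
        if layer is None:
            entry["status"] = "empty"
            report["layers"][name] = entry
            continue
        entry["status"] = "ok"
        entry["shape"] = list(layer.shape)
        entry["events"] = layer.F
        entry["links"] = layer.n_links
        for metric_name, fn in METRIC_FNS.items():
            seed = int(rng.integers(2**31 - 1))
            try:
                rep = metric_significance(
                    layer,
                    fn,
                    n_null=cfg.n_null,
                    sidedness=METRIC_SIDEDNESS[metric_name],
                    seed=seed,
                )
                entry[metric_name] = {
                    "value": _report_value(rep.metric.value),
                    "p": _report_value(rep.p_value),
                    "null": {k: _report_value(v) for k, v in rep.null_summary().items()},
                    "n_null": rep.n_null,
                    "seed": seed,
                }
            except (UndefinedMetricError, AntwebError) as exc:
                entry[metric_name] = {"undefined": str(exc)}
        seed = int(rng.integers(2**31 - 1))
        try:
            qs = standardized_Q(
                layer,
                n_null=cfg.n_null_q,
                config=cfg.annealing,
                seed=seed,
                n_iter_obs=cfg.best_of_iters,
            )
            entry["Q"] = {
                "value": _report_value(qs.q_obs),
                "standardized": _report_value(qs.z),
                "null_mean": _report_value(qs.null_mean),
                "null_sd": _report_value(qs.null_sd),
                "significant": bool(qs.significant),
                "n_null": qs.n_null,
                "seed": seed,
            }
        except (UndefinedMetricError, AntwebError) as exc:
            entry["Q"] = {"undefined": str(exc)}
        logger.info("layer %s metrics done (%.1fs)", name, time.perf_counter() - t_start)
        report["layers"][name] = entry

    # ---- stage 2: pairwise layer comparisons
    comp_layers = [
        l
        for l in (COMPARISON_LAYERS + (("fruit",) if cfg.include_fruit_in_comparisons else ()))
        if layers.get(l) is not None
    ]
    for i in range(len(comp_layers)):
        for j in range(i + 1, len(comp_layers)):
            a, b = comp_layers[i], comp_layers[j]
            for metric_name in cfg.comparison_metrics:
                seed = int(rng.integers(2**31 - 1))
                try:
                    comp = layer_difference_test(
                        layers[a],
                        layers[b],
                        METRIC_FNS[metric_name],
                        n=cfg.n_null,
                        seed=seed,
                        alpha=cfg.alpha,
                        metric_name=metric_name,
                    )
                    report["comparisons"].append(
                        {
                            "metric": metric_name,
                            "layer_a": a,
                            "layer_b": b,
                            "value_a": _report_value(comp.value_a),
                            "value_b": _report_value(comp.value_b),
                            "observed_diff": _report_value(comp.observed_diff),
                            "p": _report_value(comp.p_value),
                            "significant": bool(comp.significant),
                            "seed": seed,
                        }
                    )
                except AntwebError as exc:
                    report["warnings"].append(f"comparison {a} vs {b} ({metric_name}): {exc}")

    # ---- stage 3: site descriptors + Poisson GLMs
    sites = sorted({e.site_id for e in events})
    desc = descriptor_table(events, COMPARISON_LAYERS, sites=sites)
    report["descriptors"]["table"] = desc.to_dict(orient="records")
    report["descriptors"]["glm"] = {}
    for response in ("size", "richness", "frequency"):
        try:
            dev, ddf, p = poisson_glm_test(desc, response)
            report["descriptors"]["glm"][response] = {
                "deviance": _report_value(dev),
                "df": ddf,
                "p": _report_value(p),
            }
        except AntwebError as exc:
            report["descriptors"]["glm"][response] = {"undefined": str(exc)}

    # ---- stage 4: cores, PERMANOVA, NMDS
    cores = []
    for s in sites:
        for r in COMPARISON_LAYERS:
            try:
                layer = build_layer(events, r, sites=[s])
            except EmptyLayerError:
                continue
            cores.append(extract_core(layer, per_guild=cfg.core_per_guild))
    report["cores"]["membership"] = [
        {
            "site_id": c.site_id,
            "resource": c.resource,
            "core_ants": sorted(c.core_ants),
            "core_plants": sorted(c.core_plants),
            "threshold": _report_value(c.threshold),
        }
        for c in cores
    ]
    nmds_frames: dict[str, pd.DataFrame] = {}
    for guild in ("ants", "plants"):
        seed = int(rng.integers(2**31 - 1))
        try:
            incidence = build_core_incidence(cores, guild=guild)
            D = core_distance_matrix(incidence, distance=cfg.distance)
            res = permanova(
                D,
                incidence["resource"].to_numpy(),
                n_perm=cfg.n_perm,
                seed=seed,
                distance=cfg.distance,
            )
            ord_seed = int(rng.integers(2**31 - 1))
            nm = nmds(D, k=2, n_starts=cfg.nmds_starts, seed=ord_seed, labels=incidence.index)
            report["cores"][guild] = {
                "permanova": {
                    "pseudo_F": _report_value(res.pseudo_F),
                    "R2": _report_value(res.R2),
                    "p": _report_value(res.p_value),
                    "n_perm": res.n_perm,
                    "n_obs": res.n_obs,
                    "seed": seed,
                },
                "nmds_stress": _report_value(nm.stress),
            }
            nmds_frames[guild] = pd.DataFrame(
                nm.coordinates, index=list(nm.labels), columns=["axis1", "axis2"]
            )
        except (DegenerateDesignError, AntwebError) as exc:
            report["cores"][guild] = {"undefined": str(exc)}
            rng.integers(2**31 - 1)  # keep the seed stream aligned

    report["meta"]["runtime_s"] = round(time.perf_counter() - t_start, 3)

    if out_dir is not None:
        _write_outputs(report, layers, desc, cores, nmds_frames, Path(out_dir))
    return report


def _write_outputs(report, layers, desc, cores, nmds_frames, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stable = {k: v for k, v in report.items()}
    stable["meta"] = {k: v for k, v in report["meta"].items() if k != "runtime_s"}
    (out_dir / "report.json").write_text(json.dumps(stable, sort_keys=True, indent=1) + "\n")
    desc.to_csv(out_dir / "descriptors.csv", index=False)
    rows = []
    for c in cores:
        for guild, members in (("ants", c.core_ants), ("plants", c.core_plants)):
            for sp in sorted(members):
                rows.append(
                    {"site_id": c.site_id, "resource": c.resource, "guild": guild, "species": sp}
                )
    pd.DataFrame(rows, columns=["site_id", "resource", "guild", "species"]).to_csv(
        out_dir / "cores.csv", index=False
    )
    for guild, frame in nmds_frames.items():
        frame.to_csv(out_dir / f"nmds_{guild}.csv", index_label="unit")
    if report["meta"]["config"].get("write_matrices", True):
        mat_dir = out_dir / "matrices"
        mat_dir.mkdir(exist_ok=True)
        for name, layer in layers.items():
            if layer is not None:
                layer.to_tsv(mat_dir / f"{name}.tsv")
        pooled = layers.get(MULTILAYER)
        if pooled is not None:
            export_pajek(pooled, mat_dir / "multilayer.net")
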