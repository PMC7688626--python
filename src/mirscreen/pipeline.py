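"""End-to-end orchestration of the screen.

One config drives the whole chain: simulate (or load) the cohort, call DE on
both layers for the disease-vs-control and treated-vs-disease comparisons,
filter and intersect targets, enrich and select pathways, build the
tripartite and count-score-filtered bipartite networks, intersect pairs into
the hub network, select validation hubs, and score qPCR concordance.  The
report collects every stage's summary counts; identical config + seed yields
an identical report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import de as de_mod
from . import enrich as enrich_mod
from . import hubs as hubs_mod
from . import network as net_mod
from . import qpcr as qpcr_mod
from . import targets as targets_mod
from .exceptions import ConfigError, MirscreenError
from .io import (
    read_counts,
    read_gmt,
    read_targets,
    write_network,
)
from .simulate import (
    CohortBundle,
    SimulationConfig,
    evaluate_recovery,
    simulate_cohort,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("mirscreen")


@dataclass
class PipelineConfig:
    """All stage thresholds plus either input paths or a simulation config.

    Threshold defaults are the screen's published cut-offs: alpha 0.05 on raw
    p, |log2FC| > 1 for mRNAs only, binding score > 0.95, top 20 pathways per
    activity stratum, count-score >= 2, hub degree >= 3 with a required
    reversal pattern.
    """

    simulation: SimulationConfig | None = None
    # input paths (used when simulation is None)
    mirna_counts: str | None = None
    mrna_counts: str | None = None
    groups: str | None = None
    targets: str | None = None
    gmt: str | None = None
    signs: str | None = None
    ct: str | None = None
    ct_reference: str = "U6"
    # group roles
    control_group: str = "ND"
    disease_group: str = "WD"
    treated_group: str = "YBT"
    # thresholds
    alpha: float = 0.05
    mirna_lfc_min: float = 0.0
    mrna_lfc_min: float = 1.0
    min_binding: float = 0.95
    top_per_stratum: int = 20
    min_count_score: int = 2
    min_hub_degree: int = 3
    require_reversal: bool = True
    rng_seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if not (0 <= self.alpha <= 1):
            raise ConfigError("alpha must be in [0, 1]")
        if not (0 <= self.min_binding <= 1):
            raise ConfigError("min_binding must be in [0, 1]")
        if self.top_per_stratum < 0 or self.min_count_score < 1 or self.min_hub_degree < 1:
            raise ConfigError("selection thresholds out of range")
        if len({self.control_group, self.disease_group, self.treated_group}) != 3:
            raise ConfigError("group labels must be distinct")
        if self.simulation is None:
            required = ("mirna_counts", "mrna_counts", "groups", "targets", "gmt")
            missing = [k for k in required if getattr(self, k) is None]
            if missing:
                raise ConfigError(f"missing input paths (no simulation given): {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        sim = raw.pop("simulation", None)
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if sim is not None:
            if not isinstance(sim, dict):
                raise ConfigError("simulation section must be a mapping")
            sim.setdefault("rng_seed", cfg.rng_seed)
            try:
                cfg.simulation = SimulationConfig(**sim)
            except TypeError as exc:
                raise ConfigError(f"bad simulation config: {exc}") from None
        return cfg


@dataclass
class PipelineResult:
    """In-memory outputs of one run plus a JSON-serializable summary."""

    config: PipelineConfig
    bundle: CohortBundle | None
    de_tables: dict[str, dict[str, de_mod.DETable]]  # layer -> comparison label -> table
    overlaps: dict[str, targets_mod.OverlapGeneSet]
    enrichments: dict[str, list[enrich_mod.EnrichmentRecord]]
    selections: dict[str, list[enrich_mod.EnrichmentRecord]]
    pathway_patterns: list[enrich_mod.PathwayComparison]
    tripartite: dict[str, Any]
    bipartite: dict[str, Any]
    pairs: dict[str, Any]
    hub_network: Any
    selected_hubs: list[hubs_mod.HubSelection]
    concordance: Any | None
    recovery: Any | None
    summary: dict[str, Any] = field(default_factory=dict)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s: failed after %.2fs: %s", name, dt, exc)
            return False

    return _Timer()


def _load_inputs(config: PipelineConfig) -> CohortBundle | tuple:
    if config.simulation is not None:
        sim = config.simulation
        return simulate_cohort(sim)
    mirna = read_counts(config.mirna_counts, config.groups)
    mrna = read_counts(config.mrna_counts, config.groups)
    target_table = read_targets(config.targets)
    catalog = read_gmt(config.gmt, config.signs)
    ct = None
    if config.ct is not None:
        import pandas as pd

        ct = qpcr_mod.CtTable(
            pd.read_csv(config.ct, sep="\t", dtype={"sample_id": str, "group": str}),
            reference_assay=config.ct_reference,
        )
    return CohortBundle(
        mirna=mirna, mrna=mrna, targets=target_table, catalog=catalog, ct=ct, truth=None
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full screen and return a :class:`PipelineResult`.

    When ``outdir`` (or ``config.outdir``) is set, every stage's tables and
    networks are written there along with ``report.json`` / ``report.tsv``.
    Stage failures propagate wrapped with the stage name; outputs written
    before the failure are retained.
    """
    config.validate()
    outdir = Path(outdir or config.outdir) if (outdir or config.outdir) else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    comparisons = {
        "disease_vs_control": (config.disease_group, config.control_group),
        "treated_vs_disease": (config.treated_group, config.disease_group),
    }
    summary: dict[str, Any] = {"comparisons": {k: f"{t}_vs_{r}" for k, (t, r) in comparisons.items()}}

    def fail(stage: str, exc: Exception):
        raise MirscreenError(f"stage {stage!r} failed: {exc}") from exc

    with _stage("load"):
        try:
            bundle = _load_inputs(config)
        except MirscreenError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            fail("load", exc)

    # ---- differential expression ------------------------------------------
    de_tables: dict[str, dict[str, de_mod.DETable]] = {"mirna": {}, "mrna": {}}
    with _stage("de"):
        for label, pair in comparisons.items():
            de_tables["mirna"][label] = de_mod.call_de(
                bundle.mirna, pair, test="t", alpha=config.alpha,
                lfc_min=config.mirna_lfc_min,
            )
            de_tables["mrna"][label] = de_mod.call_de(
                bundle.mrna, pair, test="nb", alpha=config.alpha,
                lfc_min=config.mrna_lfc_min,
            )
        summary["de"] = {
            layer: {
                label: de_mod.summarize_de(t)._asdict()
                for label, t in tables.items()
            }
            for layer, tables in de_tables.items()
        }

    # ---- target filtering and intersection --------------------------------
    with _stage("intersect"):
        filtered = targets_mod.filter_bindings(bundle.targets, config.min_binding)
        overlaps = {
            label: targets_mod.build_overlap(
                de_tables["mirna"][label], de_tables["mrna"][label], filtered
            )
            for label in comparisons
        }
        summary["overlap"] = {label: len(ov) for label, ov in overlaps.items()}

    # ---- enrichment, selection, cross-comparison --------------------------
    with _stage("enrich"):
        universe = set(bundle.mrna.feature_ids)
        enrichments = {
            label: enrich_mod.enrich_comparison(
                overlaps[label], bundle.catalog, universe, alpha=config.alpha
            )
            for label in comparisons
        }
        selections = {
            label: enrich_mod.select_top_pathways(
                enrichments[label], config.top_per_stratum
            )
            for label in comparisons
        }
        patterns = enrich_mod.cross_compare(
            selections["disease_vs_control"], selections["treated_vs_disease"]
        )
        pattern_counts = {p: 0 for p in enrich_mod.PATTERNS}
        for rec in patterns:
            pattern_counts[rec.pattern] += 1
        summary["enrichment"] = {
            label: enrich_mod.activity_counts(enrichments[label])
            for label in comparisons
        }
        summary["selection"] = {label: len(sel) for label, sel in selections.items()}
        summary["pathway_overlap"] = {
            "n_overlap": len(patterns),
            **pattern_counts,
        }

    # ---- networks ----------------------------------------------------------
    tripartite: dict[str, Any] = {}
    bipartite: dict[str, Any] = {}
    pair_sets: dict[str, Any] = {}
    with _stage("network"):
        summary["network"] = {}
        for label in comparisons:
            tri = net_mod.build_tripartite(
                de_tables["mirna"][label],
                filtered,
                overlaps[label],
                selections[label],
                bundle.catalog,
            )
            pairs = net_mod.count_scores(tri)
            mirna_reg = {
                n: tri.nodes[n]["regulation"]
                for n, d in tri.nodes(data=True)
                if d["type"] == "mirna"
            }
            pw_reg = {
                n: tri.nodes[n]["regulation"]
                for n, d in tri.nodes(data=True)
                if d["type"] == "pathway"
            }
            bip = net_mod.build_mirna_pathway_network(
                pairs, config.min_count_score, mirna_reg, pw_reg
            )
            tripartite[label] = tri
            bipartite[label] = bip
            pair_sets[label] = pairs
            counts = net_mod.network_counts(tri)
            kinds = dict(bip.nodes(data="type"))
            summary["network"][label] = {
                "tripartite": counts._asdict(),
                "tripartite_total_nodes": counts.n_genes + counts.n_mirnas + counts.n_pathways,
                "bipartite": {
                    "n_mirnas": sum(1 for t in kinds.values() if t == "mirna"),
                    "n_pathways": sum(1 for t in kinds.values() if t == "pathway"),
                    "n_edges": bip.number_of_edges(),
                },
            }

    # ---- hub screening -----------------------------------------------------
    with _stage("hubs"):
        hub_pairs = hubs_mod.intersect_pairs(
            bipartite["disease_vs_control"], bipartite["treated_vs_disease"]
        )
        activity_a = {r.pathway_id: r.activity for r in selections["disease_vs_control"]}
        activity_b = {r.pathway_id: r.activity for r in selections["treated_vs_disease"]}
        hub_net = hubs_mod.build_hub_network(
            hub_pairs,
            de_tables["mirna"]["disease_vs_control"],
            de_tables["mirna"]["treated_vs_disease"],
            activity_a,
            activity_b,
        )
        selected = hubs_mod.select_validation_mirnas(
            hub_net, config.min_hub_degree, config.require_reversal
        )
        kinds = dict(hub_net.nodes(data="type"))
        summary["hubs"] = {
            "n_pairs": len(hub_pairs),
            "n_hub_mirnas": sum(1 for t in kinds.values() if t == "mirna"),
            "n_hub_pathways": sum(1 for t in kinds.values() if t == "pathway"),
            "selected": [h._asdict() for h in selected],
        }

    # ---- qPCR validation ---------------------------------------------------
    concord = None
    with _stage("qpcr"):
        if bundle.ct is not None:
            rq = qpcr_mod.delta_delta_ct(
                bundle.ct, control_group=config.control_group
            )
            concord = qpcr_mod.concordance(
                rq,
                {
                    label: de_tables["mirna"][label]
                    for label in comparisons
                },
                alpha=config.alpha,
            )
            summary["qpcr"] = {
                "n_assays": len(set(concord["assay_id"])) if len(concord) else 0,
                "fraction_concordant": (
                    float(concord["concordant"].mean()) if len(concord) else None
                ),
            }

    # ---- recovery against ground truth ------------------------------------
    recovery = None
    if bundle.truth is not None:
        recovery = evaluate_recovery(
            {h.mirna_id: h.pattern for h in selected}, bundle.truth
        )
        summary["recovery"] = recovery._asdict()

    result = PipelineResult(
        config=config,
        bundle=bundle,
        de_tables=de_tables,
        overlaps=overlaps,
        enrichments=enrichments,
        selections=selections,
        pathway_patterns=patterns,
        tripartite=tripartite,
        bipartite=bipartite,
        pairs=pair_sets,
        hub_network=hub_net,
        selected_hubs=selected,
        concordance=concord,
        recovery=recovery,
        summary=summary,
    )
    if outdir:
        _write_outputs(result, outdir)
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    for label, tables in result.de_tables.items():
        for comp, table in tables.items():
            table.write(outdir / f"de_{label}_{comp}.tsv")
    for comp, overlap in result.overlaps.items():
        overlap.write(outdir / f"overlap_{comp}.tsv")
    for comp, records in result.enrichments.items():
        selected_ids = {r.pathway_id for r in result.selections[comp]}
        with open(outdir / f"enrichment_{comp}.tsv", "w", encoding="utf-8") as fh:
            fh.write(
                "pathway_id\tk\tsize\tp_value\tneg_log10_p\tratio\tz\tactivity\tselected\n"
            )
            for r in records:
                z = f"{r.z:.6g}" if r.z is not None else "NA"
                fh.write(
                    f"{r.pathway_id}\t{r.k}\t{r.size}\t{r.p_value:.6g}\t"
                    f"{r.neg_log10_p:.6g}\t{r.ratio:.6g}\t{z}\t{r.activity}\t"
                    f"{int(r.pathway_id in selected_ids)}\n"
                )
    for comp in result.tripartite:
        write_network(result.tripartite[comp], outdir / f"tripartite_{comp}.sif", "sif")
        write_network(
            result.tripartite[comp], outdir / f"tripartite_{comp}.graphml", "graphml"
        )
        result.pairs[comp].to_csv(
            outdir / f"pairs_{comp}.tsv", sep="\t", index=False
        )
        write_network(result.bipartite[comp], outdir / f"bipartite_{comp}.sif", "sif")
    write_network(result.hub_network, outdir / "hub_network.sif", "sif")
    write_network(result.hub_network, outdir / "hub_network.graphml", "graphml")
    with open(outdir / "hubs.tsv", "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tdegree\tpattern\tpathways\n")
        for h in result.selected_hubs:
            pws = sorted(result.hub_network.neighbors(h.mirna_id))
            fh.write(f"{h.mirna_id}\t{h.degree}\t{h.pattern}\t{';'.join(pws)}\n")
    if result.concordance is not None:
        result.concordance.to_csv(outdir / "qpcr_concordance.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "report.tsv", "w", encoding="utf-8") as fh:
        fh.write("key\tvalue\n")
        for key, value in sorted(_flatten(result.summary).items()):
            fh.write(f"{key}\t{value}\n")


def _flatten(d: dict, prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in d.items():
        key = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(v, dict):
            out.update(_flatten(v, key))
        elif isinstance(v, list):
            out[key] = json.dumps(v, sort_keys=True)
        else:
            out[key] = v
    return out
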