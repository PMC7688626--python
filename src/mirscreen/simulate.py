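"""Synthetic three-group cohort with planted hub miRNAs.

Emulates the data shape of a three-arm rodent study — a control group, a
disease group and a treated group, eight animals each — profiled on two count
layers (miRNA and mRNA).  Counts are negative-binomial with Var = mu +
phi * mu^2 and log-normal library sizes.  A handful of planted hub miRNAs are
shifted down in disease and restored by treatment (or the converse); their
true target genes shift oppositely; matching target-table records carry high
binding scores; pathways seeded on those targets carry effect-sign
annotations consistent with the planted shifts, so the full screen can
recover the hubs.  A Ct table for the planted hubs (reference assay U6)
closes the loop with the qPCR module.  Everything is driven by one seeded
generator: identical config + seed gives a byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import (
    ExpressionMatrix,
    PathwayCatalog,
    TargetTable,
    write_counts,
    write_gmt,
    write_targets,
)
from .qpcr import CtTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortBundle",
    "RecoveryResult",
    "simulate_cohort",
    "evaluate_recovery",
    "write_bundle",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults define the study conditions.

    Group sizes, effect magnitudes and dispersion describe a realistic bulk
    small-RNA / mRNA design: n = 8 per arm, ~1.5 log2 units of planted miRNA
    shift, slightly smaller opposite shifts on targets, a common NB
    dispersion of 0.1 and 20% CV log-normal library sizes.
    """

    # cohort shape
    n_per_group: int = 8
    control_group: str = "ND"
    disease_group: str = "WD"
    treated_group: str = "YBT"
    n_mirnas: int = 200
    n_mrnas: int = 2000
    n_pathways: int = 50
    pathway_size: tuple[int, int] = (15, 40)
    # planted structure
    n_planted_hubs: int = 4
    fraction_down_in_disease: float = 0.75
    mirna_effect: float = 1.5  # |log2 FC| of planted miRNAs in disease
    target_effect: float = 1.4  # |log2 FC| of their targets, opposite sign
    restore_fraction: float = 1.0  # 1 = treatment restores control mean fully
    targets_per_mirna: int = 40
    pathways_per_hub: int = 5
    seeded_genes_per_pathway: int = 8
    # count model
    dispersion: float = 0.1  # Var = mu + phi mu^2
    mean_log2: float = 6.0
    sd_log2: float = 1.5
    mean_log2_clip: tuple[float, float] = (2.0, 12.0)
    library_size_cv: float = 0.2
    # binding scores
    true_binding_high_prob: float = 0.9  # P(score > 0.95) for true pairs
    decoy_binding_high_prob: float = 0.1
    # qPCR layer
    ct_base: float = 25.0
    ct_reference: str = "U6"
    ct_reference_base: float = 18.0
    ct_replicates: int = 3
    ct_noise_sd: float = 0.15  # technical, per replicate
    ct_biological_sd: float = 0.25  # per sample, log2 expression scale
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if not (0 < self.fraction_down_in_disease <= 1):
            raise ConfigError("fraction_down_in_disease must be in (0, 1]")
        if self.n_planted_hubs > self.n_mirnas:
            raise ConfigError("more planted hubs than miRNAs")
        if self.n_planted_hubs * self.targets_per_mirna > self.n_mrnas:
            raise ConfigError("planted target blocks exceed the gene pool")
        if self.n_planted_hubs * self.pathways_per_hub > self.n_pathways:
            raise ConfigError("seeded pathways exceed n_pathways")
        if self.seeded_genes_per_pathway > self.targets_per_mirna:
            raise ConfigError("seeded_genes_per_pathway exceeds targets_per_mirna")
        if self.pathway_size[0] > self.pathway_size[1]:
            raise ConfigError("pathway_size range inverted")
        if self.pathway_size[1] > self.n_mrnas:
            raise ConfigError("pathway sizes exceed the gene pool")
        if self.pathway_size[0] < self.seeded_genes_per_pathway:
            raise ConfigError("pathway_size minimum below seeded_genes_per_pathway")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        for name in ("mirna_effect", "target_effect"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        if not (0 <= self.restore_fraction <= 1):
            raise ConfigError("restore_fraction must be in [0, 1]")

    @property
    def groups(self) -> tuple[str, str, str]:
        return (self.control_group, self.disease_group, self.treated_group)


@dataclass
class GroundTruth:
    """What was planted: hubs with direction patterns, targets, seeded pathways."""

    hubs: dict[str, str]  # mirna_id -> "down_up" | "up_down"
    targets: dict[str, frozenset[str]]  # mirna_id -> true target genes
    pathways: dict[str, str]  # seeded pathway_id -> owning hub mirna_id

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("kind\tid\tvalue\n")
            for m in sorted(self.hubs):
                fh.write(f"hub\t{m}\t{self.hubs[m]}\n")
            for m in sorted(self.targets):
                fh.write(f"targets\t{m}\t{';'.join(sorted(self.targets[m]))}\n")
            for p in sorted(self.pathways):
                fh.write(f"pathway\t{p}\t{self.pathways[p]}\n")


class CohortBundle(NamedTuple):
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    targets: TargetTable
    catalog: PathwayCatalog
    ct: CtTable
    truth: GroundTruth


class RecoveryResult(NamedTuple):
    precision: float
    recall: float
    direction_accuracy: float
    n_selected: int
    n_true: int


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB counts with Var = mu + phi mu^2 (Poisson when phi = 0)."""
    if phi == 0:
        return rng.poisson(mean)
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_cohort(config: SimulationConfig | None = None) -> CohortBundle:
    """Generate the full synthetic bundle for one seed.

    Returns miRNA and mRNA count matrices, the target table, the signed
    pathway catalog, the Ct table for the planted hubs, and the ground truth.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    control, disease, treated = config.groups
    samples = [
        f"{group}_{i + 1:02d}" for group in config.groups for i in range(config.n_per_group)
    ]
    groups = {s: s.rsplit("_", 1)[0] for s in samples}

    mirna_ids = [f"mir-{i + 1:04d}" for i in range(config.n_mirnas)]
    gene_ids = [f"gene-{i + 1:05d}" for i in range(config.n_mrnas)]
    pathway_ids = [f"PW-{i + 1:03d}" for i in range(config.n_pathways)]

    # --- planted structure -------------------------------------------------
    hub_idx = rng.choice(config.n_mirnas, size=config.n_planted_hubs, replace=False)
    hub_ids = [mirna_ids[i] for i in hub_idx]
    n_down = int(np.ceil(config.fraction_down_in_disease * config.n_planted_hubs))
    hub_pattern = {
        m: ("down_up" if j < n_down else "up_down") for j, m in enumerate(hub_ids)
    }

    gene_pool = rng.permutation(config.n_mrnas)
    true_targets: dict[str, frozenset[str]] = {}
    for j, m in enumerate(hub_ids):
        block = gene_pool[j * config.targets_per_mirna : (j + 1) * config.targets_per_mirna]
        true_targets[m] = frozenset(gene_ids[i] for i in block)
    planted_genes = set().union(*true_targets.values()) if hub_ids else set()

    # --- group mean factors ------------------------------------------------
    def effect_matrix(ids: list[str], effects: Mapping[str, float]) -> np.ndarray:
        """Per-feature x per-sample multiplicative factors from planted log2
        effects (disease shifted, treatment pulled back toward control)."""
        factors = np.ones((len(ids), len(samples)))
        idx = {f: i for i, f in enumerate(ids)}
        resid = 1.0 - config.restore_fraction
        for fid, lfc in effects.items():
            row = idx[fid]
            for col, s in enumerate(samples):
                if groups[s] == disease:
                    factors[row, col] = 2.0**lfc
                elif groups[s] == treated:
                    factors[row, col] = 2.0 ** (lfc * resid)
        return factors

    mirna_effects = {
        m: (-config.mirna_effect if hub_pattern[m] == "down_up" else config.mirna_effect)
        for m in hub_ids
    }
    gene_effects: dict[str, float] = {}
    for m in hub_ids:
        sign = 1.0 if hub_pattern[m] == "down_up" else -1.0  # opposite to miRNA
        for g in true_targets[m]:
            gene_effects[g] = sign * config.target_effect

    def base_means(n: int) -> np.ndarray:
        logs = rng.normal(config.mean_log2, config.sd_log2, size=n)
        logs = np.clip(logs, *config.mean_log2_clip)
        return 2.0**logs

    lib = np.exp(
        rng.normal(0.0, np.sqrt(np.log(1 + config.library_size_cv**2)), size=len(samples))
    )

    def layer(ids: list[str], effects: Mapping[str, float]) -> ExpressionMatrix:
        mu = base_means(len(ids))[:, None] * effect_matrix(ids, effects) * lib[None, :]
        counts = _nb_draw(rng, mu, config.dispersion)
        return ExpressionMatrix(
            pd.DataFrame(counts, index=pd.Index(ids, name="feature_id"), columns=samples),
            dict(groups),
        )

    mirna = layer(mirna_ids, mirna_effects)
    mrna = layer(gene_ids, gene_effects)

    # --- target table ------------------------------------------------------
    def binding_score(high: bool) -> float:
        if high:
            return 0.95 + 0.05 * rng.uniform(1e-6, 1.0)
        return float(rng.uniform(0.3, 0.95))

    rows = []
    for m in mirna_ids:
        if m in true_targets:
            for g in sorted(true_targets[m]):
                rows.append(
                    (m, g, binding_score(rng.uniform() < config.true_binding_high_prob))
                )
        else:
            decoys = rng.choice(config.n_mrnas, size=config.targets_per_mirna, replace=False)
            for i in sorted(decoys):
                rows.append(
                    (
                        m,
                        gene_ids[i],
                        binding_score(rng.uniform() < config.decoy_binding_high_prob),
                    )
                )
    targets = TargetTable(
        pd.DataFrame(rows, columns=["mirna_id", "gene_id", "binding_score"])
    )

    # --- pathway catalog ---------------------------------------------------
    sets: dict[str, frozenset[str]] = {}
    signs: dict[str, dict[str, int]] = {}
    seeded: dict[str, str] = {}
    non_planted = [g for g in gene_ids if g not in planted_genes]
    pw_cursor = 0
    for m in hub_ids:
        hub_target_list = sorted(true_targets[m])
        for _ in range(config.pathways_per_hub):
            pid = pathway_ids[pw_cursor]
            pw_cursor += 1
            core = rng.choice(
                len(hub_target_list), size=config.seeded_genes_per_pathway, replace=False
            )
            core_genes = [hub_target_list[i] for i in core]
            size = int(rng.integers(config.pathway_size[0], config.pathway_size[1] + 1))
            n_fill = max(0, size - len(core_genes))
            fill = rng.choice(len(non_planted), size=n_fill, replace=False)
            members = set(core_genes) | {non_planted[i] for i in fill}
            sets[pid] = frozenset(members)
            # sign = the direction the gene moves when the pathway's activity
            # increases; seeded genes move with the disease shift
            signs[pid] = {g: (1 if gene_effects[g] > 0 else -1) for g in core_genes}
            seeded[pid] = m
    for pid in pathway_ids[pw_cursor:]:
        size = int(rng.integers(config.pathway_size[0], config.pathway_size[1] + 1))
        members = rng.choice(config.n_mrnas, size=size, replace=False)
        sets[pid] = frozenset(gene_ids[i] for i in members)
    catalog = PathwayCatalog(sets=sets, signs=signs)

    # --- Ct table for the planted hubs -------------------------------------
    ct_rows = []
    loading = rng.normal(0.0, 0.5, size=len(samples))  # per-sample Ct offset
    for s_i, s in enumerate(samples):
        group = groups[s]
        for assay in [config.ct_reference] + sorted(hub_ids):
            if assay == config.ct_reference:
                base = config.ct_reference_base
                rel_log2 = 0.0
            else:
                base = config.ct_base
                lfc = mirna_effects[assay]
                if group == disease:
                    rel_log2 = lfc
                elif group == treated:
                    rel_log2 = lfc * (1.0 - config.restore_fraction)
                else:
                    rel_log2 = 0.0
                rel_log2 += rng.normal(0.0, config.ct_biological_sd)
            for rep in range(1, config.ct_replicates + 1):
                noise = rng.normal(0.0, config.ct_noise_sd)
                ct_rows.append(
                    (s, group, assay, rep, base - rel_log2 + loading[s_i] + noise)
                )
    ct = CtTable(
        pd.DataFrame(ct_rows, columns=["sample_id", "group", "assay_id", "replicate", "ct"]),
        reference_assay=config.ct_reference,
    )

    truth = GroundTruth(hubs=dict(sorted(hub_pattern.items())), targets=true_targets,
                        pathways=seeded)
    return CohortBundle(mirna=mirna, mrna=mrna, targets=targets, catalog=catalog,
                        ct=ct, truth=truth)


def evaluate_recovery(
    selected_hubs: Mapping[str, str] | Iterable[str],
    truth: GroundTruth,
) -> RecoveryResult:
    """Set-based precision / recall of hub recovery plus direction accuracy.

    ``selected_hubs`` maps recovered miRNA id -> direction pattern (or is a
    plain id collection, in which case direction accuracy is vacuously 1).
    With nothing selected precision is defined as 1 and recall as 0;
    direction accuracy is the fraction of true positives whose recovered
    pattern matches the planted one (vacuously 1 with no true positives).
    """
    if isinstance(selected_hubs, Mapping):
        patterns = dict(selected_hubs)
    else:
        patterns = {m: None for m in selected_hubs}
    selected = set(patterns)
    true = set(truth.hubs)
    tp = selected & true
    precision = len(tp) / len(selected) if selected else 1.0
    recall = len(tp) / len(true) if true else 1.0
    if tp:
        matches = sum(
            1
            for m in tp
            if patterns[m] is None or patterns[m] == truth.hubs[m]
        )
        direction_accuracy = matches / len(tp)
    else:
        direction_accuracy = 1.0
    return RecoveryResult(
        precision=precision,
        recall=recall,
        direction_accuracy=direction_accuracy,
        n_selected=len(selected),
        n_true=len(true),
    )


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle artifact in the package's text formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_counts": outdir / "mirna_counts.tsv",
        "mrna_counts": outdir / "mrna_counts.tsv",
        "groups": outdir / "groups.tsv",
        "targets": outdir / "targets.tsv",
        "gmt": outdir / "pathways.gmt",
        "signs": outdir / "pathway_signs.tsv",
        "ct": outdir / "ct.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_counts(bundle.mirna, paths["mirna_counts"], paths["groups"])
    write_counts(bundle.mrna, paths["mrna_counts"])
    write_targets(bundle.targets, paths["targets"])
    write_gmt(bundle.catalog, paths["gmt"], paths["signs"])
    bundle.ct.write(paths["ct"])
    bundle.truth.write(paths["truth"])
    return paths


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
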