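"""Binding-score filtering and DE-target / DE-mRNA intersection.

The screen keeps predicted miRNA->gene pairs whose binding confidence is
strictly above the cut (default 0.95), pools the filtered targets of all DE
miRNAs of a comparison, and intersects that pool with the DE mRNA ids of the
same comparison.  Direction concordance (miRNA up => target down) is not
enforced by default — the intersection is plain set algebra — but is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .de import DETable
from .io import TargetTable

__all__ = ["OverlapGene", "OverlapGeneSet", "filter_bindings", "build_overlap"]


class OverlapGene(NamedTuple):
    direction: int  # +1 up, -1 down in the comparison
    mirnas: frozenset[str]  # DE miRNAs predicted to target the gene


@dataclass
class OverlapGeneSet:
    """Genes DE in one comparison and targeted by >=1 DE miRNA of it."""

    comparison: str
    genes: dict[str, OverlapGene]

    @property
    def gene_ids(self) -> set[str]:
        return set(self.genes)

    def directions(self) -> dict[str, int]:
        return {g: rec.direction for g, rec in self.genes.items()}

    def __len__(self) -> int:
        return len(self.genes)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_id\tdirection\tmirnas\n")
            for gene in sorted(self.genes):
                rec = self.genes[gene]
                label = "up" if rec.direction > 0 else "down"
                fh.write(f"{gene}\t{label}\t{';'.join(sorted(rec.mirnas))}\n")


def filter_bindings(table: TargetTable, min_score: float = 0.95) -> TargetTable:
    """Keep records with binding score strictly greater than ``min_score``."""
    kept = table.records[table.records["binding_score"] > min_score]
    return TargetTable(kept.reset_index(drop=True))


def build_overlap(
    de_mirnas: DETable,
    de_mrnas: DETable,
    targets: TargetTable,
    require_opposite_sign: bool = False,
) -> OverlapGeneSet:
    """Intersect the pooled targets of DE miRNAs with the DE mRNA set.

    ``targets`` must already be binding-filtered.  Each overlap gene is
    annotated with its DE direction and the DE miRNAs targeting it.  With
    ``require_opposite_sign`` a miRNA only counts toward a gene when their DE
    directions are opposite; genes left without a targeting miRNA drop out.
    """
    de_mirna_ids = set(de_mirnas.de_ids)
    de_gene_dir = {g: de_mrnas.direction_of(g) for g in de_mrnas.de_ids}

    by_gene: dict[str, set[str]] = {}
    for row in targets.records.itertuples(index=False):
        if row.mirna_id not in de_mirna_ids or row.gene_id not in de_gene_dir:
            continue
        if require_opposite_sign:
            if de_mirnas.direction_of(row.mirna_id) * de_gene_dir[row.gene_id] >= 0:
                continue
        by_gene.setdefault(row.gene_id, set()).add(row.mirna_id)

    genes = {
        gene: OverlapGene(direction=de_gene_dir[gene], mirnas=frozenset(mirnas))
        for gene, mirnas in by_gene.items()
    }
    return OverlapGeneSet(comparison=de_mrnas.comparison, genes=genes)
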