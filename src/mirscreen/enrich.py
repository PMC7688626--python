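"""Pathway enrichment with activation scoring.

An open gene-set enrichment layer: the enrichment p-value is the
hypergeometric upper tail (one-sided Fisher test) of the overlap-gene count
in each pathway against a stated gene universe; the activation z-score
summarizes concordance between observed DE directions and the pathway's
annotated per-gene effect signs as z = sum(s_i) / sqrt(N) with unit weights,
where s_i = direction_i * sign_i over the N genes carrying both annotations.

Activity classes mirror the four reported categories: increased (z > 0),
decreased (z < 0), zero (z computed and exactly 0), unknown (no annotated
gene overlaps, z undefined).  Selection keeps, among significant pathways,
the top 20 by z among z > 0, the 20 most negative among z < 0, and the top
20 by p among unknown; zero-activity pathways are never selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

from scipy import stats

from .exceptions import DataError
from .io import PathwayCatalog
from .targets import OverlapGeneSet

__all__ = [
    "EnrichmentRecord",
    "PathwayComparison",
    "hypergeom_tail",
    "activation_z",
    "classify_activity",
    "enrich_comparison",
    "select_top_pathways",
    "cross_compare",
    "activity_counts",
]

ACTIVITIES = ("increased", "decreased", "zero", "unknown")
PATTERNS = ("up_then_down", "down_then_up", "same_sign", "unknown_pattern")


@dataclass(frozen=True)
class EnrichmentRecord:
    """One pathway's enrichment result for one comparison."""

    pathway_id: str
    k: int  # overlap genes in the pathway
    size: int  # pathway size within the universe
    p_value: float
    ratio: float  # k / size
    z: float | None  # activation z-score; None when undefined
    activity: str  # increased | decreased | zero | unknown
    significant: bool  # p < alpha (strict)

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value) if self.p_value > 0 else math.inf


class PathwayComparison(NamedTuple):
    """A pathway present in both selections, with its two-comparison pattern."""

    pathway_id: str
    activity_a: str
    activity_b: str
    pattern: str


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise DataError(f"inconsistent hypergeometric arguments K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise DataError(f"k={k} outside [0, min(K={K}, n={n})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def activation_z(
    overlap_directions: Mapping[str, int],
    pathway_signs: Mapping[str, int],
) -> float | None:
    """z = sum(direction_i * sign_i) / sqrt(N) over genes in both maps.

    Returns None (undefined) when no gene carries both a DE direction and a
    pathway sign annotation.
    """
    shared = set(overlap_directions) & set(pathway_signs)
    if not shared:
        return None
    s = sum(overlap_directions[g] * pathway_signs[g] for g in shared)
    return s / math.sqrt(len(shared))


def classify_activity(z: float | None) -> str:
    if z is None:
        return "unknown"
    if z > 0:
        return "increased"
    if z < 0:
        return "decreased"
    return "zero"


def enrich_comparison(
    overlap: OverlapGeneSet,
    catalog: PathwayCatalog,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Enrichment records (k >= 1) for one comparison's overlap gene set.

    ``universe`` is the background gene population; pathway gene sets are
    intersected with it before counting.  Records are sorted by p ascending,
    then pathway id.
    """
    universe = set(universe)
    outside = overlap.gene_ids - universe
    if outside:
        raise DataError(f"overlap gene outside universe: {sorted(outside)[0]!r}")
    directions = overlap.directions()
    n = len(overlap.gene_ids)
    N = len(universe)
    records = []
    for pid in catalog.pathway_ids:
        genes = catalog.sets[pid] & universe
        K = len(genes)
        if K == 0:
            continue
        hit = overlap.gene_ids & genes
        k = len(hit)
        if k == 0:
            continue
        p = hypergeom_tail(k, K, n, N)
        z = activation_z(
            {g: directions[g] for g in hit}, catalog.signs.get(pid, {})
        )
        records.append(
            EnrichmentRecord(
                pathway_id=pid,
                k=k,
                size=K,
                p_value=p,
                ratio=k / K,
                z=z,
                activity=classify_activity(z),
                significant=p < alpha,
            )
        )
    records.sort(key=lambda r: (r.p_value, r.pathway_id))
    return records


def select_top_pathways(
    records: Sequence[EnrichmentRecord],
    n_per_stratum: int = 20,
) -> list[EnrichmentRecord]:
    """Top-20/20/20 selection among significant records.

    Positive-z stratum ranked by z descending, negative-z by z ascending
    (most negative first), unknown by p ascending; ties broken by p then
    pathway id.  Zero-activity records are excluded.  Smaller strata are
    kept whole.
    """
    sig = [r for r in records if r.significant]
    pos = sorted(
        (r for r in sig if r.activity == "increased"),
        key=lambda r: (-r.z, r.p_value, r.pathway_id),
    )
    neg = sorted(
        (r for r in sig if r.activity == "decreased"),
        key=lambda r: (r.z, r.p_value, r.pathway_id),
    )
    unk = sorted(
        (r for r in sig if r.activity == "unknown"),
        key=lambda r: (r.p_value, r.pathway_id),
    )
    return pos[:n_per_stratum] + neg[:n_per_stratum] + unk[:n_per_stratum]


def _pattern(activity_a: str, activity_b: str) -> str:
    if "unknown" in (activity_a, activity_b) or "zero" in (activity_a, activity_b):
        return "unknown_pattern"
    if activity_a == "increased" and activity_b == "decreased":
        return "up_then_down"
    if activity_a == "decreased" and activity_b == "increased":
        return "down_then_up"
    return "same_sign"


def cross_compare(
    selected_a: Sequence[EnrichmentRecord],
    selected_b: Sequence[EnrichmentRecord],
) -> list[PathwayComparison]:
    """Pathways selected in both comparisons, with their activity pattern.

    Pattern is up_then_down / down_then_up for sign reversals, same_sign when
    both activities share a sign, unknown_pattern when either is unknown.
    Sorted by pathway id.
    """
    by_id_a = {r.pathway_id: r for r in selected_a}
    by_id_b = {r.pathway_id: r for r in selected_b}
    out = []
    for pid in sorted(set(by_id_a) & set(by_id_b)):
        a, b = by_id_a[pid], by_id_b[pid]
        out.append(
            PathwayComparison(
                pathway_id=pid,
                activity_a=a.activity,
                activity_b=b.activity,
                pattern=_pattern(a.activity, b.activity),
            )
        )
    return out


def activity_counts(records: Sequence[EnrichmentRecord],
                    significant_only: bool = True) -> dict[str, int]:
    """Counts per activity class plus their total (keys: the four classes
    and ``total``)."""
    pool = [r for r in records if r.significant] if significant_only else list(records)
    counts = {a: 0 for a in ACTIVITIES}
    for r in pool:
        counts[r.activity] += 1
    counts["total"] = len(pool)
    return counts
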