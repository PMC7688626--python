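"""Differential expression for the two count layers.

miRNAs are tested per feature with a two-sample t-test on log2(CPM + 1)
(p < 0.05, no fold-change cut); mRNAs with a negative-binomial exact test on
library-size-equalized pseudocounts (p < 0.05 and |log2 fold change| > 1).
The NB exact test conditions on the two group totals under a shared mean and
a common moment-estimated dispersion; at dispersion 0 it reduces to the
binomial (conditional Poisson) test.  Raw p-values are filtered directly —
no multiple-testing correction by default — with Benjamini-Hochberg available
as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, DataError
from .io import ExpressionMatrix

__all__ = [
    "DETable",
    "DESummary",
    "cpm_normalize",
    "log_fold_change",
    "t_test_feature",
    "equalize_libraries",
    "nb_exact_test",
    "estimate_common_dispersion",
    "call_de",
    "summarize_de",
    "parse_comparison",
]


@dataclass
class DETable:
    """Per-feature DE results for one comparison (test group over reference).

    ``table`` is indexed by feature id with columns ``log2fc``, ``p_value``
    and ``call`` in {up, down, ns}.
    """

    comparison: str  # e.g. "WD_vs_ND"
    test_group: str
    ref_group: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"log2fc", "p_value", "call"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataError(f"DE table missing columns: {sorted(missing)}")
        p = self.table["p_value"]
        if len(p) and ((p < 0) | (p > 1)).any():
            raise DataError("p-values outside [0, 1]")
        bad = set(self.table["call"]) - {"up", "down", "ns"}
        if bad:
            raise DataError(f"unknown call values: {sorted(bad)}")

    @property
    def up_ids(self) -> list[str]:
        return list(self.table.index[self.table["call"] == "up"])

    @property
    def down_ids(self) -> list[str]:
        return list(self.table.index[self.table["call"] == "down"])

    @property
    def de_ids(self) -> list[str]:
        return list(self.table.index[self.table["call"] != "ns"])

    def direction_of(self, feature_id: str) -> int:
        """+1 for up, -1 for down, 0 for ns."""
        call = self.table.at[feature_id, "call"]
        return {"up": 1, "down": -1, "ns": 0}[call]

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("feature_id\tlog2fc\tp_value\tcall\n")
            for fid, row in self.table.iterrows():
                fh.write(
                    f"{fid}\t{row['log2fc']:.6g}\t{row['p_value']:.6g}\t{row['call']}\n"
                )


class DESummary(NamedTuple):
    n_up: int
    n_down: int
    n_total: int


def parse_comparison(comparison: str | tuple[str, str]) -> tuple[str, str]:
    """Parse ``"TEST:REF"`` (or a tuple) into (test_group, ref_group)."""
    if isinstance(comparison, tuple):
        test, ref = comparison
        return test, ref
    if comparison.count(":") != 1:
        raise ConfigError(f"comparison must be 'TEST:REF', got {comparison!r}")
    test, ref = comparison.split(":")
    return test, ref


# ---------------------------------------------------------------------------
# Normalization and fold changes
# ---------------------------------------------------------------------------


def cpm_normalize(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Counts-per-million: each sample column rescaled to sum to 10^6."""
    libsizes = matrix.counts.sum(axis=0)
    zero = libsizes[libsizes == 0]
    if len(zero):
        raise DataError(f"all-zero sample: {zero.index[0]!r}")
    return matrix.counts / libsizes * 1e6


def log_fold_change(mean_test: float, mean_ref: float, pseudocount: float = 0.0) -> float:
    """log2((mean_test + pc) / (mean_ref + pc))."""
    if mean_test < 0 or mean_ref < 0:
        raise DataError("means must be non-negative")
    if pseudocount < 0:
        raise DataError("pseudocount must be non-negative")
    if pseudocount == 0 and (mean_test == 0 or mean_ref == 0):
        raise DataError("zero mean requires a positive pseudocount")
    return float(np.log2((mean_test + pseudocount) / (mean_ref + pseudocount)))


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def t_test_feature(
    values_test: Sequence[float],
    values_ref: Sequence[float],
    equal_var: bool = True,
) -> float:
    """Two-sided two-sample t-test p-value (pooled variance by default).

    A degenerate feature (zero variance in both groups) returns p = 1 when
    the group means are equal and p = 0 otherwise.
    """
    a = np.asarray(values_test, dtype=float)
    b = np.asarray(values_ref, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("t-test needs >=2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.pvalue)


def equalize_libraries(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample to the geometric-mean library size, rounding
    half-to-even to integer pseudocounts."""
    libsizes = counts.sum(axis=0).to_numpy(dtype=float)
    if (libsizes == 0).any():
        bad = counts.columns[np.argwhere(libsizes == 0)[0][0]]
        raise DataError(f"all-zero sample: {bad!r}")
    target = math.exp(np.mean(np.log(libsizes)))
    scaled = counts.to_numpy(dtype=float) * (target / libsizes)
    return pd.DataFrame(
        np.rint(scaled).astype(np.int64), index=counts.index, columns=counts.columns
    )


def _group_sum_pmf(k: np.ndarray, n_samples: int, mu_per_sample: float,
                   phi: float) -> np.ndarray:
    """pmf of the sum of ``n_samples`` iid NB(mu, phi) counts.

    The sum is NB with mean n*mu and dispersion phi/n (sizes add).  phi = 0
    degenerates to Poisson.
    """
    mean = n_samples * mu_per_sample
    if phi == 0:
        return stats.poisson.pmf(k, mean)
    size = n_samples / phi
    p = size / (size + mean)
    return stats.nbinom.pmf(k, size, p)


def nb_exact_test(
    counts_test: Sequence[int],
    counts_ref: Sequence[int],
    dispersion: float,
) -> float:
    """Exact NB test conditioning on the two group totals.

    Under a shared per-sample mean and common dispersion, the two-sided
    p-value sums the conditional probabilities of every split of the combined
    total that is no more likely than the observed one.  With dispersion 0
    this is the conditional Poisson (binomial) test.
    """
    if dispersion < 0:
        raise DataError("dispersion must be >= 0")
    a = np.asarray(counts_test, dtype=np.int64)
    b = np.asarray(counts_ref, dtype=np.int64)
    if (a < 0).any() or (b < 0).any():
        raise DataError("counts must be non-negative")
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise DataError("both groups need >=1 sample")
    y_a, y_b = int(a.sum()), int(b.sum())
    total = y_a + y_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    k = np.arange(total + 1)
    with np.errstate(over="ignore", invalid="ignore"):
        probs = _group_sum_pmf(k, n_a, mu, dispersion) * _group_sum_pmf(
            total - k, n_b, mu, dispersion
        )
    norm = probs.sum()
    if not np.isfinite(norm) or norm <= 0:
        return 1.0
    observed = probs[y_a]
    # relative tolerance guards against float noise splitting exact ties
    p = probs[probs <= observed * (1 + 1e-10)].sum() / norm
    return float(min(1.0, p))


def estimate_common_dispersion(
    matrix: ExpressionMatrix | pd.DataFrame,
    groups: dict[str, str] | None = None,
) -> float:
    """Moment-based common NB dispersion under Var = mu + phi * mu^2.

    For every feature, (s^2 - m) / m^2 is computed within each group with
    replicates (on library-equalized counts) and averaged; the estimate is
    the median over features of max(0, value).  Never negative.
    """
    if isinstance(matrix, ExpressionMatrix):
        counts, groups = matrix.counts, matrix.groups
    else:
        counts = matrix
        if groups is None:
            raise DataError("groups required when passing a raw DataFrame")
    eq = equalize_libraries(counts)
    by_group: dict[str, list[str]] = {}
    for sample, group in groups.items():
        if sample in eq.columns:
            by_group.setdefault(group, []).append(sample)
    replicated = {g: s for g, s in by_group.items() if len(s) >= 2}
    if not replicated:
        raise DataError("no group has replicate samples")
    per_feature = []
    for _, row in eq.iterrows():
        vals = []
        for samples in replicated.values():
            x = row[samples].to_numpy(dtype=float)
            m = x.mean()
            if m > 0:
                vals.append((x.var(ddof=1) - m) / m**2)
        if vals:
            per_feature.append(float(np.mean(vals)))
    if not per_feature:
        return 0.0
    return float(max(0.0, np.median(per_feature)))


# ---------------------------------------------------------------------------
# DE calling
# ---------------------------------------------------------------------------


def call_de(
    matrix: ExpressionMatrix,
    comparison: str | tuple[str, str],
    test: str = "t",
    alpha: float = 0.05,
    lfc_min: float = 0.0,
    dispersion: float | None = None,
    pseudocount: float = 0.5,
    equal_var: bool = True,
    adjust: str | None = None,
) -> DETable:
    """Call differential expression for one TEST:REF comparison.

    test="t": per-feature pooled-variance t-test on log2(CPM + 1).
    test="nb": NB exact test on library-equalized counts, with the common
    dispersion estimated from the two groups when not supplied.

    Calls use strict inequalities: up/down iff p < alpha and |log2fc| >
    lfc_min, with the sign of log2fc (computed from mean CPM with a
    pseudocount) deciding the direction.  ``adjust="bh"`` applies
    Benjamini-Hochberg before thresholding (off by default).
    """
    if test not in ("t", "nb"):
        raise ConfigError(f"unknown test {test!r}; expected 't' or 'nb'")
    if not (0 <= alpha <= 1):
        raise ConfigError("alpha must be in [0, 1]")
    test_group, ref_group = parse_comparison(comparison)
    present = set(matrix.groups.values())
    for g in (test_group, ref_group):
        if g not in present:
            raise DataError(f"unknown group: {g!r}")
    sub = matrix.subset_groups([test_group, ref_group])
    test_samples = sub.samples_in(test_group)
    ref_samples = sub.samples_in(ref_group)

    cpm = cpm_normalize(sub)
    mean_test = cpm[test_samples].mean(axis=1)
    mean_ref = cpm[ref_samples].mean(axis=1)
    log2fc = np.log2((mean_test + pseudocount) / (mean_ref + pseudocount))

    col = {s: i for i, s in enumerate(sub.sample_ids)}
    test_idx = [col[s] for s in test_samples]
    ref_idx = [col[s] for s in ref_samples]
    if test == "t":
        logcpm = np.log2(cpm.to_numpy() + 1.0)
        pvals = np.array(
            [
                t_test_feature(row[test_idx], row[ref_idx], equal_var=equal_var)
                for row in logcpm
            ]
        )
    else:
        eq = equalize_libraries(sub.counts)
        phi = (
            dispersion
            if dispersion is not None
            else estimate_common_dispersion(eq, sub.groups)
        )
        eq_np = eq.to_numpy()
        pvals = np.array(
            [nb_exact_test(row[test_idx], row[ref_idx], phi) for row in eq_np]
        )

    if adjust == "bh":
        pvals = stats.false_discovery_control(pvals, method="bh")
    elif adjust is not None:
        raise ConfigError(f"unknown adjustment {adjust!r}")

    significant = (pvals < alpha) & (np.abs(log2fc.to_numpy()) > lfc_min)
    calls = np.where(
        significant & (log2fc.to_numpy() > 0),
        "up",
        np.where(significant & (log2fc.to_numpy() < 0), "down", "ns"),
    )
    table = pd.DataFrame(
        {"log2fc": log2fc.to_numpy(), "p_value": pvals, "call": calls},
        index=pd.Index(sub.feature_ids, name="feature_id"),
    )
    return DETable(
        comparison=f"{test_group}_vs_{ref_group}",
        test_group=test_group,
        ref_group=ref_group,
        table=table,
    )


def summarize_de(table: DETable) -> DESummary:
    """Counts of up-, down-regulated and total DE features; total = up + down."""
    n_up = int((table.table["call"] == "up").sum())
    n_down = int((table.table["call"] == "down").sum())
    return DESummary(n_up=n_up, n_down=n_down, n_total=n_up + n_down)
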