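"""Relative quantification from qPCR Ct values and group statistics.

Implements the Livak 2^-ddCt method: replicate Ct values are averaged per
(sample, assay); dCt = Ct_assay - Ct_reference within each sample; ddCt
subtracts the control group's mean dCt; RQ = 2^-ddCt.  Group differences are
tested with one-way ANOVA followed by Fisher's LSD (pairwise t-tests sharing
the ANOVA pooled mean-square error and its degrees of freedom), and each
assay's shift is scored for direction concordance with the sequencing DE
calls.  Amplification efficiency is fixed at 2 (no efficiency correction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import DETable
from .exceptions import DataError

__all__ = [
    "CtTable",
    "RQTable",
    "AnovaLsdResult",
    "delta_delta_ct",
    "anova_lsd",
    "concordance",
    "significance_stars",
]

CT_COLUMNS = ("sample_id", "group", "assay_id", "replicate", "ct")


@dataclass
class CtTable:
    """Raw Ct replicates: (sample, group, assay, replicate, Ct) records.

    ``reference_assay`` names the internal-control assay (e.g. U6 for the
    miRNA layer, beta-actin for mRNA); it must be measured for every sample.
    """

    data: pd.DataFrame
    reference_assay: str

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise DataError(f"Ct table missing columns: {missing}")
        df = self.data.loc[:, list(CT_COLUMNS)].copy()
        df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
        if df["ct"].isna().any() or not np.isfinite(df["ct"]).all():
            bad = df.loc[~np.isfinite(df["ct"].fillna(np.nan))].iloc[0]
            raise DataError(
                f"non-finite Ct for sample {bad['sample_id']!r}, assay {bad['assay_id']!r}"
            )
        outside = (df["ct"] < 5) | (df["ct"] > 40)
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} Ct values outside the typical 5-40 range",
                stacklevel=2,
            )
        samples = set(df["sample_id"])
        with_ref = set(df.loc[df["assay_id"] == self.reference_assay, "sample_id"])
        if samples - with_ref:
            missing_s = sorted(samples - with_ref)[0]
            raise DataError(
                f"reference assay {self.reference_assay!r} missing for sample {missing_s!r}"
            )
        # group must be consistent per sample
        per_sample = df.groupby("sample_id")["group"].nunique()
        if (per_sample > 1).any():
            raise DataError(
                f"sample with conflicting group labels: {per_sample.idxmax()!r}"
            )
        self.data = df.reset_index(drop=True)

    @property
    def assay_ids(self) -> list[str]:
        return sorted(set(self.data["assay_id"]))

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(CT_COLUMNS) + "\n")
            for row in self.data.itertuples(index=False):
                fh.write(
                    f"{row.sample_id}\t{row.group}\t{row.assay_id}\t"
                    f"{row.replicate}\t{row.ct:.4f}\n"
                )


@dataclass
class RQTable:
    """Per-(sample, assay) relative quantities with their dCt / ddCt."""

    per_sample: pd.DataFrame  # sample_id, group, assay_id, delta_ct, delta_delta_ct, rq
    control_group: str
    reference_assay: str

    def values(self, assay_id: str) -> pd.DataFrame:
        df = self.per_sample
        return df[df["assay_id"] == assay_id]

    def group_values(self, assay_id: str, group: str) -> np.ndarray:
        df = self.values(assay_id)
        return df.loc[df["group"] == group, "rq"].to_numpy()

    def group_summary(self) -> pd.DataFrame:
        """Mean +/- SD of RQ per (assay, group)."""
        return (
            self.per_sample.groupby(["assay_id", "group"])["rq"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )


class AnovaLsdResult(NamedTuple):
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    lsd: dict[tuple[str, str], float]  # pairwise LSD p-values


def delta_delta_ct(
    ct: CtTable, reference_assay: str | None = None, control_group: str = "ND"
) -> RQTable:
    """2^-ddCt relative quantities referenced to the control group mean dCt."""
    reference_assay = reference_assay or ct.reference_assay
    df = ct.data
    mean_ct = (
        df.groupby(["sample_id", "group", "assay_id"], as_index=False)["ct"].mean()
    )
    ref = mean_ct[mean_ct["assay_id"] == reference_assay].set_index("sample_id")["ct"]
    mean_ct["delta_ct"] = mean_ct["ct"] - mean_ct["sample_id"].map(ref).to_numpy()

    if control_group not in set(df["group"]):
        raise DataError(f"control group {control_group!r} not present in Ct table")
    rows = []
    for assay, sub in mean_ct.groupby("assay_id"):
        control_dct = sub.loc[sub["group"] == control_group, "delta_ct"]
        if control_dct.empty:
            raise DataError(
                f"control group {control_group!r} empty for assay {assay!r}"
            )
        baseline = control_dct.mean()
        for row in sub.itertuples(index=False):
            ddct = row.delta_ct - baseline
            rows.append(
                (row.sample_id, row.group, assay, row.delta_ct, ddct, 2.0 ** (-ddct))
            )
    per_sample = pd.DataFrame(
        rows,
        columns=["sample_id", "group", "assay_id", "delta_ct", "delta_delta_ct", "rq"],
    ).sort_values(["assay_id", "sample_id"], ignore_index=True)
    return RQTable(
        per_sample=per_sample,
        control_group=control_group,
        reference_assay=reference_assay,
    )


def anova_lsd(
    rq: RQTable,
    assay: str,
    groups: Sequence[str] | None = None,
    on: str = "rq",
) -> AnovaLsdResult:
    """One-way ANOVA across groups with Fisher's LSD post-hoc tests.

    ``on`` selects the analysed scale: ``"rq"`` (the plotted quantity,
    default) or ``"delta_ct"``.  LSD p-values come from pairwise t statistics
    using the ANOVA pooled MSE and its within-group degrees of freedom; for
    two groups the LSD p equals the pooled-variance t-test p.
    """
    if on not in ("rq", "delta_ct"):
        raise DataError(f"unknown analysis scale {on!r}")
    df = rq.values(assay)
    if df.empty:
        raise DataError(f"no RQ values for assay {assay!r}")
    if groups is None:
        groups = sorted(set(df["group"]))
    samples = {g: df.loc[df["group"] == g, on].to_numpy(dtype=float) for g in groups}
    for g, x in samples.items():
        if len(x) < 2:
            raise DataError(f"group {g!r} needs >=2 samples for ANOVA")
    k = len(groups)
    if k < 2:
        raise DataError("ANOVA needs >=2 groups")
    n_total = sum(len(x) for x in samples.values())
    grand = np.concatenate(list(samples.values())).mean()
    ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in samples.values())
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in samples.values())
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0:
        if ss_between == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = math.inf, 0.0
    else:
        mse = ss_within / df_within
        f_stat = (ss_between / df_between) / mse
        p = float(stats.f.sf(f_stat, df_between, df_within))
    lsd: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            g1, g2 = groups[i], groups[j]
            x1, x2 = samples[g1], samples[g2]
            if ss_within == 0:
                lsd[(g1, g2)] = 1.0 if x1.mean() == x2.mean() else 0.0
                continue
            se = math.sqrt(mse * (1 / len(x1) + 1 / len(x2)))
            t = (x1.mean() - x2.mean()) / se
            lsd[(g1, g2)] = float(2 * stats.t.sf(abs(t), df_within))
    return AnovaLsdResult(
        f_statistic=float(f_stat),
        p_value=float(p),
        df_between=df_between,
        df_within=df_within,
        lsd=lsd,
    )


def significance_stars(p: float) -> str:
    """Conventional significance marks: ** for p < 0.01, * for p < 0.05."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def concordance(
    rq: RQTable,
    de_tables: Mapping[str, DETable],
    assay_map: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Direction agreement between qPCR shifts and sequencing DE calls.

    For every assay and every comparison (keyed by the DE table's
    test/reference groups) the assay is concordant when the sign of the log2
    mean-RQ ratio matches the DE direction and the pairwise LSD p-value is
    below ``alpha``.  ``assay_map`` translates assay ids to feature ids
    (identity by default); unmapped assays are excluded with a warning.
    """
    assay_map = dict(assay_map or {})
    rows = []
    assays = [a for a in rq.per_sample["assay_id"].unique() if a != rq.reference_assay]
    for label, de in de_tables.items():
        for assay in assays:
            feature = assay_map.get(assay, assay)
            if feature not in de.table.index:
                warnings.warn(
                    f"assay {assay!r} has no matching feature in {de.comparison}; skipped",
                    stacklevel=2,
                )
                continue
            test_vals = rq.group_values(assay, de.test_group)
            ref_vals = rq.group_values(assay, de.ref_group)
            if len(test_vals) == 0 or len(ref_vals) == 0:
                warnings.warn(
                    f"assay {assay!r} lacks RQ values for {de.comparison}; skipped",
                    stacklevel=2,
                )
                continue
            log2_ratio = math.log2(test_vals.mean() / ref_vals.mean())
            res = anova_lsd(rq, assay, groups=sorted({de.test_group, de.ref_group}))
            lsd_p = next(iter(res.lsd.values()))
            de_dir = de.direction_of(feature)
            qpcr_dir = 1 if log2_ratio > 0 else (-1 if log2_ratio < 0 else 0)
            concordant = bool(de_dir != 0 and qpcr_dir == de_dir and lsd_p < alpha)
            rows.append(
                (label, assay, feature, log2_ratio, lsd_p, de_dir, qpcr_dir, concordant)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "comparison",
            "assay_id",
            "feature_id",
            "log2_rq_ratio",
            "lsd_p",
            "de_direction",
            "qpcr_direction",
            "concordant",
        ],
    )
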