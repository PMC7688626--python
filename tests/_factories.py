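"""Hand-construction helpers for small test objects."""

from __future__ import annotations

import math

import pandas as pd

from mirscreen.de import DETable
from mirscreen.enrich import EnrichmentRecord, classify_activity
from mirscreen.io import ExpressionMatrix, TargetTable


def make_matrix(counts: dict[str, list[int]], groups: dict[str, str],
                features: list[str] | None = None) -> ExpressionMatrix:
    """counts: sample -> column of counts."""
    df = pd.DataFrame(counts)
    if features is not None:
        df.index = features
    else:
        df.index = [f"f{i}" for i in range(len(df))]
    return ExpressionMatrix(df, groups)


def make_de_table(
    comparison: str = "WD_vs_ND",
    up: list[str] = (),
    down: list[str] = (),
    ns: list[str] = (),
) -> DETable:
    rows = (
        [(f, 2.0, 0.01, "up") for f in up]
        + [(f, -2.0, 0.01, "down") for f in down]
        + [(f, 0.1, 0.5, "ns") for f in ns]
    )
    table = pd.DataFrame(
        rows, columns=["feature_id", "log2fc", "p_value", "call"]
    ).set_index("feature_id")
    test, ref = comparison.split("_vs_")
    return DETable(comparison=comparison, test_group=test, ref_group=ref, table=table)


def make_targets(pairs: list[tuple[str, str, float]]) -> TargetTable:
    return TargetTable(
        pd.DataFrame(pairs, columns=["mirna_id", "gene_id", "binding_score"])
    )


def make_record(
    pathway_id: str,
    z: float | None,
    p: float = 0.01,
    k: int = 3,
    size: int = 30,
    alpha: float = 0.05,
) -> EnrichmentRecord:
    return EnrichmentRecord(
        pathway_id=pathway_id,
        k=k,
        size=size,
        p_value=p,
        ratio=k / size,
        z=z,
        activity=classify_activity(z),
        significant=p < alpha,
    )


def t_density_pvalue(t_stat: float, df: int) -> float:
    """Two-sided t p-value by numeric integration of the t density."""
    import numpy as np

    const = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    x = np.linspace(abs(t_stat), abs(t_stat) + 600.0, 1_200_001)
    pdf = const * (1 + x**2 / df) ** (-(df + 1) / 2)
    return float(2 * np.trapezoid(pdf, x))
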