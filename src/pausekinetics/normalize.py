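"""Library-size normalization and replicate averaging.

Size factors follow the median-of-ratios estimator: each control gene
contributes the ratio of its count to its geometric mean across samples, and
a sample's factor is the median of those ratios.  For globally repressive
treatments the control set is restricted to long genes whose distal bodies
cannot have been reached by polymerases initiated during the treatment.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = ["size_factors", "apply_normalization"]


def size_factors(
    count_table: pd.DataFrame,
    control_genes: Iterable[str] | None = None,
) -> pd.Series:
    """Median-of-ratios size factors, one per sample (column).

    ``count_table`` is genes x samples with non-negative counts.  Genes with
    any zero count are excluded (their geometric-mean ratio is degenerate).
    ``control_genes`` restricts the estimator to a subset of row labels; None
    uses all genes.
    """
    table = count_table
    if control_genes is not None:
        control = [g for g in control_genes if g in table.index]
        table = table.loc[control]
    if (table.values < 0).any():
        raise InvalidParameterError("counts must be >= 0")
    usable = table[(table > 0).all(axis=1)]
    if usable.empty:
        raise InvalidParameterError(
            "no usable control genes (all have a zero count in some sample)"
        )
    log_geo_mean = np.log(usable).mean(axis=1)
    log_ratios = np.log(usable).sub(log_geo_mean, axis=0)
    factors = np.exp(log_ratios.median(axis=0))
    factors.name = "size_factor"
    return factors


def apply_normalization(
    densities: pd.DataFrame,
    factors: Mapping[str, float] | pd.Series,
    sample_key: tuple[str, ...] = ("condition", "replicate"),
) -> pd.DataFrame:
    """Divide densities by per-sample factors, then average replicates.

    ``factors`` is keyed by "condition:replicate" (or by condition alone when
    one replicate).  Replicate records for a gene/condition are averaged
    after normalization.  Returns one row per gene and condition with
    replicate set to "mean".
    """
    if densities.empty:
        return densities.copy()
    df = densities.copy()

    def factor_for(row: pd.Series) -> float:
        key = ":".join(str(row[k]) for k in sample_key)
        if key in factors:
            return float(factors[key])
        if row["condition"] in factors:
            return float(factors[row["condition"]])
        raise InvalidParameterError(f"no size factor for sample {key!r}")

    f = df.apply(factor_for, axis=1)
    df["pause_sum"] = df["pause_sum"] / f
    df["body_mean"] = df["body_mean"] / f

    group_cols = [
        "gene_id", "chrom", "strand", "pause_start", "pause_end",
        "body_start", "body_end", "condition",
    ]
    out = (
        df.groupby(group_cols, as_index=False, sort=False)[["pause_sum", "body_mean"]]
        .mean()
    )
    out["replicate"] = "mean"
    return out
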