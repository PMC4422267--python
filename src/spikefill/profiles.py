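"""Expression-profile utilities: log2 matrices, clustering, double
normalization, and miRNA–target anti-correlation.

Heat-map style analyses run on log2(TPM) of a floored expression matrix.
Profile clustering is agglomerative with average linkage on correlation
distance (1 - Pearson r between entity profiles) — the standard choice for
expression heat maps; both linkage and the flat-cut parameter are
arguments.  qRT-PCR style series are double-normalized: first to a
reference RNA (e.g. 5.8S rRNA) within each sample, then to the baseline
sample (superior spikelets at 10 DAF), which is defined to be 1.0.
"""

from __future__ import annotations

import math
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from spikefill.io import ExpressionMatrix


def double_normalize(
    raw_target: Mapping[str, float],
    raw_reference: Mapping[str, float],
    baseline_sample: str,
) -> dict[str, float]:
    """Reference-then-baseline normalization of a qRT-PCR style series.

    ``value_s = (target_s / reference_s) / (target_b / reference_b)`` for
    baseline sample ``b``; the baseline value is exactly 1.0 and the
    result is invariant to rescaling either input globally.
    """
    if baseline_sample not in raw_target or baseline_sample not in raw_reference:
        raise KeyError(f"baseline sample {baseline_sample!r} missing from the series")
    missing_ref = [s for s in raw_target if s not in raw_reference]
    if missing_ref:
        raise KeyError(f"no reference quantity for sample(s) {missing_ref}")
    if any(v <= 0 for v in raw_reference.values()):
        raise ValueError("reference quantities must be strictly positive")
    base = raw_target[baseline_sample] / raw_reference[baseline_sample]
    if base <= 0:
        raise ValueError("baseline target quantity must be strictly positive")
    return {s: (raw_target[s] / raw_reference[s]) / base for s in raw_target}


def log2_profile_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Elementwise log2 of a floored TPM matrix (no zeros allowed)."""
    if (expr <= 0).any().any():
        raise ValueError(
            "log2 profile requires strictly positive entries; apply the "
            "0.01 TPM floor first"
        )
    return np.log2(expr)


def cluster_profiles(
    log2_matrix: pd.DataFrame,
    k: int | None = None,
    linkage_method: str = "average",
    distance_threshold: float = 0.5,
) -> tuple[pd.Series, pd.DataFrame, np.ndarray]:
    """Hierarchically cluster entity expression profiles.

    Distance is 1 - Pearson correlation between entity rows; linkage is
    average by default.  Flat clusters are cut at ``k`` clusters when
    given, else at ``distance_threshold`` on the cophenetic distance.
    Returns ``(assignments, matrix in dendrogram leaf order, linkage)``.
    The result is deterministic and, as a partition, invariant to the
    order entities are supplied in.
    """
    n = log2_matrix.shape[0]
    if n < 2:
        raise ValueError(f"clustering needs >= 2 entities, got {n}")
    if k is not None and k > n:
        raise ValueError(f"cannot cut {n} entities into {k} clusters")
    dist = pdist(log2_matrix.to_numpy(), metric="correlation")
    if np.any(~np.isfinite(dist)):
        raise ValueError("constant profiles make correlation distance undefined")
    Z = hierarchy.linkage(dist, method=linkage_method)
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    else:
        flat = hierarchy.fcluster(Z, t=distance_threshold, criterion="distance")
    order = hierarchy.leaves_list(Z)
    assignments = pd.Series(flat, index=log2_matrix.index, name="cluster")
    return assignments, log2_matrix.iloc[order], Z


def mirna_target_correlation(
    mirna_series: Sequence[float],
    target_series: Sequence[float],
    method: Literal["pearson", "spearman"] = "pearson",
) -> float:
    """Correlation between a miRNA's series and its putative target's.

    A strong negative value across grain-filling stages is the expression
    signature of repression by the miRNA.  Constant series have no defined
    correlation: NaN is returned (never 0, which would claim evidence of
    independence).
    """
    x = np.asarray(mirna_series, dtype=float)
    y = np.asarray(target_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError(f"need >= 3 stages for a correlation, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r)


def correlation_table(
    mirna_expr: pd.DataFrame,
    target_expr: pd.DataFrame,
    coupling: Mapping[str, str],
    method: Literal["pearson", "spearman"] = "pearson",
) -> pd.DataFrame:
    """Correlate each miRNA row with its coupled target row.

    ``coupling`` maps miRNA id -> target id; both matrices must share
    column order (stage series).  Returns one row per pair.
    """
    if list(mirna_expr.columns) != list(target_expr.columns):
        raise ValueError("miRNA and target matrices must share column order")
    rows = []
    for mirna, target in coupling.items():
        r = mirna_target_correlation(
            mirna_expr.loc[mirna], target_expr.loc[target], method=method
        )
        rows.append({"mirna_id": mirna, "target_id": target, "correlation": r})
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "correlation"])
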