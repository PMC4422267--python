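"""Exact two-library differential expression testing for count data.

The central statistic is the Audic–Claverie-type exact test: given that a
tag was seen ``x`` times in a library of ``N1`` total clean reads, the
probability of seeing it ``y`` times in a second, independent library of
``N2`` total clean reads is

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)

which is the negative-binomial pmf obtained by integrating the Poisson rate
out under a flat prior.  Tail probabilities over ``y`` give one-sided
p-values; the two-sided p-value doubles the smaller tail.  Everything is
evaluated in log space via the log-gamma function — factorials at
``x + y`` in the thousands overflow any fixed-width float.

Convention: ``x`` is the count in the superior-spikelet library (totals
``N1``) and ``y`` the count in the inferior-spikelet library (``N2``).
Fold changes are ``log2(R)`` with ``R = inferior TPM / superior TPM`` after
the 0.01 floor, so negative fold changes mean "higher in superior".

Classification (no multiple-testing correction by default):

* |log2 FC| > 1 and 0.01 <= p <= 0.05  ->  "differential"
* |log2 FC| > 1 and p < 0.01           ->  "significant"
* otherwise                            ->  "not_de"
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from spikefill.io import CountMatrix, ExpressionMatrix, LibraryMeta, validate_design
from spikefill.normalization import DEFAULT_FLOOR

Label = Literal["not_de", "differential", "significant"]

#: |log2 fold change| gate for calling differential expression.
FC_GATE = 1.0
#: p-value band [P_SIG, P_DE] -> "differential"; below P_SIG -> "significant".
P_DE = 0.05
P_SIG = 0.01


@dataclass(frozen=True)
class DERecord:
    """One miRNA at one grain-filling stage, superior vs inferior."""

    entity_id: str
    stage_daf: int
    tpm_superior: float
    tpm_inferior: float
    ratio_R: float
    log2_fc: float
    p_lower: float
    p_upper: float
    p_two_sided: float
    label: Label


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test of one miRNA's superior vs inferior series over stages."""

    entity_id: str
    n_pairs: int
    t_statistic: float
    p_value: float
    direction: Literal["superior_higher", "inferior_higher", "none"]
    degenerate: bool = False


def _check_test_args(x: int, y: int, n1: float, n2: float) -> None:
    if x < 0 or y < 0:
        raise ValueError(f"counts must be non-negative, got x={x}, y={y}")
    if int(x) != x or int(y) != y:
        raise ValueError(f"counts must be integers, got x={x}, y={y}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError(f"library totals must be positive, got N1={n1}, N2={n2}")


def _log_pmf(ys: np.ndarray, x: int, n1: float, n2: float) -> np.ndarray:
    """log p(y | x) for an array of y, via log-gamma."""
    log_r = math.log(n2) - math.log(n1)
    # log(1 + N2/N1) = log(N1 + N2) - log(N1): safe for any magnitude ratio
    log_1pr = math.log(n1 + n2) - math.log(n1)
    return (
        ys * log_r
        + gammaln(x + ys + 1)
        - gammaln(x + 1)
        - gammaln(ys + 1)
        - (x + ys + 1) * log_1pr
    )


def ac_probability(x: int, y: int, n1: float, n2: float) -> float:
    """Probability of count ``y`` in library 2 given ``x`` in library 1.

    Equals the negative-binomial pmf with ``x + 1`` successes and success
    probability ``N1 / (N1 + N2)``, evaluated at ``y``; for fixed ``x`` it
    sums to 1 over ``y = 0..inf``.
    """
    _check_test_args(x, y, n1, n2)
    return float(np.exp(_log_pmf(np.array([y], dtype=float), x, n1, n2)[0]))


def ac_pvalue(x: int, y: int, n1: float, n2: float) -> tuple[float, float, float]:
    """Lower, upper and two-sided tail probabilities of ``y`` given ``x``.

    * ``p_lower = sum_{k=0..y} p(k|x)``
    * ``p_upper = sum_{k=y..inf} p(k|x)`` (computed as the complement of
      the finite sum up to ``y - 1``; both tails include the observed
      point, so ``p_lower + p_upper = 1 + p(y|x)``)
    * ``p_two_sided = min(1, 2 * min(p_lower, p_upper))``
    """
    _check_test_args(x, y, n1, n2)
    ks = np.arange(0, y + 1, dtype=float)
    logs = _log_pmf(ks, x, n1, n2)
    p_lower = float(np.exp(logsumexp(logs)))
    if y == 0:
        p_upper = 1.0
    else:
        p_upper = float(1.0 - np.exp(logsumexp(logs[:-1])))
    p_lower = min(p_lower, 1.0)
    p_upper = min(max(p_upper, 0.0), 1.0)
    p_two = min(1.0, 2.0 * min(p_lower, p_upper))
    return p_lower, p_upper, p_two


def log2_fold_change(
    tpm_inferior: float, tpm_superior: float, floor: float = DEFAULT_FLOOR
) -> tuple[float, float]:
    """Ratio ``R = inferior / superior`` (zeros floored) and its log2.

    Negative log2 fold change therefore reads "higher in superior".
    """
    if tpm_inferior < 0 or tpm_superior < 0:
        raise ValueError("TPM values must be non-negative")
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    inf_ = tpm_inferior if tpm_inferior > 0 else floor
    sup_ = tpm_superior if tpm_superior > 0 else floor
    ratio = inf_ / sup_
    return ratio, math.log2(ratio)


def classify_de(log2_fc: float, p_two_sided: float) -> Label:
    """Apply the fold-change gate and the two-level p-value rule."""
    if not 0 <= p_two_sided <= 1:
        raise ValueError(f"p-value outside [0, 1]: {p_two_sided}")
    if abs(log2_fc) <= FC_GATE:
        return "not_de"
    if p_two_sided < P_SIG:
        return "significant"
    if P_SIG <= p_two_sided <= P_DE:
        return "differential"
    return "not_de"


def stage_comparison(
    expr: ExpressionMatrix,
    meta: Sequence[LibraryMeta],
    counts: CountMatrix,
    floor: float = DEFAULT_FLOOR,
    stages: Sequence[int] | None = None,
) -> list[DERecord]:
    """Superior-vs-inferior comparison of every entity at every stage.

    The exact test consumes raw counts with each library's total clean
    reads; the fold change consumes floored TPM — each formula stays on the
    scale its definition implies.  ``expr`` rows define which entities are
    compared (typically the abundance-filtered matrix); ``counts`` must
    contain those rows.
    """
    if stages is None:
        stages = sorted({m.stage_daf for m in meta})
    design = validate_design(meta, stages)
    records: list[DERecord] = []
    for stage in stages:
        sup = design[stage]["superior"]
        inf = design[stage]["inferior"]
        for entity in expr.index:
            x = int(counts.at[entity, sup.library_id])
            y = int(counts.at[entity, inf.library_id])
            p_lo, p_up, p_two = ac_pvalue(x, y, sup.total_clean_reads, inf.total_clean_reads)
            tpm_s = float(expr.at[entity, sup.library_id])
            tpm_i = float(expr.at[entity, inf.library_id])
            ratio, fc = log2_fold_change(tpm_i, tpm_s, floor=floor)
            records.append(
                DERecord(
                    entity_id=str(entity),
                    stage_daf=stage,
                    tpm_superior=tpm_s,
                    tpm_inferior=tpm_i,
                    ratio_R=ratio,
                    log2_fc=fc,
                    p_lower=p_lo,
                    p_upper=p_up,
                    p_two_sided=p_two,
                    label=classify_de(fc, p_two),
                )
            )
    return records


def paired_ttest(
    superior_series: Sequence[float],
    inferior_series: Sequence[float],
    entity_id: str = "",
    alpha: float = 0.05,
) -> PairedTestResult:
    """Two-tailed paired t-test across stages (df = n - 1).

    Applied to the per-stage (superior - inferior) differences; with the
    paper-style five-stage design n = 5, df = 4.  Degenerate cases: all
    differences zero gives t = 0, p = 1; zero variance with nonzero mean
    gives p = 0 with the ``degenerate`` flag set.  ``direction`` is
    assigned only when p < ``alpha``.
    """
    sup = np.asarray(superior_series, dtype=float)
    inf = np.asarray(inferior_series, dtype=float)
    if sup.shape != inf.shape or sup.ndim != 1:
        raise ValueError("series must be equal-length 1-D sequences")
    n = sup.size
    if n < 2:
        raise ValueError(f"need at least 2 paired stages, got {n}")
    diff = sup - inf
    mean = diff.mean()
    sd = diff.std(ddof=1)
    degenerate = False
    if sd == 0:
        if mean == 0:
            t, p = 0.0, 1.0
        else:
            t = math.inf if mean > 0 else -math.inf
            p = 0.0
            degenerate = True
    else:
        t = mean / (sd / math.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    if p < alpha:
        direction = "superior_higher" if mean > 0 else "inferior_higher"
    else:
        direction = "none"
    return PairedTestResult(
        entity_id=entity_id,
        n_pairs=n,
        t_statistic=float(t),
        p_value=float(p),
        direction=direction,
        degenerate=degenerate,
    )


def paired_tests_by_entity(
    expr: ExpressionMatrix,
    meta: Sequence[LibraryMeta],
    stages: Sequence[int] | None = None,
    log_scale: bool = True,
) -> list[PairedTestResult]:
    """Run :func:`paired_ttest` for every entity over the stage series.

    By default the test runs on log2 TPM (the scale expression heat maps
    are drawn on); pass ``log_scale=False`` for raw TPM.  ``expr`` must be
    floored when ``log_scale`` is used.
    """
    if stages is None:
        stages = sorted({m.stage_daf for m in meta})
    design = validate_design(meta, stages)
    sup_cols = [design[s]["superior"].library_id for s in stages]
    inf_cols = [design[s]["inferior"].library_id for s in stages]
    mat = expr
    if log_scale:
        if (mat <= 0).any().any():
            raise ValueError("log-scale paired test requires a floored (positive) matrix")
        mat = np.log2(mat)
    return [
        paired_ttest(mat.loc[e, sup_cols], mat.loc[e, inf_cols], entity_id=str(e))
        for e in mat.index
    ]


def records_frame(records: Sequence[DERecord]) -> pd.DataFrame:
    """Tabulate DE records with stable column order."""
    cols = [
        "entity_id", "stage_daf", "tpm_superior", "tpm_inferior", "ratio_R",
        "log2_fc", "p_lower", "p_upper", "p_two_sided", "label",
    ]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
    return df


def summarize_de(
    records: Sequence[DERecord],
    per_entity_tests: Sequence[PairedTestResult] = (),
) -> dict:
    """Summary counts and percentages of the differential-expression calls.

    Per stage: how many entities are differentially expressed (the
    "differential" and "significant" classes counted together and also
    separately), how many of those have log2 FC < 0 (higher in superior,
    since R = inferior/superior) or > 0, with percentages to two decimals.
    Globally: how many entities each paired test direction claims, as a
    percentage of all tested entities.
    """
    per_stage: dict[int, dict] = {}
    for stage in sorted({r.stage_daf for r in records}):
        recs = [r for r in records if r.stage_daf == stage]
        de = [r for r in recs if r.label != "not_de"]
        higher_sup = [r for r in de if r.log2_fc < 0]
        higher_inf = [r for r in de if r.log2_fc > 0]
        n_de = len(de)
        per_stage[stage] = {
            "n_tested": len(recs),
            "n_de": n_de,
            "n_differential": sum(r.label == "differential" for r in de),
            "n_significant": sum(r.label == "significant" for r in de),
            "n_higher_superior": len(higher_sup),
            "n_higher_inferior": len(higher_inf),
            "pct_higher_superior": _pct(len(higher_sup), n_de),
            "pct_higher_inferior": _pct(len(higher_inf), n_de),
        }
    n_entities = len(per_entity_tests)
    n_sup = sum(t.direction == "superior_higher" for t in per_entity_tests)
    n_inf = sum(t.direction == "inferior_higher" for t in per_entity_tests)
    summary = {
        "per_stage": per_stage,
        "n_de_any_stage": len({r.entity_id for r in records if r.label != "not_de"}),
        "paired": {
            "n_entities": n_entities,
            "n_consistently_superior": n_sup,
            "n_consistently_inferior": n_inf,
            "pct_consistently_superior": _pct(n_sup, n_entities),
            "pct_consistently_inferior": _pct(n_inf, n_entities),
        },
    }
    return summary


def _pct(numerator: int, denominator: int) -> float:
    if denominator == 0:
        return 0.0
    return round(100.0 * numerator / denominator, 2)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; the default workflow applies none)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
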