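"""Reproducible validation studies of the pipeline's statistical machinery.

Each function runs a self-contained study — an oracle comparison, a null
simulation, a parameter-recovery experiment, or a recomputation of worked
numbers from printed inputs — and returns plain dictionaries of measured
quantities.  The test suite asserts tolerances on these numbers and the
acceptance script reports them; the studies themselves never know about
either.

Problem sizes (grids to count 100, 2 000 null entities, 200 recovery
replicates, 100 kinetics seeds) are the package's validation design,
chosen so the full battery runs in a couple of minutes on one core.
"""

from __future__ import annotations

import numpy as np

from spikefill.diffexpr import (
    DERecord,
    PairedTestResult,
    ac_probability,
    ac_pvalue,
    stage_comparison,
    summarize_de,
)
from spikefill.kinetics import fit_logistic, kinetics_summary
from spikefill.normalization import (
    abundance_filter,
    apply_floor,
    length_distribution,
    tpm_normalize,
)
from spikefill.novel import NovelCandidate, evaluate_all, load_novel_fixture
from spikefill.profiles import correlation_table
from spikefill.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_length_histograms,
    simulate_targets,
    simulate_weights,
)

DEFAULT_TOTALS = (10**4, 10**6, 2 * 10**6)


def _spawn_seed(seed: int, index: int) -> int:
    """Derive a child seed (< 2^31) from a master seed, reproducibly."""
    child = np.random.SeedSequence(seed).spawn(index + 1)[index]
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# Exact-test oracle agreement


def oracle_max_rel_error(
    max_count: int = 100, totals: tuple[int, ...] = DEFAULT_TOTALS
) -> dict:
    """Compare the log-gamma statistic against 60-digit arbitrary precision.

    The oracle evaluates p(y|x) by a forward recurrence in ``mpmath``
    arithmetic (p(0|x) = (1+r)^-(x+1); p(y+1|x)/p(y|x) =
    r (x+y+1) / ((y+1)(1+r))), an independent route from the log-gamma
    implementation.  Scans every (x, y) up to ``max_count`` for every
    ordered pair of library totals and returns the worst relative error.
    """
    import mpmath

    worst = 0.0
    n_checked = 0
    with mpmath.workdps(60):
        for n1 in totals:
            for n2 in totals:
                r = mpmath.mpf(n2) / mpmath.mpf(n1)
                one_pr = 1 + r
                for x in range(max_count + 1):
                    p = one_pr ** -(x + 1)
                    for y in range(max_count + 1):
                        got = ac_probability(x, y, n1, n2)
                        rel = abs(got - float(p)) / float(p)
                        if rel > worst:
                            worst = rel
                        n_checked += 1
                        p = p * r * (x + y + 1) / ((y + 1) * one_pr)
    return {"max_rel_error": worst, "n_checked": n_checked}


def tail_normalization_study() -> dict:
    """Tail-sum normalization and pointwise symmetry of the statistic.

    Sums p(y|x) over y until 40 standard deviations past the mean of the
    induced negative-binomial distribution (a truncation whose remainder is
    far below 1e-9) and records the worst deviation from 1; also evaluates
    the equal-totals anchor points p(0|0) and p(1|1) and the worst
    pointwise swap asymmetry.
    """
    cases = [
        (0, 10**6, 10**6),
        (7, 10**4, 2 * 10**6),
        (25, 10**6, 10**6),
        (50, 2 * 10**6, 10**4),
    ]
    worst = 0.0
    for x, n1, n2 in cases:
        r = n2 / n1
        mu = (x + 1) * r
        sd = np.sqrt((x + 1) * r * (1 + r))
        p_lower, _, _ = ac_pvalue(x, int(mu + 40 * sd) + 1, n1, n2)
        worst = max(worst, abs(p_lower - 1.0))
    sym = max(
        abs(ac_probability(x, y, 10**6, 10**6) - ac_probability(y, x, 10**6, 10**6))
        for x, y in [(4, 9), (30, 12), (0, 80)]
    )
    return {
        "max_tail_sum_deviation": worst,
        "p_0_given_0_equal_totals": ac_probability(0, 0, 10**6, 10**6),
        "p_1_given_1_equal_totals": ac_probability(1, 1, 10**6, 10**6),
        "max_pointwise_swap_asymmetry": sym,
    }


# ---------------------------------------------------------------------------
# Null and spiked simulations


def type1_error_study(seed: int, n_entities: int = 2000) -> dict:
    """Fraction of null entity-stage tests called at p < 0.05.

    Null data: no spiked effects, Poisson-limit dispersion (the sampling
    model the exact test assumes), baselines log-normal around 100 TPM,
    library size 1e6 so count discreteness is mild at the 0.05 gate.
    The discrete doubled-tail p-value is conservative, so the measured
    rate sits slightly below nominal.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_mirnas=n_entities,
        de_fraction=0.0,
        dispersion=0.0,
        baseline_log_tpm_mean=float(np.log(100.0)),
        baseline_log_tpm_sd=1.0,
        library_size_range=(1_000_000, 1_000_000),
    )
    counts, meta, _ = simulate_counts(cfg)
    expr = apply_floor(tpm_normalize(counts, meta))
    kept, _ = abundance_filter(expr)
    records = stage_comparison(kept, meta, counts)
    ps = np.array([r.p_two_sided for r in records])
    return {
        "fraction_p_below_0.05": float((ps < 0.05).mean()),
        "fraction_labelled_de": float(np.mean([r.label != "not_de" for r in records])),
        "n_tests": int(ps.size),
    }


def de_recovery_study(
    seed: int, n_replicates: int = 200, true_fc: float = 2.0
) -> dict:
    """Recovery of entities spiked at |log2 FC| = 2 with baseline >= 100 TPM.

    Each replicate simulates a small experiment where every entity carries
    the spiked effect; only entities whose true baseline is at least
    100 TPM enter the measurement.  Reports the fraction of entity-stage
    comparisons labelled differential-or-significant and the error of the
    estimated fold change.
    """
    hits = 0
    total = 0
    errors = []
    for i in range(n_replicates):
        cfg = SimulationConfig(
            seed=_spawn_seed(seed, i),
            n_mirnas=10,
            de_fraction=1.0,
            de_log2fc_range=(true_fc, true_fc),
            dispersion=0.0,
            baseline_log_tpm_mean=6.0,
            baseline_log_tpm_sd=0.4,
        )
        counts, meta, truth = simulate_counts(cfg)
        expr = apply_floor(tpm_normalize(counts, meta))
        kept, _ = abundance_filter(expr)
        records = stage_comparison(kept, meta, counts)
        for r in records:
            fc = truth.de_log2fc.get(r.entity_id, 0.0)
            if fc == 0.0 or truth.baseline_tpm[r.entity_id] < 100.0:
                continue
            total += 1
            hits += r.label != "not_de"
            errors.append(r.log2_fc - fc)
    errors = np.array(errors)
    return {
        "recovery_rate": hits / total,
        "mean_fc_error": float(errors.mean()),
        "mean_abs_fc_error": float(np.abs(errors).mean()),
        "n_comparisons": total,
    }


# ---------------------------------------------------------------------------
# Kinetics


def kinetics_recovery_study(seed: int, n_seeds: int = 100) -> dict:
    """Median parameter-recovery error of the logistic fit per condition.

    Noise is Gaussian with sd = 2% of the condition's asymptote K, the
    nine-point 5–45 DAF sampling grid of the field design.
    """
    out = {}
    base = SimulationConfig(seed=0)
    for cond, (K, a, b) in (
        ("superior", base.kinetics_superior),
        ("inferior", base.kinetics_inferior),
    ):
        Ks, bs = [], []
        for i in range(n_seeds):
            cfg = SimulationConfig(
                seed=_spawn_seed(seed, i), weight_noise_sd=0.02 * K
            )
            sup, inf = simulate_weights(cfg)
            fit = fit_logistic(sup if cond == "superior" else inf)
            Ks.append(fit.K)
            bs.append(fit.b)
        out[f"K_median_rel_error_{cond}"] = abs(float(np.median(Ks)) - K) / K
        out[f"b_median_rel_error_{cond}"] = abs(float(np.median(bs)) - b) / b
    out["n_seeds"] = n_seeds
    return out


def fitted_kinetics_study(seed: int) -> dict:
    """Fit both conditions' default noisy weight series; derived kinetics."""
    cfg = SimulationConfig(seed=seed)
    sup, inf = simulate_weights(cfg)
    summaries = {s.condition: kinetics_summary(fit_logistic(s)) for s in (sup, inf)}
    return {
        "v_max_superior": summaries["superior"]["v_max_mg_per_day"],
        "v_max_inferior": summaries["inferior"]["v_max_mg_per_day"],
        "t_peak_superior": summaries["superior"]["t_peak_daf"],
        "t_peak_inferior": summaries["inferior"]["t_peak_daf"],
        "t95_superior": summaries["superior"]["t_completion_daf"],
        "t95_inferior": summaries["inferior"]["t_completion_daf"],
    }


# ---------------------------------------------------------------------------
# Worked numbers from printed inputs


def headline_percentage_study() -> dict:
    """Direction percentages recomputed from the published headline counts.

    Inputs are printed counts: at the 15 DAF stage 109 miRNAs were
    differentially expressed, 103 of them higher in superior spikelets;
    of 160 analyzed miRNAs, 19 were consistently higher in superior and 11
    consistently higher in inferior spikelets by the five-stage paired
    test.  The percentages are produced by ``summarize_de`` run on records
    built from those counts.
    """

    def rec(entity: str, fc: float) -> DERecord:
        return DERecord(entity, 15, 10.0, 10.0 * 2**fc, 2.0**fc, fc,
                        0.001, 0.999, 0.002, "significant")

    records = [rec(f"sup{i}", -2.0) for i in range(103)]
    records += [rec(f"inf{i}", +2.0) for i in range(109 - 103)]
    paired = (
        [PairedTestResult(f"s{i}", 5, 3.0, 0.01, "superior_higher") for i in range(19)]
        + [PairedTestResult(f"i{i}", 5, -3.0, 0.01, "inferior_higher") for i in range(11)]
        + [PairedTestResult(f"n{i}", 5, 0.5, 0.60, "none") for i in range(160 - 19 - 11)]
    )
    summary = summarize_de(records, paired)
    return {
        "pct_de_higher_in_superior": summary["per_stage"][15]["pct_higher_superior"],
        "pct_consistently_superior": summary["paired"]["pct_consistently_superior"],
        "pct_consistently_inferior": summary["paired"]["pct_consistently_inferior"],
        "n_de": summary["per_stage"][15]["n_de"],
        "n_paired": summary["paired"]["n_entities"],
    }


def novel_fixture_study() -> dict:
    """Decisions on the packaged 13-candidate table, full and H-only."""
    candidates = load_novel_fixture()
    full = evaluate_all(candidates, n_libraries=10)
    stripped = [
        NovelCandidate(c.candidate_id, c.mature_sequence, dict(c.tpm_by_library))
        for c in candidates
    ]
    h_only = evaluate_all(stripped, n_libraries=10, detection_floor=float("inf"))
    return {
        "n_candidates": len(candidates),
        "n_accepted": sum(d.accepted for d in full),
        "n_accepted_high_tpm_only": sum(d.accepted for d in h_only),
        "high_tpm_ids": sorted(d.candidate_id for d in h_only if d.accepted),
    }


def length_mix_study(seed: int, reads_per_library: int = 100_000) -> dict:
    """Pooled 24-nt and 21-nt read fractions of the simulated libraries."""
    cfg = SimulationConfig(seed=seed)
    hists = simulate_length_histograms(cfg, reads_per_library=reads_per_library)
    _, pooled = length_distribution(hists)
    return {
        "pct_24nt": 100.0 * pooled.proportions[24],
        "pct_21nt": 100.0 * pooled.proportions[21],
        "n_reads": reads_per_library * len(hists),
    }


def target_correlation_study(seed: int, n_mirnas: int = 100) -> dict:
    """Mean log-scale Pearson correlation of anti-coupled miRNA–target pairs."""
    cfg = SimulationConfig(seed=seed, n_mirnas=n_mirnas, de_fraction=0.0)
    counts, meta, truth = simulate_counts(cfg)
    expr = apply_floor(tpm_normalize(counts, meta))
    targets, coupling = simulate_targets(cfg, expr, truth=truth)
    table = correlation_table(np.log2(expr), np.log2(targets), coupling)
    return {
        "mean_pearson": float(table["correlation"].mean()),
        "n_pairs": int(table.shape[0]),
    }
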