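"""End-to-end orchestration: simulate → normalize → test → summarize →
kinetics → profiles, with one JSON report and a reproducible run log.

Every stage output is a pure function of (inputs, config, seed); the same
config and seed give a byte-identical JSON summary.  Parameter validation
happens before any stage runs (e.g. a minimum-TPM threshold at or below
the zero floor aborts immediately), and the report's differential-
expression percentages are recomputed from the report's own DE table as an
internal consistency check.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import spikefill
from spikefill import io as sio
from spikefill import diffexpr, kinetics, normalization, novel, profiles, simulate

logger = logging.getLogger("spikefill")


@dataclass
class RunConfig:
    """Effective parameters of one pipeline run (all are logged)."""

    seed: int
    out_dir: str = "spikefill_run"
    # Inputs; when counts/meta are None the synthetic generator provides them.
    counts_path: str | None = None
    meta_path: str | None = None
    floor: float = normalization.DEFAULT_FLOOR
    min_tpm: float = normalization.DEFAULT_MIN_TPM
    tpm_high: float = novel.DEFAULT_TPM_HIGH
    detection_floor: float = novel.DEFAULT_DETECTION_FLOOR
    cluster_k: int = 2
    sim: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.min_tpm <= self.floor:
            raise ValueError(
                f"min_tpm ({self.min_tpm}) must exceed the zero floor "
                f"({self.floor}); aborting before any stage runs"
            )
        if self.floor < 0:
            raise ValueError("floor must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for h in list(logger.handlers):
        if isinstance(h, logging.FileHandler):
            h.close()
            logger.removeHandler(h)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order and write the report bundle.

    Writes per-stage TSVs, ``summary.json`` and ``run.log`` under
    ``config.out_dir`` and returns the summary dict.  Any stage failure
    propagates with the stage named; partial outputs are left in place.
    """
    config.validate()
    out = Path(config.out_dir)
    _setup_logging(out)
    logger.info("spikefill %s starting; seed=%d", spikefill.__version__, config.seed)
    logger.info("effective config: %s", json.dumps(dataclasses.asdict(config), sort_keys=True))

    stage = "simulate"
    try:
        cfg = simulate.SimulationConfig(seed=config.seed, **config.sim)
        if config.counts_path and config.meta_path:
            counts = sio.read_count_matrix(config.counts_path)
            meta = sio.read_metadata(config.meta_path)
        else:
            counts, meta, truth = simulate.simulate_counts(cfg)
            sio.write_results(counts, out / "counts.tsv")
            pd.DataFrame([dataclasses.asdict(m) for m in meta]).to_csv(
                out / "meta.tsv", sep="\t", index=False
            )
        sio.check_totals(counts, meta)

        stage = "normalize"
        expr = normalization.tpm_normalize(counts, meta)
        floored = normalization.apply_floor(expr, floor=config.floor)
        kept, dropped = normalization.abundance_filter(
            floored, threshold=config.min_tpm, floor=config.floor
        )
        sio.write_results(floored, out / "expression_tpm.tsv")
        logger.info("normalize: %d entities kept, %d dropped (<= %g TPM everywhere)",
                    kept.shape[0], len(dropped), config.min_tpm)

        stage = "detest"
        records = diffexpr.stage_comparison(kept, meta, counts, floor=config.floor)
        de_table = diffexpr.records_frame(records)
        sio.write_results(de_table, out / "differential_expression.tsv")
        paired = diffexpr.paired_tests_by_entity(kept, meta)
        summary_de = diffexpr.summarize_de(records, paired)
        _consistency_check(records, summary_de)

        stage = "novel"
        candidates, star_truth = simulate.simulate_novel_candidates(cfg)
        decisions = novel.evaluate_all(
            candidates, meta=meta,
            tpm_high=config.tpm_high, detection_floor=config.detection_floor,
        )
        novel.decisions_frame(decisions).to_csv(out / "novel_decisions.tsv", sep="\t", index=False)

        stage = "kinetics"
        sup_series, inf_series = simulate.simulate_weights(cfg)
        fits = {}
        for series in (sup_series, inf_series):
            fit = kinetics.fit_logistic(series)
            fits[series.condition] = kinetics.kinetics_summary(fit)
        weights_df = pd.DataFrame({
            "daf": sup_series.times,
            "superior_mg": sup_series.weights,
            "inferior_mg": inf_series.weights,
        })
        sio.write_results(weights_df, out / "grain_weights.tsv")

        stage = "profiles"
        log2m = profiles.log2_profile_matrix(kept)
        if log2m.shape[0] >= max(2, config.cluster_k):
            assignments, _, _ = profiles.cluster_profiles(log2m, k=config.cluster_k)
            assignments.to_csv(out / "clusters.tsv", sep="\t")
        targets, coupling = simulate.simulate_targets(cfg, kept)
        corr = profiles.correlation_table(
            np.log2(kept), np.log2(targets), coupling, method="pearson"
        )
        sio.write_results(corr, out / "mirna_target_correlation.tsv")

        stage = "report"
        summary = {
            "seed": config.seed,
            "n_entities": int(counts.shape[0]),
            "n_libraries": int(counts.shape[1]),
            "n_kept": int(kept.shape[0]),
            "n_dropped": len(dropped),
            "differential_expression": summary_de,
            "novel": {
                "n_candidates": len(decisions),
                "n_accepted": sum(d.accepted for d in decisions),
            },
            "kinetics": fits,
            "target_correlation_mean": round(float(corr["correlation"].mean()), 6),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        logger.info("report written to %s", out / "summary.json")
        return summary
    except Exception as exc:
        logger.exception("stage %r failed; partial outputs retained in %s", stage, out)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _consistency_check(records, summary_de) -> None:
    """The report's percentages must equal summarize_de on its own table."""
    recheck = diffexpr.summarize_de(records, [])
    if recheck["per_stage"] != summary_de["per_stage"]:
        raise AssertionError("internal DE summary inconsistency")
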