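"""Synthetic small-RNA experiments with complete ground truth.

The generator emulates the two-condition, five-stage grain-filling design:
one superior and one inferior library at 10, 15, 21, 27 and 35 DAF (no
sequencing replicates, as in single-library deep-sequencing studies).
Baseline miRNA abundances are log-normal; differential entities receive a
multiplicative condition effect; counts are negative-binomial with
configurable overdispersion (``dispersion = 0`` gives the Poisson limit,
matching the sampling model the exact two-library test assumes).  Library
sizes default to 1e5–2e5 reads — the real design's ~1.1e7–1.8e7 clean
reads scaled down so simulation studies run at desk scale; sizes up to
1e7 are accepted.

Grain-weight series are sampled from the logistic law with Gaussian noise.
The default kinetics coefficients reproduce the contrast reported for
field-grown rice: superior spikelets peak near 1.5 mg/grain/day early and
finish filling in roughly three weeks past flowering, inferior spikelets
peak near 0.6 mg/grain/day later and take until ~45 DAF.

Target-gene series are log-linearly anti-coupled to their miRNA
(``log2 target = intercept + slope * log2 miRNA + noise``, slope -1 by
default), emulating repression of targets by their miRNAs.

Every stochastic choice downstream stages estimate is recorded in
:class:`GroundTruth`; the same config and seed reproduce identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from spikefill.io import CountMatrix, ExpressionMatrix, LibraryMeta
from spikefill.kinetics import GrainWeightSeries, logistic_weight

DEFAULT_STAGES = (10, 15, 21, 27, 35)

# Pooled read-length mix of deep-sequenced filling grains: 24-nt small RNAs
# dominant (58.28%), 21-nt secondary (18.30%), remainder spread evenly.
_OTHER_LENGTHS = tuple(l for l in range(18, 31) if l not in (21, 24))
DEFAULT_LENGTH_WEIGHTS: dict[int, float] = {
    24: 0.5828,
    21: 0.1830,
    **{l: (1.0 - 0.5828 - 0.1830) / len(_OTHER_LENGTHS) for l in _OTHER_LENGTHS},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic experiment.  ``seed`` is mandatory."""

    seed: int
    n_mirnas: int = 300
    stage_daf: tuple[int, ...] = DEFAULT_STAGES
    library_size_range: tuple[int, int] = (100_000, 200_000)
    de_fraction: float = 0.2
    de_log2fc_range: tuple[float, float] = (1.0, 3.0)
    dispersion: float = 0.05
    baseline_log_tpm_mean: float = 3.0  # ln TPM; median ~ e^3 ~ 20 TPM
    baseline_log_tpm_sd: float = 1.5
    length_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    star_fraction: float = 0.3
    kinetics_superior: tuple[float, float, float] = (21.0, 41.0, 0.286)
    kinetics_inferior: tuple[float, float, float] = (16.0, 27.0, 0.15)
    weight_noise_sd: float = 0.4
    weight_times: tuple[float, ...] = tuple(range(5, 50, 5))
    target_coupling_slope: float = -1.0
    target_noise_sd: float = 0.1

    def validate(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas: must be >= 1")
        if not self.stage_daf or any(s <= 0 for s in self.stage_daf):
            raise ValueError("stage_daf: stages must be positive DAF values")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range: need 0 < low <= high")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction: must lie in [0, 1]")
        if self.de_log2fc_range[0] > self.de_log2fc_range[1]:
            raise ValueError("de_log2fc_range: must be ordered (low, high)")
        if self.dispersion < 0:
            raise ValueError("dispersion: must be >= 0 (0 = Poisson limit)")
        if not 0 <= self.star_fraction <= 1:
            raise ValueError("star_fraction: must lie in [0, 1]")
        if self.weight_noise_sd < 0:
            raise ValueError("weight_noise_sd: must be >= 0")
        for name, (K, a, b) in (
            ("kinetics_superior", self.kinetics_superior),
            ("kinetics_inferior", self.kinetics_inferior),
        ):
            if K <= 0 or a <= 0 or b <= 0:
                raise ValueError(f"{name}: K, a, b must all be positive")
        w = sum(self.length_weights.values())
        if abs(w - 1.0) > 1e-6:
            raise ValueError(f"length_weights: weights sum to {w}, expected 1")


@dataclass
class GroundTruth:
    """Everything the generator decided that downstream stages estimate."""

    #: entity -> true log2(inferior/superior) fold change (same at every stage)
    de_log2fc: dict[str, float]
    #: entity -> baseline TPM before condition effects
    baseline_tpm: dict[str, float]
    kinetics_superior: tuple[float, float, float]
    kinetics_inferior: tuple[float, float, float]
    #: miRNA id -> coupled target id (filled by simulate_targets)
    coupling: dict[str, str] = field(default_factory=dict)
    #: candidate id -> evidence codes it truly satisfies
    novel_flags: dict[str, frozenset[str]] = field(default_factory=dict)

    def de_label(self, entity: str, stage: int) -> float:
        """True log2 fold change of ``entity`` at ``stage`` (0 if null)."""
        return self.de_log2fc.get(entity, 0.0)


def _rng(seed: int, stream: int) -> np.random.Generator:
    # Independent child streams so each simulate_* call is reproducible on
    # its own, regardless of call order.
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(16)[stream])


def simulate_counts(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, list[LibraryMeta], GroundTruth]:
    """Generate a raw count matrix, its metadata, and the ground truth."""
    cfg.validate()
    rng = _rng(cfg.seed, 0)
    entities = [f"mir{i:04d}" for i in range(1, cfg.n_mirnas + 1)]
    stages = list(cfg.stage_daf)
    lib_ids = [f"S{s}" for s in stages] + [f"I{s}" for s in stages]
    conditions = ["superior"] * len(stages) + ["inferior"] * len(stages)
    lib_stages = stages + stages
    lo, hi = cfg.library_size_range
    sizes = rng.integers(lo, hi + 1, size=len(lib_ids))

    baseline = np.exp(
        rng.normal(cfg.baseline_log_tpm_mean, cfg.baseline_log_tpm_sd, size=cfg.n_mirnas)
    )
    n_de = int(round(cfg.de_fraction * cfg.n_mirnas))
    de_idx = rng.choice(cfg.n_mirnas, size=n_de, replace=False)
    fc_lo, fc_hi = cfg.de_log2fc_range
    magnitudes = rng.uniform(fc_lo, fc_hi, size=n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    fcs = np.zeros(cfg.n_mirnas)
    fcs[de_idx] = magnitudes * signs

    counts = np.zeros((cfg.n_mirnas, len(lib_ids)), dtype=np.int64)
    for j, (lib, cond, size) in enumerate(zip(lib_ids, conditions, sizes)):
        tpm = baseline * np.exp2(fcs) if cond == "inferior" else baseline
        mu = tpm * size / 1e6
        if cfg.dispersion > 0:
            shape = 1.0 / cfg.dispersion
            lam = rng.gamma(shape, mu / shape)
            counts[:, j] = rng.poisson(lam)
        else:
            counts[:, j] = rng.poisson(mu)

    matrix = pd.DataFrame(counts, index=pd.Index(entities, name="entity_id"), columns=lib_ids)
    meta = [
        LibraryMeta(
            library_id=lib,
            condition=cond,
            stage_daf=stage,
            total_clean_reads=int(size),
        )
        for lib, cond, stage, size in zip(lib_ids, conditions, lib_stages, sizes)
    ]
    truth = GroundTruth(
        de_log2fc={entities[i]: float(fcs[i]) for i in de_idx},
        baseline_tpm=dict(zip(entities, baseline.tolist())),
        kinetics_superior=cfg.kinetics_superior,
        kinetics_inferior=cfg.kinetics_inferior,
    )
    return matrix, meta, truth


def simulate_length_histograms(
    cfg: SimulationConfig, reads_per_library: int = 100_000
) -> dict[str, dict[int, int]]:
    """Multinomial read-length histograms from the configured length mix."""
    cfg.validate()
    rng = _rng(cfg.seed, 1)
    lengths = sorted(cfg.length_weights)
    probs = np.array([cfg.length_weights[l] for l in lengths])
    out = {}
    for s in cfg.stage_daf:
        for prefix in ("S", "I"):
            draw = rng.multinomial(reads_per_library, probs)
            out[f"{prefix}{s}"] = {l: int(c) for l, c in zip(lengths, draw)}
    return out


def simulate_weights(
    cfg: SimulationConfig,
) -> tuple[GrainWeightSeries, GrainWeightSeries]:
    """Noisy logistic grain-weight trajectories for both conditions.

    Negative noisy weights are clamped to 0 (with a warning); with the
    default noise level this is practically never triggered.
    """
    cfg.validate()
    rng = _rng(cfg.seed, 2)
    times = np.asarray(cfg.weight_times, dtype=float)
    out = []
    n_clamped = 0
    for cond, (K, a, b) in (
        ("superior", cfg.kinetics_superior),
        ("inferior", cfg.kinetics_inferior),
    ):
        y = logistic_weight(times, K, a, b)
        if cfg.weight_noise_sd > 0:
            y = y + rng.normal(0.0, cfg.weight_noise_sd, size=times.size)
        clamped = y < 0
        n_clamped += int(clamped.sum())
        y = np.where(clamped, 0.0, y)
        out.append(
            GrainWeightSeries(condition=cond, times=tuple(times), weights=tuple(y))
        )
    if n_clamped:
        warnings.warn(f"clamped {n_clamped} negative noisy weight(s) to 0", stacklevel=2)
    return out[0], out[1]


def simulate_targets(
    cfg: SimulationConfig,
    mirna_expr: ExpressionMatrix,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Target-gene series log-linearly anti-coupled to each miRNA row.

    ``log2(target) = intercept + slope * log2(miRNA) + N(0, noise_sd)``
    per cell; the expression matrix must be strictly positive (floored).
    Returns the target matrix (same columns) and the miRNA -> target
    coupling map, which is also recorded on ``truth`` when given.
    """
    cfg.validate()
    if (mirna_expr <= 0).to_numpy().any():
        raise ValueError("mirna_expr must be strictly positive (apply the floor first)")
    rng = _rng(cfg.seed, 3)
    log_m = np.log2(mirna_expr.to_numpy(dtype=float))
    intercept = 10.0  # arbitrary reference scale for relative target abundance
    noise = (
        rng.normal(0.0, cfg.target_noise_sd, size=log_m.shape)
        if cfg.target_noise_sd > 0
        else 0.0
    )
    log_t = intercept + cfg.target_coupling_slope * log_m + noise
    coupling = {str(m): f"target_of_{m}" for m in mirna_expr.index}
    targets = pd.DataFrame(
        np.exp2(log_t),
        index=pd.Index([coupling[str(m)] for m in mirna_expr.index], name="gene_id"),
        columns=mirna_expr.columns,
    )
    if truth is not None:
        truth.coupling = dict(coupling)
    return targets, coupling


def simulate_novel_candidates(
    cfg: SimulationConfig,
    n_candidates: int = 20,
    truth: GroundTruth | None = None,
):
    """Novel-miRNA candidates with known evidence-criteria ground truth.

    Roughly a quarter of candidates are built to satisfy each of the
    high-abundance (H), breadth (F) and star (S) criteria, and the rest
    none; the criteria each candidate truly satisfies are recorded.
    """
    from spikefill.novel import NovelCandidate  # local import avoids a cycle

    cfg.validate()
    rng = _rng(cfg.seed, 4)
    lib_ids = [f"{p}{s}" for p in ("S", "I") for s in cfg.stage_daf]
    n_half = len(lib_ids) // 2
    bases = np.array(list("ACGT"))
    candidates = []
    flags: dict[str, frozenset[str]] = {}
    kinds = [("H", 0.25), ("F", 0.25), ("S", 0.25), ("none", 0.25)]
    kind_of = rng.choice(
        [k for k, _ in kinds], p=[p for _, p in kinds], size=n_candidates
    )
    for i, kind in enumerate(kind_of, start=1):
        cid = f"cand{i:03d}"
        seq = "".join(rng.choice(bases, size=int(rng.integers(20, 25))))
        tpm = {lib: 0.0 for lib in lib_ids}
        stars = {}
        truly = set()
        detect_libs = rng.permutation(lib_ids)
        if kind == "H":
            tpm[detect_libs[0]] = float(rng.uniform(60.0, 400.0))
            truly.add("H")
            if 2 * 1 >= len(lib_ids):  # degenerate tiny designs
                truly.add("F")
        elif kind == "F":
            for lib in detect_libs[: n_half + 1]:
                tpm[lib] = float(rng.uniform(0.3, 5.0))
            truly.add("F")
        elif kind == "S":
            tpm[detect_libs[0]] = float(rng.uniform(0.3, 5.0))
            stars[detect_libs[0]] = True
            truly.add("S")
        else:  # detected sparsely and weakly: fails everything
            for lib in detect_libs[: max(1, n_half - 2)]:
                tpm[lib] = float(rng.uniform(0.3, 5.0))
        candidates.append(
            NovelCandidate(
                candidate_id=cid,
                mature_sequence=seq,
                tpm_by_library=tpm,
                star_detected_by_library=stars,
            )
        )
        flags[cid] = frozenset(truly)
    if truth is not None:
        truth.novel_flags = dict(flags)
    return candidates, flags


def config_to_dict(cfg: SimulationConfig) -> dict:
    """JSON-serializable view of a config (for run logs)."""
    d = asdict(cfg)
    d["length_weights"] = {str(k): v for k, v in dict(cfg.length_weights).items()}
    return d
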