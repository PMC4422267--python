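"""TPM normalization, the zero floor, the abundance filter, and read summaries.

Normalization scales each library's raw counts to transcripts per million
(TPM) using that library's total clean reads as the denominator — the same
denominator the exact count test uses, which keeps the two on a consistent
footing.  After normalization, entities that were not observed at all (TPM
exactly 0) are set to a small floor (default 0.01 TPM) so that fold changes
remain finite; entities never exceeding a minimum abundance (default
10 TPM, strict) in any library are excluded from differential analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from spikefill.io import CountMatrix, ExpressionMatrix, LibraryMeta

#: TPM assigned to entities with zero observed reads.
DEFAULT_FLOOR = 0.01
#: Minimum TPM (strict, in at least one library) for differential analysis.
DEFAULT_MIN_TPM = 10.0

LENGTH_RANGE = range(18, 31)

#: Annotation classes in matching priority order; reads matching nothing
#: are "unannotated".  The priority is a package choice (structural RNA
#: classes before miRNA) and can be overridden per call.
CLASS_PRIORITY = ("rRNA", "tRNA", "snoRNA", "snRNA", "miRNA")


@dataclass(frozen=True)
class LengthProfile:
    """Per-library fraction of reads at each length (18–30 nt)."""

    library_id: str
    proportions: dict[int, float]


@dataclass(frozen=True)
class ClassComposition:
    """Reads per annotation class for one library; conserves totals."""

    library_id: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def tpm_normalize(
    counts: CountMatrix, meta: Sequence[LibraryMeta]
) -> ExpressionMatrix:
    """Scale raw counts to TPM: ``count * 1e6 / total_clean_reads``.

    No floor is applied here; zeros stay zero.  Raises ``KeyError`` when a
    count column has no metadata record.
    """
    totals = {m.library_id: m.total_clean_reads for m in meta}
    missing = [c for c in counts.columns if c not in totals]
    if missing:
        raise KeyError(f"no LibraryMeta for count column(s) {missing}")
    denom = np.array([totals[c] for c in counts.columns], dtype=float)
    return counts.astype(float) * (1e6 / denom)


def apply_floor(
    expr: ExpressionMatrix, floor: float = DEFAULT_FLOOR
) -> ExpressionMatrix:
    """Replace exact-zero TPM entries with ``floor``; idempotent.

    Only cells that are exactly 0 ("not expressed") are raised; small
    nonzero values are real observations and pass through unchanged.
    """
    if floor < 0:
        raise ValueError(f"floor must be non-negative, got {floor}")
    return expr.mask(expr == 0, floor)


def abundance_filter(
    expr: ExpressionMatrix, threshold: float = DEFAULT_MIN_TPM, floor: float = DEFAULT_FLOOR
) -> tuple[ExpressionMatrix, list[str]]:
    """Partition entities by the minimum-abundance rule.

    An entity is kept iff its TPM is strictly greater than ``threshold`` in
    at least one library; everything else is dropped from differential
    analysis.  Returns ``(kept_matrix, dropped_entity_ids)``; the partition
    is exhaustive and disjoint.  The floor must lie below the threshold so
    flooring can never change the partition.
    """
    if threshold <= floor:
        raise ValueError(
            f"abundance threshold ({threshold}) must exceed the zero floor "
            f"({floor}); otherwise floored entries could pass the filter"
        )
    keep = (expr > threshold).any(axis=1)
    kept = expr.loc[keep]
    dropped = expr.index[~keep].tolist()
    return kept, dropped


def length_distribution(
    histograms: Mapping[str, Mapping[int, int]],
    lengths: Iterable[int] = LENGTH_RANGE,
) -> tuple[list[LengthProfile], LengthProfile]:
    """Per-library and pooled read-length fractions over 18–30 nt.

    ``histograms`` maps library_id to ``{length: read count}``.  Lengths
    outside the declared range, empty histograms and negative counts are
    errors.  Returns ``(per_library_profiles, pooled_profile)`` where the
    pooled profile (library_id ``"pooled"``) aggregates raw counts across
    libraries before normalizing.
    """
    lengths = list(lengths)
    profiles = []
    pooled: Counter[int] = Counter()
    for lib, hist in histograms.items():
        total = sum(hist.values())
        if total <= 0:
            raise ValueError(f"library {lib!r}: empty read-length histogram")
        bad = [l for l in hist if l not in lengths]
        if bad:
            raise ValueError(f"library {lib!r}: length(s) {bad} outside {lengths[0]}–{lengths[-1]} nt")
        if any(v < 0 for v in hist.values()):
            raise ValueError(f"library {lib!r}: negative length count")
        props = {l: hist.get(l, 0) / total for l in lengths}
        profiles.append(LengthProfile(library_id=lib, proportions=props))
        pooled.update(hist)
    total = sum(pooled.values())
    pooled_profile = LengthProfile(
        library_id="pooled", proportions={l: pooled.get(l, 0) / total for l in lengths}
    )
    return profiles, pooled_profile


def classify_reads(
    reads: Iterable[str],
    class_sets: Mapping[str, Iterable[str]],
    library_id: str = "",
    priority: Sequence[str] = CLASS_PRIORITY,
) -> ClassComposition:
    """Assign each read to the first annotation class containing it.

    Matching is exact, full-length, case-insensitive string identity
    against the supplied per-class sequence sets (the database/alignment
    annotation a full pipeline would do upstream is out of scope here).
    Reads matching no class are "unannotated"; class counts always sum to
    the number of input reads.  An empty ``class_sets`` is allowed — every
    read is then unannotated.
    """
    lookup = []
    for cls in priority:
        seqs = class_sets.get(cls)
        if seqs is not None:
            lookup.append((cls, {s.upper() for s in seqs}))
    extra = [c for c in class_sets if c not in priority]
    for cls in extra:
        lookup.append((cls, {s.upper() for s in class_sets[cls]}))

    counts: Counter[str] = Counter({cls: 0 for cls, _ in lookup})
    counts["unannotated"] = 0
    for read in reads:
        seq = read.upper()
        for cls, seqs in lookup:
            if seq in seqs:
                counts[cls] += 1
                break
        else:
            counts["unannotated"] += 1
    return ClassComposition(library_id=library_id, counts=dict(counts))


def length_profiles_frame(profiles: Sequence[LengthProfile]) -> pd.DataFrame:
    """Tabulate length profiles as a libraries x lengths DataFrame."""
    rows = {p.library_id: p.proportions for p in profiles}
    df = pd.DataFrame(rows).T
    df.index.name = "library_id"
    return df
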