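"""Acceptance criteria for novel miRNA candidates.

A candidate (already validated upstream for a hairpin precursor) is
accepted as a novel miRNA when at least one of three lines of evidence
holds:

* ``H`` — high abundance: mature TPM strictly above ``tpm_high``
  (default 50) in at least one library;
* ``F`` — detection breadth: the mature sequence detected (TPM strictly
  above ``detection_floor``, default 0) in at least half of the libraries;
* ``S`` — biogenesis: the miRNA* passenger strand observed in at least
  one library.

Detection breadth defaults to "at least half" (``2 * n_detected >= n``)
because the published candidate set treats 5 of 10 libraries as
sufficient; a literal strict-majority reading is available via
``strict_majority=True``.  The evidence codes mirror the candidate table's
legend (``S`` rendered there as ``*``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from spikefill.io import LibraryMeta, ParseError

#: TPM above which a single library suffices for acceptance (criterion H).
DEFAULT_TPM_HIGH = 50.0
#: TPM strictly above this counts as "detected" (criterion F).
DEFAULT_DETECTION_FLOOR = 0.0

_VALID_BASES = set("ACGTU")


@dataclass(frozen=True)
class NovelCandidate:
    """A mature candidate sequence with per-library expression evidence."""

    candidate_id: str
    mature_sequence: str
    tpm_by_library: dict[str, float]
    star_detected_by_library: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seq = self.mature_sequence.upper()
        if not 18 <= len(seq) <= 26:
            raise ValueError(
                f"{self.candidate_id}: mature sequence length {len(seq)} "
                "outside the 18–26 nt mature miRNA range"
            )
        if set(seq) - _VALID_BASES:
            raise ValueError(
                f"{self.candidate_id}: invalid bases {sorted(set(seq) - _VALID_BASES)}"
            )
        if any(v < 0 for v in self.tpm_by_library.values()):
            raise ValueError(f"{self.candidate_id}: negative TPM value")

    @property
    def length(self) -> int:
        return len(self.mature_sequence)


@dataclass(frozen=True)
class NovelDecision:
    candidate_id: str
    accepted: bool
    evidence_codes: frozenset[str]


def evaluate_candidate(
    candidate: NovelCandidate,
    n_libraries: int,
    tpm_high: float = DEFAULT_TPM_HIGH,
    detection_floor: float = DEFAULT_DETECTION_FLOOR,
    strict_majority: bool = False,
) -> NovelDecision:
    """Apply the three acceptance criteria to one candidate.

    ``n_libraries`` is the size of the library universe (detections are
    counted against it, not against the keys present in the TPM map).
    """
    if n_libraries < 1:
        raise ValueError(f"n_libraries must be >= 1, got {n_libraries}")
    if not candidate.tpm_by_library:
        raise ValueError(f"{candidate.candidate_id}: empty TPM map")
    codes = set()
    tpms = candidate.tpm_by_library.values()
    if max(tpms) > tpm_high:
        codes.add("H")
    n_detected = sum(v > detection_floor for v in tpms)
    breadth_ok = (
        2 * n_detected > n_libraries if strict_majority else 2 * n_detected >= n_libraries
    )
    if breadth_ok:
        codes.add("F")
    if any(candidate.star_detected_by_library.values()):
        codes.add("S")
    return NovelDecision(
        candidate_id=candidate.candidate_id,
        accepted=bool(codes),
        evidence_codes=frozenset(codes),
    )


def evaluate_all(
    candidates: Sequence[NovelCandidate],
    meta: Sequence[LibraryMeta] | None = None,
    n_libraries: int | None = None,
    **kwargs,
) -> list[NovelDecision]:
    """Evaluate every candidate against a consistent library universe.

    Rejected candidates are retained (with empty evidence) for audit.
    The universe comes from ``meta`` when given, else ``n_libraries``,
    else the union of library ids seen across candidates.
    """
    if meta is not None:
        universe = {m.library_id for m in meta}
        for c in candidates:
            stray = set(c.tpm_by_library) - universe
            if stray:
                raise ParseError(
                    f"{c.candidate_id}: TPM reported for unknown librarie(s) {sorted(stray)}"
                )
        n = len(universe)
    elif n_libraries is not None:
        n = n_libraries
    else:
        n = len({lib for c in candidates for lib in c.tpm_by_library})
    return [evaluate_candidate(c, n, **kwargs) for c in candidates]


def load_novel_fixture(path: str | Path | None = None) -> list[NovelCandidate]:
    """Load the packaged novel-candidate table (13 published candidates).

    Rows whose published evidence code is ``*`` get a star flag set in
    their highest-TPM library — the published table records only that the
    passenger strand was seen in at least one library, not in which one,
    so the placement is a synthetic stand-in for that fact.
    """
    if path is None:
        ref = resources.files("spikefill.data") / "novel_mirna_candidates.tsv"
        with resources.as_file(ref) as p:
            return load_novel_fixture(p)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    lib_cols = [c for c in df.columns if c not in ("candidate_id", "sequence", "length", "evidence")]
    out = []
    for _, row in df.iterrows():
        tpm = {lib: float(row[lib]) for lib in lib_cols}
        stars: dict[str, bool] = {}
        if row.get("evidence") == "*":
            positives = [lib for lib, v in tpm.items() if v > 0]
            anchor = max(positives, key=lambda l: tpm[l]) if positives else lib_cols[0]
            stars[anchor] = True
        cand = NovelCandidate(
            candidate_id=str(row["candidate_id"]),
            mature_sequence=str(row["sequence"]),
            tpm_by_library=tpm,
            star_detected_by_library=stars,
        )
        if int(row["length"]) != cand.length:
            raise ParseError(
                f"{cand.candidate_id}: declared length {row['length']} != "
                f"sequence length {cand.length}"
            )
        out.append(cand)
    return out


def decisions_frame(decisions: Sequence[NovelDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "candidate_id": [d.candidate_id for d in decisions],
            "accepted": [d.accepted for d in decisions],
            "evidence": ["".join(sorted(d.evidence_codes)) for d in decisions],
        }
    )
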