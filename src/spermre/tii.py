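"""Transcript Integrity Index (TII) sample QC.

RNA quality per sample is scored from coverage of a panel of stable
sperm-specific transcripts (22 in the reference workflow, supplied by the
user, never hard-coded).  A transcript "passes" in a sample when at least
half of its exon bases are covered at >= 5 RPM; the sample-level TII score is
the fraction of panel transcripts passing.  Samples in the fourth quartile of
TII scores (strictly below the linear-interpolation 25th percentile) are
flagged as poor-quality RNA and removed.

Both coverage comparisons use >= at their thresholds ("at least 5 reads" is
>= by plain reading; the 50% side follows the same convention).  Ties at the
25th percentile are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import CoverageTrack

__all__ = ["TIIResult", "transcript_fraction", "transcript_pass", "compute_tii", "filter_q4"]


@dataclass
class TIIResult:
    sample_id: str
    per_transcript_fraction: dict[str, float]
    n_pass: int
    tii_score: float
    quartile: int | None = None
    passed: bool | None = None

    @property
    def n_panel(self) -> int:
        return len(self.per_transcript_fraction)


def transcript_fraction(track: CoverageTrack, rpm_threshold: float = 5.0) -> float:
    """Fraction of exon bases covered at >= rpm_threshold."""
    if track.n_bases == 0:
        raise ValueError(f"{track.transcript_id}: empty exon set")
    return float(np.count_nonzero(track.depth >= rpm_threshold)) / track.n_bases


def transcript_pass(
    track: CoverageTrack,
    rpm_threshold: float = 5.0,
    coverage_fraction: float = 0.5,
) -> bool:
    """True iff >= ``coverage_fraction`` of exon bases reach ``rpm_threshold``."""
    return transcript_fraction(track, rpm_threshold) >= coverage_fraction


def compute_tii(
    tracks: Iterable[CoverageTrack] | Mapping[str, CoverageTrack],
    panel: Sequence[str],
    rpm_threshold: float = 5.0,
    coverage_fraction: float = 0.5,
) -> TIIResult:
    """TII for one sample over ``panel`` transcripts.

    A panel transcript with no track contributes fraction 0 (it is simply not
    covered in this sample).
    """
    if not panel:
        raise ValueError("empty panel: TII undefined")
    if isinstance(tracks, Mapping):
        by_tid = dict(tracks)
    else:
        by_tid = {t.transcript_id: t for t in tracks}
    samples = {t.sample_id for t in by_tid.values()}
    if len(samples) > 1:
        raise ValueError(f"compute_tii takes tracks for one sample, got {sorted(samples)}")
    sample_id = samples.pop() if samples else ""
    fractions = {
        tid: (transcript_fraction(by_tid[tid], rpm_threshold) if tid in by_tid else 0.0)
        for tid in panel
    }
    n_pass = sum(1 for f in fractions.values() if f >= coverage_fraction)
    return TIIResult(
        sample_id=sample_id,
        per_transcript_fraction=fractions,
        n_pass=n_pass,
        tii_score=n_pass / len(panel),
    )


def filter_q4(results: Sequence[TIIResult]) -> tuple[list[TIIResult], list[TIIResult]]:
    """Assign quartiles and split into (kept, removed) by the Q4 rule.

    Quartile boundaries are the linear-interpolation 25/50/75th percentiles of
    the score vector; a sample is Q4 (removed) iff its score is strictly below
    the 25th percentile, so ties at the boundary are kept and the max-score
    sample always survives.  Deterministic and order-independent.
    """
    if len(results) < 4:
        raise ValueError(f"need >= 4 samples for quartiles, got {len(results)}")
    scores = np.array([r.tii_score for r in results], dtype=float)
    q25, q50, q75 = np.percentile(scores, [25, 50, 75])
    kept: list[TIIResult] = []
    removed: list[TIIResult] = []
    for r in results:
        s = r.tii_score
        if s < q25:
            r.quartile = 4
        elif s < q50:
            r.quartile = 3
        elif s < q75:
            r.quartile = 2
        else:
            r.quartile = 1
        r.passed = r.quartile != 4
        (kept if r.passed else removed).append(r)
    return kept, removed
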