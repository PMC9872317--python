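"""Full-length transcript calls from per-sample exon coverage.

A programmatic stand-in for genome-browser visual inspection: a transcript is
FULL_LENGTH when every assessed sample covers it at >= 5 RPKM, PARTIAL when
some but not all samples do, FAIL when none does.  "Covers" defaults to the
strictest reading — every exon base at or above threshold — with a
configurable fraction-of-bases relaxation, since visual calls tolerate small
gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .io import CoverageTrack

__all__ = ["IntegrityCall", "FULL_LENGTH", "PARTIAL", "FAIL", "sample_covers", "call_integrity"]

FULL_LENGTH = "FULL_LENGTH"
PARTIAL = "PARTIAL"
FAIL = "FAIL"


@dataclass(frozen=True)
class IntegrityCall:
    transcript_id: str
    status: str
    n_pass: int
    n_total: int
    rpkm_min: float

    @property
    def label(self) -> str:
        """Rendered as printed in results tables."""
        if self.status == FULL_LENGTH:
            return "Full-length"
        if self.status == PARTIAL:
            return f"Full-length (≥ 1 < {self.n_total} samples)"
        return "Fail"


def sample_covers(track: CoverageTrack, rpkm_min: float = 5.0,
                  min_fraction: float = 1.0) -> bool:
    """Does one sample cover the transcript at >= rpkm_min?

    With the default ``min_fraction`` of 1.0 every exon base must reach the
    threshold; lower values tolerate small gaps.
    """
    frac = float(np.count_nonzero(track.depth >= rpkm_min)) / track.n_bases
    return frac >= min_fraction


def call_integrity(
    tracks: Iterable[CoverageTrack] | Mapping[str, CoverageTrack],
    rpkm_min: float = 5.0,
    min_fraction: float = 1.0,
) -> IntegrityCall:
    """FULL_LENGTH / PARTIAL / FAIL for one transcript across samples."""
    tracks = list(tracks.values()) if isinstance(tracks, Mapping) else list(tracks)
    if not tracks:
        raise ValueError("need >= 1 sample track")
    tids = {t.transcript_id for t in tracks}
    if len(tids) != 1:
        raise ValueError(f"tracks span several transcripts: {sorted(tids)}")
    exon_models = {tuple(t.exons) for t in tracks}
    if len(exon_models) != 1:
        raise ValueError(f"{tids.pop()}: inconsistent exon models across samples")
    n_total = len(tracks)
    n_pass = sum(1 for t in tracks if sample_covers(t, rpkm_min, min_fraction))
    status = FULL_LENGTH if n_pass == n_total else (PARTIAL if n_pass >= 1 else FAIL)
    return IntegrityCall(
        transcript_id=tracks[0].transcript_id,
        status=status, n_pass=n_pass, n_total=n_total, rpkm_min=rpkm_min,
    )
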