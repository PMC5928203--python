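"""Locate -10/-35 promoter elements and classify TF sites by mode.

A sigma70-style promoter is modeled as a TTGACA (-35) hexamer, a 15-19 bp
spacer, and a TATAAT (-10) hexamer, each scored with a consensus-biased
weight matrix on the coding strand only.  The joint score of the best
arrangement is compared against a per-region empirical null (best joint
score in shuffled copies of the same region); below the 95th percentile of
that null the promoter call is "none".

Mode of regulation follows promoter geometry: a TF site lying entirely
upstream of the -35 element leaves the polymerase footprint free and is
called an activator site; a site overlapping either element, the spacer, or
lying downstream of the -10 element occludes polymerase and is called a
repressor site; without a confident promoter the mode is undetermined (ND).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from bifidoreg.genome_io import UpstreamRegion
from bifidoreg.motif_core import build_weights, encode
from bifidoreg.site_scan import SiteHit

MINUS10_CONSENSUS = "TATAAT"
MINUS35_CONSENSUS = "TTGACA"
SPACER_RANGE = (15, 19)            # inclusive, bp between -35 end and -10
NULL_SHUFFLES = 60
NULL_QUANTILE = 0.95
_NULL_SEED = 1804                  # fixed: calibration must be reproducible
#: a confident call must also come within this margin of the best possible
#: joint score; one hexamer mismatch costs ~2.1, so the default admits only
#: consensus-grade promoters and leaves weaker arrangements as "none"
CONSENSUS_MARGIN = 1.0

REPRESSOR = "repressor"
ACTIVATOR = "activator"
UNDETERMINED = "ND"


def _consensus_weights(consensus: str, strength: float = 8.0) -> np.ndarray:
    """Zero-sum weights strongly favoring the consensus hexamer."""
    counts = np.full((len(consensus), 4), 1.0)
    counts[np.arange(len(consensus)), encode(consensus)] = strength
    return build_weights(counts)


_W10 = _consensus_weights(MINUS10_CONSENSUS)
_W35 = _consensus_weights(MINUS35_CONSENSUS)


@dataclass(frozen=True)
class PromoterAnnotation:
    """Best -35/spacer/-10 arrangement in one upstream region.

    Offsets are indices into the region sequence (coding strand).
    ``confidence`` is "confident" or "none".
    """

    minus35_offset: int
    minus35_seq: str
    minus35_score: float
    minus10_offset: int
    minus10_seq: str
    minus10_score: float
    spacer_len: int
    joint_score: float
    confidence: str

    @property
    def confident(self) -> bool:
        return self.confidence == "confident"


def _hexamer_scores(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    n = codes.size - 6 + 1
    if n <= 0:
        return np.full(0, -np.inf)
    win = np.lib.stride_tricks.sliding_window_view(codes, 6)
    bad = (win < 0).any(axis=1)
    safe = np.where(win < 0, 0, win)
    scores = weights[np.arange(6), safe].sum(axis=1)
    scores[bad] = -np.inf
    return scores


def _best_arrangement(codes: np.ndarray
                      ) -> tuple[float, int, int, int] | None:
    """(joint score, -35 offset, -10 offset, spacer) of the best layout.

    Ties break toward the arrangement closer to the start codon (larger -10
    offset), then the shorter spacer — a total order, hence deterministic.
    """
    s35 = _hexamer_scores(codes, _W35)
    s10 = _hexamer_scores(codes, _W10)
    best: tuple[float, int, int, int] | None = None
    for spacer in range(SPACER_RANGE[0], SPACER_RANGE[1] + 1):
        shift = 6 + spacer
        n = s35.size - shift
        if n <= 0:
            continue
        joint = s35[:n] + s10[shift:shift + n]
        # among equal scores prefer the arrangement closest to the start
        # codon (the largest offset), hence argmax on the reversed array
        i = n - 1 - int(joint[::-1].argmax())
        cand = (float(joint[i]), i, i + shift, spacer)
        if best is None \
                or cand[0] > best[0] \
                or (cand[0] == best[0] and (cand[2], -cand[3])
                    > (best[2], -best[3])):
            best = cand
    return best


def promoter_null_cutoff(seq: str, n_shuffles: int = NULL_SHUFFLES,
                         quantile: float = NULL_QUANTILE) -> float:
    """Empirical score cutoff: quantile of best joint scores over
    composition-preserving shuffles of the region itself."""
    rng = np.random.default_rng(_NULL_SEED)
    codes = encode(seq)
    scores = []
    for _ in range(n_shuffles):
        arr = _best_arrangement(rng.permutation(codes))
        scores.append(arr[0] if arr else -np.inf)
    return float(np.quantile(scores, quantile))


def find_promoter(region: UpstreamRegion | str,
                  consensus_margin: float = CONSENSUS_MARGIN
                  ) -> PromoterAnnotation:
    """Best-scoring sigma70 promoter arrangement on the coding strand.

    Requires a region of at least 60 bp.  A call is "confident" only when
    the joint score both exceeds the shuffled-region null cutoff and comes
    within ``consensus_margin`` of the best achievable joint score; an
    exact consensus arrangement always qualifies, while background
    arrangements essentially never do.
    """
    seq = region if isinstance(region, str) else region.seq
    if len(seq) < 60:
        raise ValueError("region too short for promoter search (<60 bp)")
    codes = encode(seq)
    arr = _best_arrangement(codes)
    assert arr is not None
    joint, o35, o10, spacer = arr
    cutoff = promoter_null_cutoff(seq)
    max_joint = float(_W35.max(axis=1).sum() + _W10.max(axis=1).sum())
    conf = "confident" if joint > cutoff \
        and joint >= max_joint - consensus_margin else "none"
    return PromoterAnnotation(
        minus35_offset=o35, minus35_seq=seq[o35:o35 + 6],
        minus35_score=float(_hexamer_scores(codes[o35:o35 + 6], _W35)[0]),
        minus10_offset=o10, minus10_seq=seq[o10:o10 + 6],
        minus10_score=float(_hexamer_scores(codes[o10:o10 + 6], _W10)[0]),
        spacer_len=spacer, joint_score=joint, confidence=conf)


def classify_mode_offsets(site_start: int, site_end: int,
                          promoter: PromoterAnnotation) -> str:
    """Mode from site interval vs promoter elements, all in region coords.

    activator  iff the site lies entirely upstream of the -35 element;
    repressor  otherwise (overlapping either element, filling the spacer,
               or downstream of the -10 element — all occlude polymerase);
    ND         when no confident promoter was found.
    """
    if not promoter.confident:
        return UNDETERMINED
    if site_end <= promoter.minus35_offset:
        return ACTIVATOR
    return REPRESSOR


def classify_mode(hit: SiteHit, promoter: PromoterAnnotation,
                  region: UpstreamRegion) -> str:
    """Mode for a scanned hit in the region it was found in."""
    start = hit.pos_vs_start_codon + region.offset_of_start_codon
    return classify_mode_offsets(start, start + len(hit.sequence), promoter)


def render_region(region: UpstreamRegion, promoter: PromoterAnnotation,
                  site_start: int | None = None,
                  site_len: int = 0) -> str:
    """Plain-text rendering with promoter boxes and site brackets."""
    seq = region.seq
    marks = [" "] * len(seq)
    if promoter.confident:
        for i in range(promoter.minus35_offset, promoter.minus35_offset + 6):
            marks[i] = "3"
        for i in range(promoter.minus10_offset, promoter.minus10_offset + 6):
            marks[i] = "1"
    if site_start is not None:
        for i in range(site_start, min(site_start + site_len, len(seq))):
            marks[i] = "[" if marks[i] == " " else "#"
    lines = []
    for i in range(0, len(seq), 60):
        lines.append(seq[i:i + 60])
        lines.append("".join(marks[i:i + 60]))
    return "\n".join(lines)
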