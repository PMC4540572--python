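"""Both-strand mPWM scanning of FASTA sequences (the "Score" tool).

Every L-bp window on each strand is scored; windows containing an
ambiguous base (N) are skipped rather than scored with a penalty.
Reverse-strand hits are reported at the forward-strand start of the
window, so one coordinate system serves both strands. Modes:

* ``all`` — every scored window, both strands;
* ``threshold`` — hits with score >= limit (inclusive, so a published
  cutoff keeps sites exactly at it);
* ``best`` — the single top hit per sequence, ties broken by smallest
  start and then the + strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .mpwm import MPWM, MPWMError, NT_INDEX, revcomp, score_window

__all__ = [
    "SequenceRecord",
    "SiteHit",
    "ScanReport",
    "read_fasta",
    "scan_record",
    "scan_fasta",
    "best_hit",
    "score_profile",
    "score_histogram",
]

MODES = ("best", "threshold", "all")

_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence; input is upper-cased and any non-ACGT letter
    (IUPAC ambiguity codes included) is normalized to N."""

    id: str
    seq: str

    @staticmethod
    def from_raw(id: str, seq: str) -> "SequenceRecord":
        return SequenceRecord(id, _NON_ACGTN.sub("N", seq.upper()))


@dataclass(frozen=True)
class SiteHit:
    """One scored window.

    ``start`` is the 0-based offset of the window's leftmost base on the
    forward strand regardless of strand; ``site`` is the L-mer as read
    in scoring orientation (reverse-complemented for - hits).
    """

    seq_id: str
    start: int
    strand: str
    site: str
    score: float


@dataclass
class ScanReport:
    """Per-record hit lists from one scan, with the mode and limit used."""

    hits: dict[str, list[SiteHit]]
    mode: str
    limit: Optional[float] = None

    def all_hits(self) -> list[SiteHit]:
        return [h for hits in self.hits.values() for h in hits]


def read_fasta(path) -> list[SequenceRecord]:
    """Read a multi-record FASTA into normalized sequence records."""
    from Bio import SeqIO

    return [SequenceRecord.from_raw(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def scan_record(
    model: MPWM,
    rec: SequenceRecord,
    mode: str = "all",
    limit: Optional[float] = None,
) -> list[SiteHit]:
    """Score every valid window of one record on both strands.

    Hits are ordered by start, + strand before -. A sequence shorter
    than the model yields an empty list. ``limit`` is required in
    threshold mode and ignored otherwise.
    """
    if mode not in MODES:
        raise MPWMError(f"unknown scan mode {mode!r}; expected one of {MODES}")
    if mode == "threshold" and limit is None:
        raise MPWMError("mode='threshold' requires a limit")
    L = model.length
    seq = rec.seq
    hits: list[SiteHit] = []
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        if "N" in window:
            continue
        hits.append(SiteHit(rec.id, start, "+", window, score_window(model, window)))
        rc = revcomp(window)
        hits.append(SiteHit(rec.id, start, "-", rc, score_window(model, rc)))
    if mode == "threshold":
        hits = [h for h in hits if h.score >= limit]
    elif mode == "best":
        best = _argbest(hits)
        hits = [best] if best is not None else []
    return hits


def _argbest(hits: Sequence[SiteHit]) -> Optional[SiteHit]:
    best = None
    for h in hits:  # generation order is (start asc, + before -): ties keep first
        if best is None or h.score > best.score:
            best = h
    return best


def best_hit(model: MPWM, rec: SequenceRecord) -> Optional[SiteHit]:
    """The maximal-score hit of a record, or None if no window is valid."""
    return _argbest(scan_record(model, rec, mode="all"))


def scan_fasta(
    model: MPWM,
    records: Iterable[SequenceRecord],
    mode: str = "all",
    limit: Optional[float] = None,
) -> ScanReport:
    """Scan a collection of records; one hit list per record id."""
    return ScanReport(
        {rec.id: scan_record(model, rec, mode, limit) for rec in records}, mode, limit
    )


def score_profile(hits: Sequence[SiteHit], seq_length: int) -> dict[str, np.ndarray]:
    """Per-start score traces for one record, for plotting.

    Returns arrays ``starts``, ``forward`` and ``reverse`` of equal
    length (one entry per possible window start); positions without a
    hit hold NaN. Trace values equal hit scores exactly — no smoothing.
    """
    if not hits:
        empty = np.empty(0)
        return {"starts": empty.astype(int), "forward": empty, "reverse": empty}
    L = len(hits[0].site)
    n = seq_length - L + 1
    fwd = np.full(n, np.nan)
    rev = np.full(n, np.nan)
    for h in hits:
        (fwd if h.strand == "+" else rev)[h.start] = h.score
    return {"starts": np.arange(n), "forward": fwd, "reverse": rev}


def score_histogram(
    hits: Sequence[SiteHit] | Sequence[float],
    bin_width: float,
    origin: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin hit scores into half-open bins [lo, lo + width).

    Returns ``(edges, counts)`` with ``len(edges) == len(counts) + 1``.
    The origin defaults to the smallest bin edge at a multiple of the
    width covering the minimum score. Counts always sum to the number of
    scores.
    """
    if bin_width <= 0:
        raise MPWMError("bin_width must be > 0")
    scores = np.array(
        [h.score if isinstance(h, SiteHit) else float(h) for h in hits], dtype=float
    )
    if scores.size == 0:
        return np.empty(0), np.empty(0, dtype=int)
    if origin is None:
        origin = math_floor_mult(scores.min(), bin_width)
    idx = np.floor((scores - origin) / bin_width).astype(int)
    if np.any(idx < 0):
        raise MPWMError("histogram origin lies above the minimum score")
    counts = np.bincount(idx)
    edges = origin + bin_width * np.arange(counts.size + 1)
    return edges, counts


def math_floor_mult(x: float, w: float) -> float:
    """Largest multiple of w that is <= x."""
    return float(np.floor(x / w) * w)
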