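"""Thermodynamic predicted occupancy of DNA regions (the "Occupancy" tool).

A site's score is linearly related to the log of its relative
dissociation constant, score = -a*ln(Kd) + b, so Kd = exp((b - score)/a).
At TF concentration [X] the site is bound with probability

    p = [X] / ([X] + Kd)        (single-site binding isotherm)

When no concentration is supplied it defaults to [X] = e**(b/a), the
concentration at which the best possible site (maximal score, 0 for a
normalized weight model) is bound with probability one half. With the
default calibration a=1, b=0 this is [X] = 1.

A region's predicted occupancy is the SUM of the binding probabilities
of its sites (both strands) — the expected number of bound sites —
optionally restricted to sites with score >= limit. Overlapping sites
contribute independently; no steric exclusion or TF-TF competition is
modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .mpwm import MPWM, Calibration
from .scanner import SequenceRecord, SiteHit, scan_record

__all__ = [
    "OccupancyResult",
    "kd_from_score",
    "default_concentration",
    "resolve_concentration",
    "site_probability",
    "region_occupancy",
    "occupancy_fasta",
]

DEFAULT_CALIBRATION = Calibration(a=1.0, b=0.0)


@dataclass(frozen=True)
class OccupancyResult:
    """Predicted occupancy of one region and the parameters used."""

    seq_id: str
    occupancy: float
    n_sites_used: int
    a: float
    b: float
    concentration: float
    limit: Optional[float] = None


def kd_from_score(score: float, calib: Calibration = DEFAULT_CALIBRATION) -> float:
    """Relative dissociation constant of a site: Kd = exp((b - score)/a).

    Strictly decreasing in score; the maximal-score site of a normalized
    model (score 0) has Kd = e**(b/a).
    """
    return math.exp((calib.b - score) / calib.a)


def default_concentration(calib: Calibration = DEFAULT_CALIBRATION) -> float:
    """Default relative TF concentration [X] = e**(b/a), at which the
    maximal-score site is bound with probability 0.5."""
    return math.exp(calib.b / calib.a)


def resolve_concentration(calib: Calibration) -> float:
    """The calibration's concentration, or the default when absent."""
    if calib.concentration is not None:
        return calib.concentration
    return default_concentration(calib)


def site_probability(score: float, calib: Calibration = DEFAULT_CALIBRATION) -> float:
    """Binding probability of one site, p = [X]/([X] + Kd).

    Strictly increasing in score; exactly 0.5 when [X] = Kd.
    """
    x = resolve_concentration(calib)
    kd = kd_from_score(score, calib)
    return x / (x + kd)


def region_occupancy(
    hits: Sequence[SiteHit],
    calib: Calibration = DEFAULT_CALIBRATION,
    limit: Optional[float] = None,
    seq_id: Optional[str] = None,
) -> OccupancyResult:
    """Sum site binding probabilities over one record's mode=all hits.

    Sites with score below ``limit`` are excluded (all sites when limit
    is None). An empty retained set gives occupancy 0.
    """
    retained = [h for h in hits if limit is None or h.score >= limit]
    occ = sum(site_probability(h.score, calib) for h in retained)
    if seq_id is None:
        seq_id = hits[0].seq_id if hits else ""
    return OccupancyResult(
        seq_id=seq_id,
        occupancy=occ,
        n_sites_used=len(retained),
        a=calib.a,
        b=calib.b,
        concentration=resolve_concentration(calib),
        limit=limit,
    )


def occupancy_fasta(
    model: MPWM,
    records: Iterable[SequenceRecord],
    calib: Optional[Calibration] = None,
    limit: Optional[float] = None,
) -> list[OccupancyResult]:
    """Predicted occupancy of each record under a weight model.

    The calibration defaults to the model's own (from its file) and then
    to a=1, b=0 with the default concentration rule.
    """
    if calib is None:
        calib = model.calibration or DEFAULT_CALIBRATION
    results = []
    for rec in records:
        hits = scan_record(model, rec, mode="all")
        results.append(region_occupancy(hits, calib, limit, seq_id=rec.id))
    return results
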