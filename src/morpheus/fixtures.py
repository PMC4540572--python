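"""Synthetic inputs for tests, examples, and benchmarking.

Everything here is seeded and deterministic: random weight models,
order-0 (i.i.d.) background sequences at a chosen GC content, positives
with consensus sites planted at known positions and strands, and
size-matched non-overlapping negative sets sampled from a genome — the
standard recipe for building an ROC control class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .mpwm import (
    ALPHABET,
    DependencyGroup,
    MPWM,
    MPWMError,
    consensus_site,
    nt_tuples,
    revcomp,
    validate,
    weights_from_frequencies,
)
from .scanner import SequenceRecord

__all__ = [
    "PlantedTruth",
    "random_weight_model",
    "background_sequences",
    "plant_sites",
    "sample_negative_set",
    "load_bed",
    "write_fasta",
]


@dataclass
class PlantedTruth:
    """Ground truth for planted sites: per record id, a list of
    (start, strand, site) with the site in scoring orientation."""

    sites: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)


def random_weight_model(
    L: int,
    n_groups: int = 0,
    d: int = 2,
    seed: int = 0,
    name: str = "random",
) -> MPWM:
    """A normalized random weight mPWM (max score 0).

    Per-position and per-group frequencies are drawn from a flat
    Dirichlet and converted with the ln(f/f_max) rule; group positions
    are sampled disjointly at random. Deterministic per seed.
    """
    if n_groups * d > L:
        raise MPWMError(
            f"cannot place {n_groups} disjoint groups of {d} positions in L={L}"
        )
    rng = np.random.default_rng(seed)
    matrix = rng.dirichlet(np.ones(4), size=L)
    perm = rng.permutation(L) + 1
    groups = []
    for i in range(n_groups):
        positions = tuple(sorted(int(p) for p in perm[i * d : (i + 1) * d]))
        freqs = rng.dirichlet(np.ones(4 ** d))
        groups.append(
            DependencyGroup(positions, dict(zip(nt_tuples(d), freqs.tolist())))
        )
    freq_model = validate(MPWM(name, "frequency", matrix, groups))
    return weights_from_frequencies(freq_model)


def background_sequences(
    n: int,
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    id_prefix: str = "bg",
) -> list[SequenceRecord]:
    """i.i.d. background sequences with P(G)+P(C) = gc, split equally."""
    if not (0 < gc < 1):
        raise MPWMError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list(ALPHABET))
    return [
        SequenceRecord(
            f"{id_prefix}_{i}", "".join(alphabet[rng.choice(4, size=length, p=probs)])
        )
        for i in range(n)
    ]


def plant_sites(
    records: Sequence[SequenceRecord],
    model: MPWM,
    sites_per_record: int = 1,
    strand_policy: str = "both",
    seed: int = 0,
    max_attempts: int = 10_000,
) -> tuple[list[SequenceRecord], PlantedTruth]:
    """Write the model's consensus site into each record at random
    non-overlapping positions.

    ``strand_policy``: '+' plants the consensus forward, '-' plants its
    reverse complement, 'both' picks a strand uniformly per site. The
    returned truth records (start, strand, consensus) per record.
    """
    if strand_policy not in ("+", "-", "both"):
        raise MPWMError("strand_policy must be '+', '-', or 'both'")
    rng = np.random.default_rng(seed)
    site = consensus_site(model)
    L = len(site)
    truth = PlantedTruth()
    out: list[SequenceRecord] = []
    for rec in records:
        if sites_per_record == 0:
            out.append(rec)
            truth.sites[rec.id] = []
            continue
        if len(rec.seq) < L * sites_per_record:
            raise MPWMError(
                f"record {rec.id} (length {len(rec.seq)}) cannot hold "
                f"{sites_per_record} non-overlapping {L}-bp sites"
            )
        starts = _place_nonoverlapping(
            rng, len(rec.seq), L, sites_per_record, max_attempts, rec.id
        )
        seq = list(rec.seq)
        entries = []
        for start in starts:
            strand = (
                strand_policy
                if strand_policy in ("+", "-")
                else ("+", "-")[int(rng.integers(2))]
            )
            planted = site if strand == "+" else revcomp(site)
            seq[start : start + L] = planted
            entries.append((start, strand, site))
        out.append(SequenceRecord(rec.id, "".join(seq)))
        truth.sites[rec.id] = sorted(entries)
    return out, truth


def _place_nonoverlapping(
    rng: np.random.Generator,
    seq_len: int,
    L: int,
    k: int,
    max_attempts: int,
    context: str,
) -> list[int]:
    placed: list[int] = []
    for _ in range(k):
        for _attempt in range(max_attempts):
            start = int(rng.integers(0, seq_len - L + 1))
            if all(abs(start - p) >= L for p in placed):
                placed.append(start)
                break
        else:
            raise MPWMError(
                f"could not place {k} non-overlapping {L}-bp sites in {context} "
                f"after {max_attempts} attempts"
            )
    return placed


def sample_negative_set(
    genome_records: Sequence[SequenceRecord],
    positive_intervals: Sequence[tuple[str, int, int]],
    seed: int = 0,
    max_attempts: int = 10_000,
) -> tuple[list[SequenceRecord], list[tuple[str, int, int]]]:
    """Sample one negative per positive with the same length, anywhere in
    the genome that overlaps neither a positive nor another negative.

    ``positive_intervals`` are BED-style (chrom, start, end), 0-based
    half-open. Returns the negative records and their intervals.
    Rejection sampling is capped at ``max_attempts`` per interval; a
    placement failure raises and names the lengths that failed.
    """
    by_id = {rec.id: rec for rec in genome_records}
    blocked: dict[str, list[tuple[int, int]]] = {rec.id: [] for rec in genome_records}
    for chrom, start, end in positive_intervals:
        if chrom not in blocked:
            raise MPWMError(f"positive interval on unknown sequence {chrom!r}")
        blocked[chrom].append((int(start), int(end)))
    rng = np.random.default_rng(seed)
    ids = [rec.id for rec in genome_records]
    records: list[SequenceRecord] = []
    intervals: list[tuple[str, int, int]] = []
    failed: list[int] = []
    for i, (_, pstart, pend) in enumerate(positive_intervals):
        length = int(pend) - int(pstart)
        placed = False
        for _attempt in range(max_attempts):
            chrom = ids[int(rng.integers(len(ids)))]
            room = len(by_id[chrom].seq) - length
            if room < 0:
                continue
            start = int(rng.integers(0, room + 1))
            end = start + length
            if any(start < e and b < end for b, e in blocked[chrom]):
                continue
            blocked[chrom].append((start, end))
            records.append(
                SequenceRecord(f"neg_{i}", by_id[chrom].seq[start:end])
            )
            intervals.append((chrom, start, end))
            placed = True
            break
        if not placed:
            failed.append(length)
    if failed:
        raise MPWMError(
            f"could not place negatives of lengths {failed} after "
            f"{max_attempts} attempts each"
        )
    return records, intervals


def load_bed(path) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) triples from a BED file (0-based,
    half-open; extra columns ignored)."""
    intervals = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return intervals


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    """Write records as uncompressed FASTA."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
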