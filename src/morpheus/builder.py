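"""Build mPWMs from alignments of equal-length binding sites.

The pipeline is counts -> (optional symmetrization) -> frequencies ->
weights. Dependency position groups are user input: which positions are
interdependent must be decided upstream (e.g. with a dependency-logo
tool); this module only tabulates the 4^d joint counts for the groups it
is given.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .mpwm import (
    ALPHABET,
    NT_INDEX,
    Calibration,
    DependencyGroup,
    MPWM,
    MPWMError,
    MPWMValidationError,
    nt_tuples,
    revcomp_model,
    validate,
    weights_from_frequencies,
)

__all__ = [
    "load_alignment",
    "counts_from_alignment",
    "frequencies_from_counts",
    "symmetrize",
    "build_weight_model",
]


def load_alignment(path) -> list[str]:
    """Read binding sites from plain text (one site per line) or FASTA.

    All sites must be the same length and contain only A, C, G, T
    (case-insensitive).
    """
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    if text.lstrip().startswith(">"):
        import io

        from Bio import SeqIO

        sites = [str(rec.seq).upper() for rec in SeqIO.parse(io.StringIO(text), "fasta")]
    else:
        sites = [line.strip().upper() for line in text.splitlines() if line.strip()]
    _check_alignment(sites)
    return sites


def _check_alignment(sites: Sequence[str]) -> int:
    if not sites:
        raise MPWMError("alignment has no sites")
    L = len(sites[0])
    for i, s in enumerate(sites):
        if len(s) != L:
            raise MPWMError(
                f"site {i + 1} has length {len(s)}, expected {L}: sites must be aligned"
            )
        for c in s:
            if c not in NT_INDEX:
                raise MPWMError(
                    f"site {i + 1} contains disallowed character {c!r} "
                    "(ambiguity codes are not accepted in alignments)"
                )
    return L


def counts_from_alignment(
    sites: Sequence[str],
    groups: Sequence[Sequence[int]] = (),
    name: str = "mpwm",
) -> MPWM:
    """Tally a count mPWM from aligned sites.

    The independent matrix holds per-position nucleotide counts at every
    position (including group members, so group tables marginalize to
    the matrix); each group's table counts the observed d-tuples read at
    its 1-based positions. Groups must be disjoint and within [1, L].
    """
    sites = [s.upper() for s in sites]
    L = _check_alignment(sites)
    matrix = np.zeros((L, 4))
    for s in sites:
        for p, c in enumerate(s):
            matrix[p, NT_INDEX[c]] += 1
    for g in groups:
        for p in g:
            if not (1 <= int(p) <= L):
                raise MPWMValidationError(
                    f"dependency group {tuple(g)}: position {p} outside [1, {L}]"
                )
    dep_groups = [
        DependencyGroup(tuple(int(p) for p in g), {k: 0.0 for k in nt_tuples(len(g))})
        for g in groups
    ]
    for g in dep_groups:
        for s in sites:
            key = "".join(s[p - 1] for p in g.positions)
            g.values[key] += 1
    return validate(MPWM(name, "count", matrix, dep_groups))


def frequencies_from_counts(model: MPWM, pseudocount: float = 0.5) -> MPWM:
    """Normalize counts to frequencies with additive smoothing.

    Per position: f = (count + pc) / (N + 4*pc); per group tuple:
    f = (count + pc) / (N + 4^d * pc), where N is the block total and pc
    the pseudocount added to every cell. pc = 0 reproduces the raw
    proportions and fails on an all-zero block.
    """
    if model.kind != "count":
        raise MPWMError(f"expected a count model, got kind={model.kind!r}")
    if pseudocount < 0:
        raise MPWMError("pseudocount must be >= 0")
    validate(model)
    matrix = model.matrix + pseudocount
    totals = matrix.sum(axis=1)
    if np.any(totals == 0):
        p = int(np.nonzero(totals == 0)[0][0]) + 1
        raise MPWMError(
            f"position {p} has zero total count and pseudocount is 0; "
            "cannot form frequencies"
        )
    matrix = matrix / totals[:, None]
    new_groups = []
    for g in model.groups:
        total = sum(g.values.values()) + (4 ** g.d) * pseudocount
        if total == 0:
            raise MPWMError(
                f"dependency group {g.positions} has zero total count and "
                "pseudocount is 0; cannot form frequencies"
            )
        new_groups.append(
            DependencyGroup(
                g.positions, {k: (v + pseudocount) / total for k, v in g.values.items()}
            )
        )
    return validate(MPWM(model.name, "frequency", matrix, new_groups, model.calibration))


def symmetrize(model: MPWM) -> MPWM:
    """Average a count or frequency model with its reverse complement.

    Appropriate for TFs binding as symmetric dimers. The result equals
    its own reverse-complement model. The model's dependency groups must
    be mirror-consistent: each group's mirrored position set must itself
    be a declared group (possibly the same group). Averaging happens in
    count/frequency space, never weight space, so the subsequent
    ln(f/f_max) normalization is preserved.
    """
    if model.kind not in ("count", "frequency"):
        raise MPWMError(
            f"symmetrize requires a count or frequency model, got kind={model.kind!r}"
        )
    validate(model)
    rc = revcomp_model(model)
    rc_by_pos = {g.positions: g for g in rc.groups}
    own_pos = {g.positions for g in model.groups}
    for g in model.groups:
        if g.positions not in rc_by_pos or (
            tuple(sorted(model.length + 1 - p for p in g.positions)) not in own_pos
        ):
            raise MPWMValidationError(
                f"dependency group {g.positions} has no mirror group at "
                f"{tuple(sorted(model.length + 1 - p for p in g.positions))}; "
                "cannot symmetrize"
            )
    matrix = (model.matrix + rc.matrix) / 2.0
    new_groups = [
        DependencyGroup(
            g.positions,
            {
                k: (v + rc_by_pos[g.positions].values[k]) / 2.0
                for k, v in g.values.items()
            },
        )
        for g in model.groups
    ]
    return validate(MPWM(model.name, model.kind, matrix, new_groups, model.calibration))


def build_weight_model(
    sites: Sequence[str],
    groups: Sequence[Sequence[int]] = (),
    pseudocount: float = 0.5,
    symmetric: bool = False,
    name: str = "mpwm",
    calibration: Optional[Calibration] = None,
) -> MPWM:
    """Alignment -> weight mPWM: counts, optional symmetrization,
    smoothed frequencies, then ln(f/f_max) weights (max score 0)."""
    model = counts_from_alignment(sites, groups, name=name)
    if symmetric:
        model = symmetrize(model)
    model = frequencies_from_counts(model, pseudocount)
    model = weights_from_frequencies(model)
    if calibration is not None:
        model.calibration = calibration
    return model
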