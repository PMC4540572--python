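"""mPWM binding models: data model, text format, and window scoring.

A position weight matrix (PWM) scores an L-bp DNA window as a sum of
per-position nucleotide weights, assuming positional independence. An
mPWM relaxes that assumption for declared groups of 2 or 3 (possibly
non-adjacent) positions: the joint nucleotide tuple at each group is
scored from a 4^d value table instead of d independent terms, so

    score(site) = sum over independent positions p of W[p, site[p]]
                + sum over dependency groups q of W_q[tuple at q]

Weights are log-ratios against the most frequent nucleotide (or tuple),
W = ln(f / f_max), so the best choice at every block scores 0 and the
best possible site scores 0 overall. Count and frequency models carry
the raw statistics; only weight models are scored.

The text format is line-oriented: ``name:``/``type:`` headers, optional
calibration headers (``a:``, ``b:``, ``concentration:``), a ``matrix:``
block of L rows in A C G T column order, then zero or more
``dependency: p1,p2[,p3]`` blocks of 4^d ``<tuple> <value>`` lines.
``#`` starts a comment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

ALPHABET = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

KINDS = ("count", "frequency", "weight")

#: tolerance for frequency-sum validation (text-format rounding)
FREQ_SUM_TOL = 1e-6


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G, N fixed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def nt_tuples(d: int) -> Iterator[str]:
    """All 4^d nucleotide tuples of width d in lexicographic order."""
    for combo in itertools.product(ALPHABET, repeat=d):
        yield "".join(combo)


class MPWMError(ValueError):
    """Base error for mPWM parsing, validation, and scoring."""


class MPWMParseError(MPWMError):
    pass


class MPWMValidationError(MPWMError):
    pass


@dataclass(frozen=True)
class Calibration:
    """Score <-> dissociation-constant calibration.

    The score of a site is related to its relative dissociation constant
    by ``score = -a * ln(Kd) + b``; ``a`` is the slope (score units per
    ln relative Kd, must be positive) and ``b`` the intercept.
    ``concentration`` is the relative TF concentration [X]; when absent
    the occupancy model resolves it to ``e**(b/a)``, the concentration at
    which the maximal-score site is bound with probability 0.5.
    """

    a: float = 1.0
    b: float = 0.0
    concentration: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise MPWMValidationError(f"calibration slope a must be > 0, got {self.a}")
        if self.concentration is not None and not (self.concentration > 0):
            raise MPWMValidationError(
                f"concentration must be > 0, got {self.concentration}"
            )


@dataclass
class DependencyGroup:
    """A 4^d value table over the joint nucleotides of d positions.

    ``positions`` are 1-based, distinct, d in {2, 3}; they need not be
    adjacent. ``values`` maps each d-tuple (read at the positions in
    their declared order) to one value.
    """

    positions: tuple[int, ...]
    values: dict[str, float]

    @property
    def d(self) -> int:
        return len(self.positions)

    def copy(self) -> "DependencyGroup":
        return DependencyGroup(self.positions, dict(self.values))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DependencyGroup):
            return NotImplemented
        return self.positions == other.positions and self.values == other.values


@dataclass(eq=False)
class MPWM:
    """A binding model: independent matrix plus dependency groups.

    ``matrix`` is an (L, 4) array in A,C,G,T column order; row index is
    the 0-based position. Rows at positions covered by a dependency
    group are present for positional readability but ignored in scoring.
    """

    name: str
    kind: str
    matrix: np.ndarray
    groups: list[DependencyGroup] = field(default_factory=list)
    calibration: Optional[Calibration] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def group_positions(self) -> set[int]:
        """All 1-based positions covered by some dependency group."""
        return {p for g in self.groups for p in g.positions}

    @property
    def independent_positions(self) -> list[int]:
        """1-based positions scored from the independent matrix."""
        covered = self.group_positions
        return [p for p in range(1, self.length + 1) if p not in covered]

    def copy(self) -> "MPWM":
        return MPWM(
            self.name,
            self.kind,
            self.matrix.copy(),
            [g.copy() for g in self.groups],
            self.calibration,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MPWM):
            return NotImplemented
        return (
            self.name == other.name
            and self.kind == other.kind
            and self.matrix.shape == other.matrix.shape
            and bool(np.array_equal(self.matrix, other.matrix))
            and self.groups == other.groups
            and self.calibration == other.calibration
        )


def validate(model: MPWM) -> MPWM:
    """Check structural and kind invariants; return the model.

    Raises :class:`MPWMValidationError` on duplicate group positions,
    out-of-range positions, wrong table sizes, or values inconsistent
    with the declared kind (negative counts, frequencies outside [0,1]
    or not summing to 1 at independent positions, non-finite weights).
    """
    if model.kind not in KINDS:
        raise MPWMValidationError(f"unknown matrix kind {model.kind!r}")
    L = model.length
    if L < 1 or model.matrix.shape != (L, 4):
        raise MPWMValidationError("independent matrix must be L x 4 with L >= 1")
    if not np.all(np.isfinite(model.matrix)):
        raise MPWMValidationError("independent matrix contains non-finite values")

    seen: set[int] = set()
    for g in model.groups:
        if g.d not in (2, 3):
            raise MPWMValidationError(
                f"dependency group {g.positions}: d must be 2 or 3"
            )
        if len(set(g.positions)) != g.d:
            raise MPWMValidationError(
                f"dependency group {g.positions}: duplicate position"
            )
        for p in g.positions:
            if not (1 <= p <= L):
                raise MPWMValidationError(
                    f"dependency group {g.positions}: position {p} outside [1, {L}]"
                )
            if p in seen:
                raise MPWMValidationError(
                    f"duplicate position {p}: appears in more than one dependency group"
                )
            seen.add(p)
        expected = set(nt_tuples(g.d))
        if set(g.values) != expected:
            raise MPWMValidationError(
                f"dependency group {g.positions}: expected {4 ** g.d} tuple entries, "
                f"got {len(g.values)}"
            )
        vals = np.fromiter(g.values.values(), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise MPWMValidationError(
                f"dependency group {g.positions}: non-finite value"
            )

    indep = [p - 1 for p in model.independent_positions]
    if model.kind == "count":
        if np.any(model.matrix < 0):
            raise MPWMValidationError("count matrix has negative entries")
        for g in model.groups:
            if any(v < 0 for v in g.values.values()):
                raise MPWMValidationError(
                    f"dependency group {g.positions}: negative count"
                )
    elif model.kind == "frequency":
        if np.any(model.matrix < 0) or np.any(model.matrix > 1):
            raise MPWMValidationError("frequencies must lie in [0, 1]")
        sums = model.matrix[indep].sum(axis=1) if indep else np.empty(0)
        bad = np.nonzero(np.abs(sums - 1.0) > FREQ_SUM_TOL)[0]
        if bad.size:
            p = model.independent_positions[int(bad[0])]
            raise MPWMValidationError(
                f"frequencies at position {p} sum to {sums[bad[0]]:.8f}, not 1"
            )
        for g in model.groups:
            s = sum(g.values.values())
            if abs(s - 1.0) > FREQ_SUM_TOL:
                raise MPWMValidationError(
                    f"dependency group {g.positions}: tuple frequencies sum to "
                    f"{s:.8f}, not 1"
                )
    return model


# ---------------------------------------------------------------------------
# text format
# ---------------------------------------------------------------------------

def parse_mpwm(text: str) -> MPWM:
    """Parse an mPWM document into a validated :class:`MPWM`."""
    # (line_number, stripped_content) with comments and blanks removed
    lines: list[tuple[int, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        content = raw.split("#", 1)[0].strip()
        if content:
            lines.append((lineno, content))

    def parse_float(token: str, lineno: int, what: str) -> float:
        try:
            return float(token)
        except ValueError:
            raise MPWMParseError(
                f"line {lineno}: malformed numeric field {token!r} in {what}"
            ) from None

    name = "mpwm"
    kind: Optional[str] = None
    calib_fields: dict[str, float] = {}
    rows: list[list[float]] = []
    groups: list[DependencyGroup] = []

    i = 0
    n = len(lines)
    # headers
    while i < n:
        lineno, content = lines[i]
        if content.lower() == "matrix:":
            i += 1
            break
        if ":" not in content:
            raise MPWMParseError(f"line {lineno}: expected 'key: value' header, got {content!r}")
        key, _, value = content.partition(":")
        key = key.strip().lower()
        value = value.strip()
        if key == "name":
            name = value
        elif key == "type":
            if value not in KINDS:
                raise MPWMParseError(
                    f"line {lineno}: type must be one of {', '.join(KINDS)}, got {value!r}"
                )
            kind = value
        elif key in ("a", "b", "concentration"):
            calib_fields[key] = parse_float(value, lineno, f"header {key!r}")
        elif key == "dependency":
            raise MPWMParseError(f"line {lineno}: 'dependency:' block before 'matrix:' block")
        else:
            raise MPWMParseError(f"line {lineno}: unknown header {key!r}")
        i += 1
    else:
        raise MPWMParseError("document has no 'matrix:' block")

    if kind is None:
        raise MPWMParseError("document does not declare 'type:'")

    # independent matrix rows
    while i < n and not lines[i][1].lower().startswith("dependency:"):
        lineno, content = lines[i]
        fields = content.split()
        if len(fields) != 4:
            raise MPWMParseError(
                f"line {lineno}: matrix row must have 4 values (A C G T), got {len(fields)}"
            )
        rows.append([parse_float(f, lineno, "matrix row") for f in fields])
        i += 1
    if not rows:
        raise MPWMParseError("matrix block has no rows")

    # dependency blocks
    while i < n:
        lineno, content = lines[i]
        spec_str = content.partition(":")[2].strip()
        try:
            positions = tuple(int(tok) for tok in spec_str.split(","))
        except ValueError:
            raise MPWMParseError(
                f"line {lineno}: malformed position list {spec_str!r} in dependency header"
            ) from None
        d = len(positions)
        if d not in (2, 3):
            raise MPWMValidationError(
                f"line {lineno}: dependency group must have 2 or 3 positions, got {d}"
            )
        i += 1
        values: dict[str, float] = {}
        while i < n and not lines[i][1].lower().startswith("dependency:"):
            entry_lineno, entry = lines[i]
            fields = entry.split()
            if len(fields) != 2:
                raise MPWMParseError(
                    f"line {entry_lineno}: dependency entry must be '<tuple> <value>', got {entry!r}"
                )
            key = fields[0].upper()
            if len(key) != d or any(c not in NT_INDEX for c in key):
                raise MPWMValidationError(
                    f"line {entry_lineno}: bad nucleotide tuple {fields[0]!r} for a "
                    f"{d}-position group"
                )
            if key in values:
                raise MPWMValidationError(
                    f"line {entry_lineno}: duplicate tuple {key!r} in dependency block"
                )
            values[key] = parse_float(fields[1], entry_lineno, "dependency entry")
            i += 1
        if len(values) != 4 ** d:
            raise MPWMValidationError(
                f"dependency block at line {lineno}: expected {4 ** d} entries, got {len(values)}"
            )
        groups.append(DependencyGroup(positions, values))

    calibration: Optional[Calibration] = None
    if calib_fields:
        calibration = Calibration(
            a=calib_fields.get("a", 1.0),
            b=calib_fields.get("b", 0.0),
            concentration=calib_fields.get("concentration"),
        )

    return validate(MPWM(name, kind, np.array(rows, dtype=float), groups, calibration))


def write_mpwm(model: MPWM) -> str:
    """Serialize a model to the mPWM text format.

    Floats are written with Python's shortest round-trip repr, so
    ``parse_mpwm(write_mpwm(m)) == m`` exactly for any valid model.
    """
    validate(model)
    out: list[str] = [f"name: {model.name}", f"type: {model.kind}"]
    if model.calibration is not None:
        c = model.calibration
        out.append(f"a: {_fmt(c.a)}")
        out.append(f"b: {_fmt(c.b)}")
        if c.concentration is not None:
            out.append(f"concentration: {_fmt(c.concentration)}")
    out.append("matrix:")
    for row in model.matrix:
        out.append("\t".join(_fmt(v) for v in row))
    for g in model.groups:
        out.append("dependency: " + ",".join(str(p) for p in g.positions))
        for key in nt_tuples(g.d):
            out.append(f"{key}\t{_fmt(g.values[key])}")
    return "\n".join(out) + "\n"


def _fmt(v: float) -> str:
    return repr(float(v))


def load_mpwm(path) -> MPWM:
    """Read an mPWM file from ``path``."""
    with open(path, encoding="utf-8") as fh:
        return parse_mpwm(fh.read())


def save_mpwm(model: MPWM, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_mpwm(model))


# ---------------------------------------------------------------------------
# weight conversion and scoring
# ---------------------------------------------------------------------------

def weights_from_frequencies(model: MPWM) -> MPWM:
    """Convert a frequency model to weights, W = ln(f / f_max).

    Applied per independent position on nucleotide frequencies and per
    dependency group on tuple frequencies, so the maximum of every block
    is 0 and the best possible site scores 0. Rows of the weight matrix
    at group-covered positions are written as 0 (they are never scored).

    Zero frequencies are refused: smoothing is the builder's job (see
    ``frequencies_from_counts`` and its pseudocount).
    """
    validate(model)
    if model.kind != "frequency":
        raise MPWMError(f"expected a frequency model, got kind={model.kind!r}")
    W = np.zeros_like(model.matrix)
    indep = [p - 1 for p in model.independent_positions]
    for p in indep:
        row = model.matrix[p]
        if np.any(row <= 0):
            raise MPWMError(
                f"zero frequency at position {p + 1}: apply a pseudocount before "
                "converting to weights"
            )
        W[p] = np.log(row / row.max())
    new_groups: list[DependencyGroup] = []
    for g in model.groups:
        fmax = max(g.values.values())
        if any(v <= 0 for v in g.values.values()):
            raise MPWMError(
                f"zero tuple frequency in dependency group {g.positions}: apply a "
                "pseudocount before converting to weights"
            )
        new_groups.append(
            DependencyGroup(
                g.positions, {k: math.log(v / fmax) for k, v in g.values.items()}
            )
        )
    return MPWM(model.name, "weight", W, new_groups, model.calibration)


def score_window(model: MPWM, site: str) -> float:
    """Score one L-bp window: independent terms plus group tuple terms."""
    if model.kind != "weight":
        raise MPWMError(f"scoring requires a weight model, got kind={model.kind!r}")
    L = model.length
    if len(site) != L:
        raise MPWMError(f"site length {len(site)} does not match model length {L}")
    site = site.upper()
    try:
        idx = [NT_INDEX[c] for c in site]
    except KeyError as exc:
        raise MPWMError(f"site contains disallowed character {exc.args[0]!r}") from None
    score = 0.0
    for p in model.independent_positions:
        score += model.matrix[p - 1, idx[p - 1]]
    for g in model.groups:
        key = "".join(site[p - 1] for p in g.positions)
        score += g.values[key]
    return score


def max_score(model: MPWM) -> float:
    """Maximum attainable window score.

    Equals the sum of per-independent-position maxima plus per-group
    maxima, which is the max over all 4^L sites because the groups are
    position-disjoint. Zero for models from ``weights_from_frequencies``.
    """
    if model.kind != "weight":
        raise MPWMError(f"max_score requires a weight model, got kind={model.kind!r}")
    total = sum(float(model.matrix[p - 1].max()) for p in model.independent_positions)
    total += sum(max(g.values.values()) for g in model.groups)
    return total


def consensus_site(model: MPWM) -> str:
    """A site attaining ``max_score``: argmax nucleotide per independent
    position and argmax tuple per group (ties broken in A<C<G<T /
    lexicographic order)."""
    if model.kind != "weight":
        raise MPWMError("consensus_site requires a weight model")
    site = ["A"] * model.length
    for p in model.independent_positions:
        site[p - 1] = ALPHABET[int(np.argmax(model.matrix[p - 1]))]
    for g in model.groups:
        best = max(nt_tuples(g.d), key=lambda k: g.values[k])
        for p, c in zip(g.positions, best):
            site[p - 1] = c
    return "".join(site)


def revcomp_model(model: MPWM) -> MPWM:
    """The model that scores each site as the input scores its reverse
    complement.

    Position p maps to L+1-p with nucleotide columns complemented; each
    group's positions are mapped and re-sorted ascending and its table
    re-keyed by reverse-complemented tuples. An involution.
    """
    validate(model)
    L = model.length
    # complement = reverse nucleotide column order (A,C,G,T -> T,G,C,A)
    new_matrix = model.matrix[::-1, ::-1].copy()
    new_groups: list[DependencyGroup] = []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for g in model.groups:
        # ascending mapped positions visit the declared positions in
        # descending order; re-key each tuple along that permutation,
        # complementing every base
        order = sorted(range(g.d), key=lambda j: L + 1 - g.positions[j])
        mapped = tuple(L + 1 - g.positions[j] for j in order)
        new_values = {
            "".join(comp[k[j]] for j in order): v for k, v in g.values.items()
        }
        new_groups.append(DependencyGroup(mapped, new_values))
    return MPWM(model.name, model.kind, new_matrix, new_groups, model.calibration)
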