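"""Degenerate catalytic-center motif grammar and matcher.

Candidate guanylyl-cyclase (GC) catalytic centers inside larger proteins —
typically embedded in the kinase domain of leucine-rich-repeat receptor-like
kinases — can be flagged with a short degenerate pattern over amino-acid
classes.  This module implements a PROSITE-flavoured pattern dialect, a
sliding-window matcher with mismatch tolerance, per-position near-miss
diagnostics, the downstream [D/E] metal-binding rule, and a small built-in
catalog of GC-center patterns.

Pattern grammar
---------------
A pattern is a whitespace-separated (whitespace optional) sequence of tokens:

* ``[XYZ]`` — a residue class: the position accepts any listed residue.
* a single residue letter, e.g. ``G`` — a singleton class.
* ``x`` — a wildcard accepting any residue.
* any token may carry a repeat suffix ``(n)`` (exactly n copies) or
  ``(n,m)`` (n to m copies).

The canonical example is the 14-position GC catalytic-center motif::

    [RKS] [YFW] [GCTH] [VIL] [FV] x(3) [VIL] x(4) [KR]

Positions 1, 3 and 14 of that motif are functionally assigned: position 1
hydrogen-bonds the purine ring, position 3 sets GTP-vs-ATP substrate
specificity, and position 14 stabilizes the transition state from GTP to
cGMP.  An aspartate or glutamate two to three residues downstream of
position 14 coordinates the Mg2+/Mn2+ cofactor.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field, replace

import numpy as np

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

# Ambiguity/non-canonical codes (X, B, Z, J, U, O, *) never satisfy a class
# constraint; wildcards accept any alphabetic character.
_ALPHABET = frozenset(string.ascii_uppercase)

#: Functional-role labels for the GC core motif.
ROLE_H_BOND = "hydrogen-bond-with-guanine"
ROLE_SPECIFICITY = "substrate-specificity"
ROLE_TRANSITION_STATE = "transition-state-stabilization"

_GC_CORE_ROLES = {1: ROLE_H_BOND, 3: ROLE_SPECIFICITY, 14: ROLE_TRANSITION_STATE}

GC_CORE_STRICT_TEXT = "[RKS][YFW][GCTH][VIL][FV]x(3)[VIL]x(4)[KR]"
GC_CORE_MONOCOT_TEXT = "[RKS][YFW][GCTH][VIL][FV]x(3)[VIL]x(4)[KRM]"
_METAL_TAIL_TEXT = "x(1,2)[DE]"


class PatternError(ValueError):
    """Raised for a malformed pattern string.

    Carries the offending token text and its 0-based character offset.
    """

    def __init__(self, message: str, token: str, offset: int):
        super().__init__(f"{message} (token {token!r} at offset {offset})")
        self.token = token
        self.offset = offset


@dataclass(frozen=True)
class PositionConstraint:
    """One pattern token: a residue class or a wildcard, with a repeat count."""

    kind: str  # "class" | "wildcard"
    allowed: frozenset = frozenset()
    repeat_min: int = 1
    repeat_max: int = 1

    def __post_init__(self):
        if self.kind not in ("class", "wildcard"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if not (1 <= self.repeat_min <= self.repeat_max):
            raise ValueError(
                f"invalid repeat range ({self.repeat_min},{self.repeat_max})"
            )
        if self.kind == "class":
            if not self.allowed:
                raise ValueError("class constraint with empty allowed set")
            if not self.allowed <= CANONICAL_SET:
                bad = "".join(sorted(self.allowed - CANONICAL_SET))
                raise ValueError(f"non-canonical residues in class: {bad}")
        elif self.allowed:
            raise ValueError("wildcard constraint must have empty allowed set")

    @property
    def constrained(self) -> bool:
        return self.kind == "class"

    def satisfied_by(self, residue: str) -> bool:
        """Whether one residue satisfies this constraint.

        Non-canonical codes (X, B, Z, J, U, O, ``*``) never satisfy a class;
        a wildcard accepts any alphabetic character.
        """
        if self.kind == "wildcard":
            return residue in _ALPHABET
        return residue in self.allowed

    def render(self) -> str:
        if self.kind == "wildcard":
            body = "x"
        elif len(self.allowed) == 1:
            body = next(iter(self.allowed))
        else:
            body = "[" + "".join(sorted(self.allowed)) + "]"
        if self.repeat_min == self.repeat_max:
            return body if self.repeat_min == 1 else f"{body}({self.repeat_min})"
        return f"{body}({self.repeat_min},{self.repeat_max})"


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate pattern.

    ``functional_roles`` maps 1-based *expanded* position indices to role
    labels (e.g. position 14 of the GC core → transition-state
    stabilization).
    """

    name: str
    constraints: tuple
    functional_roles: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        for pos in self.functional_roles:
            if not (1 <= pos <= self.max_length):
                raise ValueError(f"functional role index {pos} outside pattern")

    @property
    def min_length(self) -> int:
        return sum(c.repeat_min for c in self.constraints)

    @property
    def max_length(self) -> int:
        return sum(c.repeat_max for c in self.constraints)

    @property
    def fixed_length(self) -> bool:
        return self.min_length == self.max_length

    def render(self) -> str:
        """Render back to pattern-grammar text (parses to an equal pattern)."""
        return "".join(c.render() for c in self.constraints)

    def expansions(self):
        """Yield every distinct fixed-length expansion.

        Each expansion is a tuple of single-position constraints obtained by
        choosing a concrete repeat count for every token.  Expansions whose
        per-position constraint sequences coincide (e.g. ``x(1,2)x(1,2)``
        repeat choices (1,2) and (2,1)) are yielded once.
        """
        seen = set()
        ranges = [range(c.repeat_min, c.repeat_max + 1) for c in self.constraints]
        for counts in itertools.product(*ranges):
            expanded = tuple(
                replace(c, repeat_min=1, repeat_max=1)
                for c, n in zip(self.constraints, counts)
                for _ in range(n)
            )
            if expanded not in seen:
                seen.add(expanded)
                yield expanded

    def expanded_positions(self):
        """Expanded constraints at minimal repeat counts (the sole expansion
        for fixed-length patterns)."""
        return tuple(
            replace(c, repeat_min=1, repeat_max=1)
            for c in self.constraints
            for _ in range(c.repeat_min)
        )

    def constrained_positions(self) -> tuple:
        """1-based expanded indices holding a class constraint (minimal
        expansion)."""
        return tuple(
            i + 1
            for i, c in enumerate(self.expanded_positions())
            if c.constrained
        )


@dataclass(frozen=True)
class PositionDiagnostic:
    index: int  # 1-based expanded position
    residue: str
    constrained: bool
    satisfied: bool


@dataclass(frozen=True)
class MatchDiagnostics:
    """Per-position pass/fail report for one window against one pattern."""

    window: str
    positions: tuple

    @property
    def mismatch_count(self) -> int:
        return sum(1 for p in self.positions if p.constrained and not p.satisfied)

    @property
    def n_constrained(self) -> int:
        return sum(1 for p in self.positions if p.constrained)

    @property
    def n_satisfied_constrained(self) -> int:
        return sum(1 for p in self.positions if p.constrained and p.satisfied)

    def mismatch_positions(self) -> tuple:
        """1-based expanded indices of violated constrained positions."""
        return tuple(
            p.index for p in self.positions if p.constrained and not p.satisfied
        )


@dataclass(frozen=True)
class MetalBindingResult:
    """Outcome of the downstream [D/E] metal-binding check."""

    found: bool
    offset: int | None = None  # 2 or 3 when found
    residue: str | None = None  # 'D' or 'E' when found


@dataclass
class MotifMatch:
    """A located motif occurrence; coordinates are 1-based inclusive."""

    seq_id: str
    start: int
    end: int
    pattern_name: str
    matched: str
    diagnostics: MatchDiagnostics
    metal: MetalBindingResult | None = None
    score: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _parse_repeat(text: str, i: int, token_start: int):
    """Parse an optional ``(n)`` / ``(n,m)`` suffix; returns (min, max, next_i)."""
    if i >= len(text) or text[i] != "(":
        return 1, 1, i
    close = text.find(")", i)
    if close < 0:
        raise PatternError("unterminated repeat suffix", text[i:], i)
    body = text[i + 1 : close]
    parts = body.split(",")
    token = text[token_start : close + 1]
    try:
        nums = [int(p.strip()) for p in parts]
    except ValueError:
        raise PatternError("non-integer repeat count", token, token_start) from None
    if len(nums) == 1:
        lo = hi = nums[0]
    elif len(nums) == 2:
        lo, hi = nums
    else:
        raise PatternError("repeat suffix takes one or two counts", token, token_start)
    if lo < 1:
        raise PatternError("zero or negative repeat count", token, token_start)
    if lo > hi:
        raise PatternError("repeat range has n > m", token, token_start)
    return lo, hi, close + 1


def parse_pattern(text: str, name: str = "user") -> MotifPattern:
    """Compile pattern-grammar text into a :class:`MotifPattern`.

    The grammar is case-insensitive and ignores whitespace between tokens.
    Raises :class:`PatternError` naming the offending token and character
    offset for malformed input.
    """
    if not text or not text.strip():
        raise PatternError("empty pattern", text, 0)
    src = text.upper()
    constraints = []
    i = 0
    while i < len(src):
        ch = src[i]
        if ch.isspace():
            i += 1
            continue
        token_start = i
        if ch == "[":
            close = src.find("]", i)
            if close < 0:
                raise PatternError("unterminated class", src[i:], i)
            body = src[i + 1 : close]
            token = src[i : close + 1]
            if not body:
                raise PatternError("empty class", token, token_start)
            bad = [c for c in body if c not in CANONICAL_SET]
            if bad:
                raise PatternError(
                    f"non-residue letter {bad[0]!r} in class", token, token_start
                )
            lo, hi, i = _parse_repeat(src, close + 1, token_start)
            constraints.append(
                PositionConstraint("class", frozenset(body), lo, hi)
            )
        elif ch == "X":
            lo, hi, i = _parse_repeat(src, i + 1, token_start)
            constraints.append(
                PositionConstraint("wildcard", frozenset(), lo, hi)
            )
        elif ch in CANONICAL_SET:
            lo, hi, i = _parse_repeat(src, i + 1, token_start)
            constraints.append(
                PositionConstraint("class", frozenset(ch), lo, hi)
            )
        else:
            raise PatternError(f"unexpected character {ch!r}", ch, token_start)
    return MotifPattern(name=name, constraints=tuple(constraints))


def builtin_catalog() -> dict:
    """The built-in GC catalytic-center patterns.

    * ``GC_CORE_STRICT`` — the 14-position core motif with [KR] at position 14.
    * ``GC_CORE_MONOCOT`` — the monocot expansion permitting methionine at
      position 14 ([KRM]), motivated by active monocot GCs that carry M there.
    * ``GC_FULL_STRICT`` / ``GC_FULL_MONOCOT`` — core followed by
      ``x(1,2)[DE]``, folding the downstream metal-binding residue into the
      pattern itself (total length 16-17).

    No adenylyl-cyclase pattern ships: AC centers differ from GC centers at
    position 3, but the AC residue classes there are not established; users
    can define one with :func:`parse_pattern`.
    """
    catalog = {}
    for name, text in (
        ("GC_CORE_STRICT", GC_CORE_STRICT_TEXT),
        ("GC_CORE_MONOCOT", GC_CORE_MONOCOT_TEXT),
        ("GC_FULL_STRICT", GC_CORE_STRICT_TEXT + _METAL_TAIL_TEXT),
        ("GC_FULL_MONOCOT", GC_CORE_MONOCOT_TEXT + _METAL_TAIL_TEXT),
    ):
        pat = parse_pattern(text, name=name)
        catalog[name] = replace(pat, functional_roles=dict(_GC_CORE_ROLES))
    return catalog


def diagnose_window(pattern: MotifPattern, window: str) -> MatchDiagnostics:
    """Evaluate one window against a fixed-length pattern, position by
    position.

    Wildcard positions are always reported satisfied; mismatches are counted
    only at constrained (class) positions.
    """
    if not pattern.fixed_length:
        raise ValueError(
            f"pattern {pattern.name!r} is variable-length "
            f"({pattern.min_length}-{pattern.max_length}); diagnose per expansion"
        )
    window = window.upper()
    expanded = pattern.expanded_positions()
    if len(window) != len(expanded):
        raise ValueError(
            f"window length {len(window)} != pattern length {len(expanded)}"
        )
    return _diagnose_expanded(expanded, window)


def _diagnose_expanded(expanded, window: str) -> MatchDiagnostics:
    positions = tuple(
        PositionDiagnostic(
            index=i + 1,
            residue=res,
            constrained=c.constrained,
            satisfied=True if not c.constrained else c.satisfied_by(res),
        )
        for i, (c, res) in enumerate(zip(expanded, window))
    )
    return MatchDiagnostics(window=window, positions=positions)


def _mismatch_counts_vectorized(expanded, seq: str) -> np.ndarray:
    """Mismatch count per window start (0-based) for one fixed-length
    expansion, via per-position 256-entry lookup tables."""
    length = len(expanded)
    n_windows = len(seq) - length + 1
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    counts = np.zeros(n_windows, dtype=np.int32)
    for offset, c in enumerate(expanded):
        if not c.constrained:
            continue
        bad = np.ones(256, dtype=bool)
        for r in c.allowed:
            bad[ord(r)] = False
        counts += bad[codes[offset : offset + n_windows]]
    return counts


def find_matches(
    pattern: MotifPattern,
    sequence: str,
    max_mismatch: int = 0,
    all_expansions: bool = False,
    seq_id: str = "",
) -> list:
    """Slide ``pattern`` over ``sequence`` and return every near-match.

    A window is reported when its mismatch count (violated class positions;
    wildcards never mismatch) is at most ``max_mismatch``.  For
    variable-length patterns the default reports, per start, only the
    shortest satisfying expansion; ``all_expansions=True`` reports every
    satisfying length.  Matches may overlap.  Output is sorted by
    (start, length); coordinates are 1-based inclusive.  ``metal`` and
    ``score`` are left unset (see :mod:`cyclasescan.scan`).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be non-negative")
    seq = sequence.upper()
    # (start0, length) -> (best mismatch count, expansion)
    best: dict = {}
    for expanded in pattern.expansions():
        length = len(expanded)
        if length > len(seq):
            continue
        counts = _mismatch_counts_vectorized(expanded, seq)
        for start0 in np.flatnonzero(counts <= max_mismatch):
            key = (int(start0), length)
            mm = int(counts[start0])
            if key not in best or mm < best[key][0]:
                best[key] = (mm, expanded)
    if not all_expansions:
        shortest: dict = {}
        for (start0, length) in sorted(best):
            if start0 not in shortest:
                shortest[start0] = length
        best = {
            k: v for k, v in best.items() if shortest.get(k[0]) == k[1]
        }
    matches = []
    for (start0, length) in sorted(best):
        _, expanded = best[(start0, length)]
        window = seq[start0 : start0 + length]
        matches.append(
            MotifMatch(
                seq_id=seq_id,
                start=start0 + 1,
                end=start0 + length,
                pattern_name=pattern.name,
                matched=window,
                diagnostics=_diagnose_expanded(expanded, window),
            )
        )
    return matches


def check_metal_binding(sequence: str, core_end: int) -> MetalBindingResult:
    """Apply the downstream metal-binding rule.

    Looks for an aspartate or glutamate at offset +2, then +3, after the
    1-based position ``core_end`` (expanded motif position 14).  The +2
    offset wins when both qualify.  Returns ``found=False`` when neither
    offset carries [D/E] or the sequence ends first.
    """
    if not (1 <= core_end <= len(sequence)):
        raise IndexError(
            f"core_end {core_end} outside sequence of length {len(sequence)}"
        )
    seq = sequence.upper()
    for offset in (2, 3):
        idx = core_end - 1 + offset
        if idx < len(seq) and seq[idx] in ("D", "E"):
            return MetalBindingResult(found=True, offset=offset, residue=seq[idx])
    return MetalBindingResult(found=False)


#: Score weights: constrained-position agreement dominates; the metal bonus
#: is small enough that a full core match without metal support (0.9) still
#: outranks any near-miss (≤ 0.9 × 6/7 + 0.1 ≈ 0.871).
SCORE_WEIGHT_CORE = 0.9
SCORE_WEIGHT_METAL = 0.1


def score_match(diag: MatchDiagnostics, metal: MetalBindingResult) -> float:
    """Candidate score in [0, 1]: fraction of satisfied constrained positions
    weighted 0.9, plus 0.1 when the downstream [D/E] metal residue is found."""
    n = diag.n_constrained
    frac = diag.n_satisfied_constrained / n if n else 1.0
    return SCORE_WEIGHT_CORE * frac + SCORE_WEIGHT_METAL * (1.0 if metal.found else 0.0)


def sample_realization(pattern: MotifPattern, seed) -> str:
    """Draw a random residue string satisfying ``pattern``.

    Repeat counts are uniform over their ranges, class positions uniform over
    their allowed sets, wildcards uniform over the 20 canonical residues.
    ``seed`` may be an int or a :class:`numpy.random.Generator`; the same
    integer seed always yields the same string.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for c in pattern.constraints:
        n = int(rng.integers(c.repeat_min, c.repeat_max + 1))
        if c.constrained:
            choices = sorted(c.allowed)
        else:
            choices = list(CANONICAL_RESIDUES)
        out.extend(choices[int(rng.integers(len(choices)))] for _ in range(n))
    return "".join(out)
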