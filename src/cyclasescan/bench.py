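"""Planted-motif benchmark: seeded synthetic proteomes with ground truth,
an independent brute-force oracle scanner, scan-evaluation metrics, and the
analytic per-window match probability under an i.i.d. background.

The generator emulates only the null features that matter for a degenerate
motif scanner — i.i.d. background residues and exact planted realizations —
and deliberately none of the structure of real proteomes (domain
architecture, homology, compositional bias).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .motif import (
    CANONICAL_RESIDUES,
    MotifPattern,
    PositionConstraint,
    builtin_catalog,
    sample_realization,
)
from .scan import CandidateTable, ProteinRecord


@dataclass(frozen=True)
class ProteomeSpec:
    """Recipe for one seeded synthetic proteome.

    ``plants`` lists (pattern name, total count) pairs: ``count`` motif
    realizations placed across the whole proteome at uniform non-overlapping
    positions in uniformly chosen sequences.
    """

    n_seqs: int
    length_mean: float
    length_sd: float = 0.0
    background_freqs: dict | None = None  # residue -> prob; None = uniform
    plants: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_seqs < 1:
            raise ValueError("n_seqs must be >= 1")
        if self.background_freqs is not None:
            total = sum(self.background_freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"background_freqs sum to {total}, not 1")


@dataclass(frozen=True)
class TruthEntry:
    seq_id: str
    start: int  # 1-based inclusive
    end: int
    pattern_name: str
    planted: str


@dataclass
class TruthTable:
    entries: list = field(default_factory=list)

    def __len__(self):
        return len(self.entries)


class PackingError(RuntimeError):
    """Planted instances could not be placed without overlap."""


def _background_arrays(spec: ProteomeSpec):
    letters = np.frombuffer(CANONICAL_RESIDUES.encode(), dtype=np.uint8)
    if spec.background_freqs is None:
        probs = np.full(20, 1.0 / 20)
    else:
        probs = np.array(
            [spec.background_freqs.get(r, 0.0) for r in CANONICAL_RESIDUES]
        )
        probs = probs / probs.sum()
    return letters, probs


def generate_proteome(spec: ProteomeSpec, patterns: dict | None = None):
    """Generate (records, truth) for a :class:`ProteomeSpec`.

    Background residues are i.i.d. from ``background_freqs``; each plant is
    a fresh :func:`sample_realization` overwriting a uniformly chosen
    non-overlapping window of a uniformly chosen sequence.  The same seed
    yields byte-identical output.  ``patterns`` supplies named patterns
    beyond the built-in catalog.
    """
    rng = np.random.default_rng(spec.seed)
    catalog = dict(builtin_catalog())
    if patterns:
        catalog.update(patterns)
    plant_patterns = []
    for name, count in spec.plants:
        if name not in catalog:
            raise KeyError(f"unknown pattern {name!r} in plants")
        plant_patterns.append((catalog[name], int(count)))

    min_len = max([1] + [p.max_length for p, _ in plant_patterns])

    letters, probs = _background_arrays(spec)
    n_digits = max(4, len(str(spec.n_seqs)))
    sequences = []
    for i in range(spec.n_seqs):
        length = int(round(rng.normal(spec.length_mean, spec.length_sd)))
        length = max(length, min_len, 1)
        codes = rng.choice(letters, size=length, p=probs)
        sequences.append(bytearray(codes.tobytes()))

    occupied = [[] for _ in range(spec.n_seqs)]  # list of (start0, end0excl)
    truth = TruthTable()
    for pattern, count in plant_patterns:
        for _ in range(count):
            planted = sample_realization(pattern, rng)
            placed = False
            for _attempt in range(1000):
                si = int(rng.integers(spec.n_seqs))
                seq = sequences[si]
                span = len(planted)
                if len(seq) < span:
                    continue
                start0 = int(rng.integers(len(seq) - span + 1))
                end0 = start0 + span
                if any(s < end0 and start0 < e for s, e in occupied[si]):
                    continue
                seq[start0:end0] = planted.encode()
                occupied[si].append((start0, end0))
                truth.entries.append(
                    TruthEntry(
                        seq_id=f"synth_{si + 1:0{n_digits}d}",
                        start=start0 + 1,
                        end=end0,
                        pattern_name=pattern.name,
                        planted=planted,
                    )
                )
                placed = True
                break
            if not placed:
                raise PackingError(
                    f"could not place a {pattern.name} realization without overlap"
                )
    records = [
        ProteinRecord(
            id=f"synth_{i + 1:0{n_digits}d}",
            description="synthetic background",
            sequence=seq.decode(),
        )
        for i, seq in enumerate(sequences)
    ]
    truth.entries.sort(key=lambda e: (e.seq_id, e.start))
    return records, truth


def write_truth_tsv(truth: TruthTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["seq_id", "start", "end", "pattern", "planted_seq"])
        for e in truth.entries:
            w.writerow([e.seq_id, e.start, e.end, e.pattern_name, e.planted])


def read_truth_tsv(path) -> TruthTable:
    truth = TruthTable()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            truth.entries.append(
                TruthEntry(
                    seq_id=row["seq_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    pattern_name=row["pattern"],
                    planted=row["planted_seq"],
                )
            )
    return truth


def brute_force_scan(
    pattern: MotifPattern,
    sequence: str,
    max_mismatch: int = 0,
    all_expansions: bool = False,
) -> list:
    """Literal enumeration oracle, independent of the production matcher.

    Recursively walks the token list from every start position, trying every
    repeat count and checking each constrained residue by set membership.
    Returns (start, end, mismatch_count) triples, 1-based inclusive, with
    the same per-start selection rules as ``find_matches``: minimal mismatch
    count per (start, end); only the shortest end per start unless
    ``all_expansions``.
    """
    seq = sequence.upper()
    tokens = pattern.constraints
    found: dict = {}  # (start0, end0excl) -> min mismatches

    def walk(start0: int, pos: int, tok_i: int, mism: int):
        if mism > max_mismatch:
            return
        if tok_i == len(tokens):
            key = (start0, pos)
            if key not in found or mism < found[key]:
                found[key] = mism
            return
        tok = tokens[tok_i]
        for n in range(tok.repeat_min, tok.repeat_max + 1):
            if pos + n > len(seq):
                break
            add = 0
            if tok.constrained:
                add = sum(1 for r in seq[pos : pos + n] if r not in tok.allowed)
            walk(start0, pos + n, tok_i + 1, mism + add)

    for start0 in range(len(seq) + 1):
        if start0 + pattern.min_length > len(seq):
            break
        walk(start0, start0, 0, 0)

    if not all_expansions:
        shortest: dict = {}
        for (s0, e0) in sorted(found):
            if s0 not in shortest:
                shortest[s0] = e0
        found = {k: v for k, v in found.items() if shortest[k[0]] == k[1]}
    return sorted((s0 + 1, e0, mm) for (s0, e0), mm in found.items())


@dataclass(frozen=True)
class EvaluationResult:
    sensitivity: float
    precision: float
    fp_per_window: float
    n_truth: int
    n_predicted: int
    n_recovered: int


def count_windows(records, patterns) -> int:
    """Total windows a scan examines: one per (record, pattern expansion,
    feasible start)."""
    total = 0
    for record in records:
        L = len(record.sequence)
        for pattern in patterns:
            for expanded in pattern.expansions():
                total += max(0, L - len(expanded) + 1)
    return total


def evaluate_predictions(
    predicted: CandidateTable, truth: TruthTable, n_windows: int
) -> EvaluationResult:
    """Sensitivity / precision / false positives per window.

    A truth entry counts as recovered only on an exact (seq_id, start, end)
    coordinate hit.  Predictions not matching any truth entry are false
    positives relative to the planted set (chance background matches should
    be screened with :func:`brute_force_scan` beforehand if they are to be
    excluded).
    """
    truth_keys = {(e.seq_id, e.start, e.end) for e in truth.entries}
    pred_keys = [
        (r.seq_id, r.match.start, r.match.end) for r in predicted.rows
    ]
    recovered = truth_keys & set(pred_keys)
    n_fp = sum(1 for k in pred_keys if k not in truth_keys)
    sensitivity = len(recovered) / len(truth_keys) if truth_keys else 1.0
    precision = (
        (len(pred_keys) - n_fp) / len(pred_keys) if pred_keys else 1.0
    )
    return EvaluationResult(
        sensitivity=sensitivity,
        precision=precision,
        fp_per_window=n_fp / n_windows if n_windows else 0.0,
        n_truth=len(truth_keys),
        n_predicted=len(pred_keys),
        n_recovered=len(recovered),
    )


def expected_match_probability(
    pattern: MotifPattern, background_freqs: dict | None = None
) -> float:
    """Analytic per-window exact-match probability under an i.i.d.
    background: product over constrained positions of the summed frequency
    of their allowed residues (wildcards contribute 1).  Fixed-length
    patterns only; compute per expansion for variable-length patterns.

    Arithmetic follows the frequency type: exact frequencies (e.g.
    :class:`fractions.Fraction`) give an exact probability."""
    if not pattern.fixed_length:
        raise ValueError(
            "variable-length pattern: compute the probability per expansion"
        )
    if background_freqs is None:
        background_freqs = {r: 1.0 / 20 for r in CANONICAL_RESIDUES}
    prob = 1
    for c in pattern.expanded_positions():
        if c.constrained:
            prob *= sum(background_freqs[r] for r in c.allowed if r in background_freqs)
    return prob


def random_pattern(rng: np.random.Generator, max_tokens: int = 8) -> MotifPattern:
    """Draw a small random pattern for oracle-equivalence testing.

    Mixes singleton/larger classes and wildcards; occasionally attaches
    fixed or variable repeat suffixes so variable-length patterns are
    exercised too.
    """
    n_tokens = int(rng.integers(2, max_tokens + 1))
    constraints = []
    for _ in range(n_tokens):
        lo = 1
        hi = 1
        roll = rng.random()
        if roll < 0.2:
            lo = hi = int(rng.integers(2, 4))
        elif roll < 0.4:
            lo = int(rng.integers(1, 3))
            hi = lo + int(rng.integers(1, 3))
        if rng.random() < 0.3:
            constraints.append(PositionConstraint("wildcard", frozenset(), lo, hi))
        else:
            k = int(rng.integers(1, 5))
            residues = rng.choice(list(CANONICAL_RESIDUES), size=k, replace=False)
            constraints.append(
                PositionConstraint("class", frozenset(residues.tolist()), lo, hi)
            )
    return MotifPattern(name="random", constraints=tuple(constraints))
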