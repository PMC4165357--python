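"""Assign read pairs to amplicon targets by primer-prefix matching.

Amplicon reads have fixed start and stop positions, so assignment (and,
downstream, duplicate marking) cannot use alignment coordinates.  Instead the
first 22 bases of Read 1 are compared with the reverse complement of each
target's downstream locus-specific primer, and the first 22 bases of Read 2
with each upstream primer, allowing up to ``max_dist`` Levenshtein edits
(default 2).  A pair is kept only when both mates match the same target
uniquely; all other outcomes are labelled and excluded downstream rather than
silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import edlib

from ._dna import revcomp
from .formats_io import TaggedReadPair, TargetDesign

PREFIX_LEN = 22
DEFAULT_MAX_DIST = 2
MIN_TRIMMED_LEN = 35  # trimmed reads must be strictly longer than this

UNASSIGNED = "UNASSIGNED"

ASSIGNED = "ASSIGNED"
NO_MATCH = "NO_MATCH"
CROSS_TARGET = "CROSS_TARGET"
AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class Assignment:
    """Outcome of matching one read pair against a design set.

    ``dist1`` / ``dist2`` are the edit distances of the Read 1 / Read 2
    prefixes to the winning target's comparison windows (-1 when no match
    within ``max_dist``).
    """

    read_id: str
    target_id: str
    dist1: int
    dist2: int
    status: str


def bounded_levenshtein(a: str, b: str, max_dist: int) -> int:
    """Levenshtein distance between ``a`` and ``b``, or -1 if > ``max_dist``.

    N in either string mismatches every base (edlib treats it as a distinct
    symbol, which is what an ambiguous base call deserves here).
    """
    return edlib.align(a, b, mode="NW", task="distance", k=max_dist)["editDistance"]


def match_prefix(
    prefix: str,
    candidates: Sequence[tuple[str, str]],
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[tuple[str, int]]:
    """All candidate targets within ``max_dist`` edits of a 22-base prefix.

    ``candidates`` is a sequence of ``(target_id, 22-base window)`` pairs.
    """
    if len(prefix) < PREFIX_LEN:
        raise ValueError(
            f"prefix of length {len(prefix)} is shorter than {PREFIX_LEN} bases"
        )
    prefix = prefix[:PREFIX_LEN]
    hits = []
    for target_id, window in candidates:
        d = bounded_levenshtein(prefix, window, max_dist)
        if d >= 0:
            hits.append((target_id, d))
    return hits


def _best_hit(hits: list[tuple[str, int]]) -> tuple[str | None, int, bool]:
    """(winning target or None, min distance, tie?) for a hit list."""
    if not hits:
        return None, -1, False
    dmin = min(d for _, d in hits)
    winners = [t for t, d in hits if d == dmin]
    return winners[0], dmin, len(winners) > 1


class TargetMatcher:
    """Precomputed 22-base comparison windows for a design set.

    Read 1 windows are the reverse complement of each downstream primer as it
    appears at the start of Read 1 (the first 22 sequenced bases); Read 2
    windows are the first 22 bases of each upstream primer.
    """

    def __init__(
        self,
        designs: Sequence[TargetDesign],
        max_dist: int = DEFAULT_MAX_DIST,
        validate_separation: bool = False,
    ):
        if not designs:
            raise ValueError("design set is empty")
        self.designs = {d.target_id: d for d in designs}
        self.max_dist = max_dist
        self.read1_windows = [
            (d.target_id, revcomp(d.downstream_primer)[:PREFIX_LEN]) for d in designs
        ]
        self.read2_windows = [
            (d.target_id, d.upstream_primer[:PREFIX_LEN]) for d in designs
        ]
        if validate_separation:
            self._check_separation()

    def _check_separation(self) -> None:
        # Windows mutually within max_dist make every read AMBIGUOUS; such a
        # design is unusable and is rejected outright.
        for name, windows in (("Read 1", self.read1_windows), ("Read 2", self.read2_windows)):
            for i in range(len(windows)):
                for j in range(i + 1, len(windows)):
                    d = bounded_levenshtein(windows[i][1], windows[j][1], self.max_dist)
                    if d >= 0:
                        raise ValueError(
                            f"{name} primer windows of targets {windows[i][0]} and "
                            f"{windows[j][0]} are within edit distance {d} <= "
                            f"{self.max_dist}; designs are not separable"
                        )

    def assign(self, pair: TaggedReadPair) -> Assignment:
        hits1 = match_prefix(pair.seq1, self.read1_windows, self.max_dist)
        hits2 = match_prefix(pair.seq2, self.read2_windows, self.max_dist)
        best1, d1, tie1 = _best_hit(hits1)
        best2, d2, tie2 = _best_hit(hits2)
        if best1 is None or best2 is None:
            return Assignment(pair.read_id, UNASSIGNED, d1, d2, NO_MATCH)
        if tie1 or tie2:
            return Assignment(pair.read_id, UNASSIGNED, d1, d2, AMBIGUOUS)
        if best1 != best2:
            return Assignment(pair.read_id, UNASSIGNED, d1, d2, CROSS_TARGET)
        return Assignment(pair.read_id, best1, d1, d2, ASSIGNED)


def assign_read_pair(
    pair: TaggedReadPair,
    designs: Sequence[TargetDesign],
    max_dist: int = DEFAULT_MAX_DIST,
) -> Assignment:
    """Assign one read pair; see :class:`TargetMatcher` for batch use."""
    return TargetMatcher(designs, max_dist).assign(pair)


def assign_stream(
    pairs: Iterable[TaggedReadPair],
    matcher: TargetMatcher,
) -> tuple[list[tuple[TaggedReadPair, Assignment]], dict[str, int]]:
    """Assign a stream of pairs; returns (pair, assignment) list and QC counts."""
    qc = {ASSIGNED: 0, NO_MATCH: 0, CROSS_TARGET: 0, AMBIGUOUS: 0}
    out = []
    for pair in pairs:
        a = matcher.assign(pair)
        qc[a.status] += 1
        out.append((pair, a))
    return out, qc


def trim_primers(
    pair: TaggedReadPair,
    target: TargetDesign,
    min_len: int = MIN_TRIMMED_LEN,
    orient: bool = True,
) -> TaggedReadPair | None:
    """Remove primer sequence from an assigned pair; None if a mate is too short.

    Read 1 begins with the reverse complement of the downstream primer and
    Read 2 with the upstream primer; those prefixes are removed, and each
    read is capped at the insert length so any 3' read-through into the
    opposite primer is trimmed too.  A mate whose trimmed length is not
    strictly greater than ``min_len`` (35 bases) fails QC and the pair is
    dropped.

    With ``orient=True`` (default) the trimmed Read 1 is reverse-complemented
    so both mates are reported in insert-forward coordinates: position ``i``
    of either trimmed read is insert position ``i`` (Read 2) or counts from
    the insert 5' end after re-orientation (Read 1 covers the insert 3' end,
    reported as forward-strand sequence ending at the last insert base).
    """
    ins_len = len(target.insert_seq)
    p1 = len(target.downstream_primer)
    p2 = len(target.upstream_primer)
    seq1, qual1 = pair.seq1[p1 : p1 + ins_len], pair.qual1[p1 : p1 + ins_len]
    seq2, qual2 = pair.seq2[p2 : p2 + ins_len], pair.qual2[p2 : p2 + ins_len]
    if len(seq1) <= min_len or len(seq2) <= min_len:
        return None
    if orient:
        seq1, qual1 = revcomp(seq1), qual1[::-1]
    return replace(pair, seq1=seq1, qual1=qual1, seq2=seq2, qual2=qual2)
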