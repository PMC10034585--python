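"""Compositional-bias detection and hard masking.

Detects low-complexity / compositionally biased tracts by optimal
ungapped local alignment of a sequence against an infinite homopolymer of
each residue type, and iteratively replaces the offending residues with X
until no tract scores above the threshold. This is the CAST family of
maskers; the working threshold throughout this package is 15 (in the
substitution matrix's score units), deliberately aggressive so that
FG-repeat and poly-amino-acid tracts of nucleoporin-like proteins are
removed before statistics-sensitive searching.

Masking is hard (X, which scores -1 in every search) rather than
lowercase soft-masking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import (AA_INDEX, AMINO_ACIDS, ProteinSequence,
                        SubstitutionMatrix)

DEFAULT_THRESHOLD = 15


@dataclass(frozen=True)
class BiasSegment:
    """A compositionally biased tract: the dominant residue type, its
    1-based inclusive interval, and the homopolymer alignment score."""

    residue_type: str
    start: int
    end: int
    score: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")
        if self.score <= 0:
            raise ValueError("segment score must be positive")


@dataclass(frozen=True)
class MaskedSequence:
    """A sequence with its biased positions replaced by X."""

    source: ProteinSequence
    masked_residues: str
    segments: tuple[BiasSegment, ...]
    threshold: int

    def to_sequence(self) -> ProteinSequence:
        return ProteinSequence(id=self.source.id, residues=self.masked_residues,
                               description=self.source.description,
                               taxon=self.source.taxon)


def _encode(residues: str) -> np.ndarray:
    return np.fromiter((AA_INDEX[c] for c in residues), dtype=np.intp,
                       count=len(residues))


def _best_segments(enc: np.ndarray, matrix: SubstitutionMatrix):
    """Per residue type: maximal-subarray score, 0-based start, 0-based end.

    Maximum-scoring contiguous segment of per-position scores
    matrix(type, seq_i), via the cumulative-sum formulation. Deterministic
    tie-break: smallest end, then smallest start (leftmost-maximal).
    """
    S = matrix.scores[:20][:, enc]  # (20, n)
    cs = np.cumsum(S, axis=1)
    prefix = np.concatenate([np.zeros((20, 1), dtype=cs.dtype), cs[:, :-1]], axis=1)
    pref_min = np.minimum.accumulate(prefix, axis=1)
    vals = cs - pref_min
    scores = vals.max(axis=1)
    ends = vals.argmax(axis=1)  # first maximal end
    starts = np.empty(20, dtype=np.intp)
    for a in range(20):
        starts[a] = int(np.argmin(prefix[a, : ends[a] + 1]))  # first minimal prefix
    return scores, starts, ends


def homopolymer_bias_score(seq: str, residue: str,
                           matrix: SubstitutionMatrix) -> tuple[int, tuple[int, int] | None]:
    """Maximal-scoring segment of ``seq`` against a homopolymer of ``residue``.

    Per-position score is matrix(residue, seq[i]); the optimum is the
    classic maximum-scoring contiguous subsequence. Returns
    (score, (start, end)) with 1-based inclusive coordinates, or
    (0, None) when no positive segment exists. Ties resolve to the
    segment with the smallest end, then the smallest start.
    """
    if not seq:
        raise ValueError("empty sequence")
    enc = _encode(seq.upper())
    scores, starts, ends = _best_segments(enc, matrix)
    a = AA_INDEX[residue]
    if scores[a] <= 0:
        return 0, None
    return int(scores[a]), (int(starts[a]) + 1, int(ends[a]) + 1)


def mask_compositional_bias(seq: ProteinSequence, matrix: SubstitutionMatrix,
                            threshold: int = DEFAULT_THRESHOLD) -> MaskedSequence:
    """Iteratively mask the sequence's compositionally biased tracts.

    Each round scores all 20 residue types against the current (partially
    masked) residues; if the best tract scores above the threshold, the
    occurrences of that residue type inside the tract become X and the
    round repeats. Ties on score break alphabetically. Stops when the best
    tract score is <= threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    enc = _encode(seq.residues)
    x = AA_INDEX["X"]
    segments: list[BiasSegment] = []
    while True:
        scores, starts, ends = _best_segments(enc, matrix)
        # Highest score first, alphabetical tie-break; a tract only counts
        # if it actually contains its residue type (guarantees progress).
        order = np.lexsort((np.arange(20), -scores))
        chosen = -1
        for a in order:
            if scores[a] <= threshold:
                break
            if np.any(enc[starts[a] : ends[a] + 1] == a):
                chosen = int(a)
                break
        if chosen < 0:
            break
        a = chosen
        start, end = int(starts[a]), int(ends[a])
        span = enc[start : end + 1]
        span[span == a] = x
        segments.append(BiasSegment(residue_type=AMINO_ACIDS[a], start=start + 1,
                                    end=end + 1, score=int(scores[a])))
    masked = "".join(AMINO_ACIDS[i] if i < 20 else "X" for i in enc)
    return MaskedSequence(source=seq, masked_residues=masked,
                          segments=tuple(segments), threshold=threshold)


def mask_db(seqs, matrix: SubstitutionMatrix,
            threshold: int = DEFAULT_THRESHOLD) -> list[MaskedSequence]:
    """Mask every sequence of an iterable; convenience for proteome runs."""
    return [mask_compositional_bias(s, matrix, threshold) for s in seqs]


def segments_tsv(masked: list[MaskedSequence]) -> str:
    """Biased-tract report: seq_id, residue, start, end, score (TSV)."""
    lines = ["seq_id\tresidue\tstart\tend\tscore"]
    for m in masked:
        for s in m.segments:
            lines.append(f"{m.source.id}\t{s.residue_type}\t{s.start}\t{s.end}\t{s.score}")
    return "\n".join(lines) + "\n"
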