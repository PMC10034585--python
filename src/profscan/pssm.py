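"""Family PSSM construction from curated homolog sets.

A family profile is built in master coordinates: every member is aligned
to a designated representative (master) by local affine-gap alignment,
best HSP only; member residues land in master-indexed columns and
insertions relative to the master are dropped (counted for diagnostics).
Columns are then summarised into position-specific scores via
Henikoff position-based sequence weighting, pseudocount-mixed
frequencies (Altschul mixture, alpha = N_c - 1, beta = 10) and
integer-scaled log-odds in half-bit units.

The exported ASCII PSSM is this package's central artifact; searching it
against proteomes is the job of :mod:`profscan.search`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _dp
from .sequences import (AA_INDEX, ALPHABET, AMINO_ACIDS, ProteinSequence,
                        SubstitutionMatrix)

logger = logging.getLogger("profscan")

#: Half-bit integer score scale, the classic ASCII-PSSM convention.
HALF_BIT = math.log(2) / 2.0
#: Default gapped Karlin-Altschul statistics for half-bit scores with
#: gap penalties 11/1 (the published BLOSUM62 11/1 gapped values).
DEFAULT_GAPPED_LAMBDA = 0.267
DEFAULT_GAPPED_K = 0.041
#: Most-negative exported score (log-odds of an unobserved residue).
MIN_SCORE = -32

GAP = -1  # within the aligned span, deleted relative to member
NOT_COVERED = -2  # outside the member's aligned span


@dataclass
class FamilySeedSet:
    """A curated set of homologs defining one protein family.

    ``master_id`` names the representative sequence whose coordinates
    anchor the profile. ``inclusion_evalue`` is the family-specific
    admission threshold used during harvesting (repeat-rich families get
    more stringent values). One entry may represent two subunit names
    (note the shared-gene case of certain nucleoporins, e.g. a single
    polypeptide cleaved into two subunits); record that in ``notes``.
    """

    family: str
    members: list[ProteinSequence]
    master_id: str
    inclusion_evalue: float = 1e-5
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.family}: family has no members")
        if self.master_id not in {m.id for m in self.members}:
            raise ValueError(f"{self.family}: master {self.master_id!r} not a member")
        if self.inclusion_evalue < 0:
            raise ValueError("inclusion_evalue must be >= 0")

    @property
    def master(self) -> ProteinSequence:
        for m in self.members:
            if m.id == self.master_id:
                return m
        raise AssertionError


@dataclass
class PairwiseAlignment:
    """Best local alignment of a member against the master.

    Coordinates are 1-based inclusive; ``columns`` maps each aligned
    master position (1-based) to the member residue index (0..20) or GAP.
    ``insertions`` counts member residues falling between master columns
    (dropped from the profile). score 0 means an empty alignment.
    """

    score: int
    master_start: int = 0
    master_end: int = 0
    member_start: int = 0
    member_end: int = 0
    columns: dict[int, int] = field(default_factory=dict)
    insertions: int = 0

    @property
    def empty(self) -> bool:
        return self.score <= 0


def _sequence_profile(seq: ProteinSequence, matrix: SubstitutionMatrix) -> np.ndarray:
    """A sequence as an (L, 21) position-score matrix (its matrix rows)."""
    return np.ascontiguousarray(matrix.scores[seq.encoded().astype(np.intp)],
                                dtype=np.int32)


def align_to_master(master: ProteinSequence, member: ProteinSequence,
                    matrix: SubstitutionMatrix, gap_open: int = 11,
                    gap_extend: int = 1) -> PairwiseAlignment:
    """Optimal Smith-Waterman local alignment of member to master.

    Affine gaps (cost open + k*extend), best-scoring HSP only, with the
    deterministic tie-breaks of the DP kernel. An all-X member yields an
    empty alignment (score 0) with a warning.
    """
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    profile = _sequence_profile(master, matrix)
    subject = member.encoded()
    score, qs, qe, ss, se, qpath, spath = _dp.sw_traceback(
        profile, subject, gap_open, gap_extend)
    if score <= 0:
        if set(member.residues) == {"X"}:
            logger.warning("%s: member is entirely masked (all X)", member.id)
        return PairwiseAlignment(score=0)
    columns: dict[int, int] = {}
    insertions = 0
    for q, s in zip(qpath, spath):
        if q >= 0 and s >= 0:
            columns[int(q) + 1] = int(subject[s])
        elif q >= 0:
            columns[int(q) + 1] = GAP
        else:
            insertions += 1
    return PairwiseAlignment(score=int(score), master_start=qs + 1,
                             master_end=qe + 1, member_start=ss + 1,
                             member_end=se + 1, columns=columns,
                             insertions=insertions)


@dataclass
class MasterSlaveMSA:
    """Multiple alignment in master coordinates.

    ``rows[member_id]`` is an int8 array of length L: residue index
    (0..19), 20 for X, GAP (-1) inside the aligned span, NOT_COVERED (-2)
    outside it. The master's own row is gap-free and equals its residues.
    Insertions relative to the master are only recorded as counts.
    """

    master: ProteinSequence
    member_ids: list[str]
    rows: dict[str, np.ndarray]
    insertion_counts: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.master)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    def coverage_sets(self) -> list[frozenset]:
        """Per column, the set of members whose aligned span covers it."""
        out = []
        for c in range(self.length):
            out.append(frozenset(m for m in self.member_ids
                                 if self.rows[m][c] != NOT_COVERED))
        return out


def build_msa(seeds: FamilySeedSet, matrix: SubstitutionMatrix,
              gap_open: int = 11, gap_extend: int = 1,
              min_coverage: float = 0.5) -> MasterSlaveMSA:
    """Align every member to the master and stack rows in master coordinates.

    Members whose best HSP covers less than ``min_coverage`` of the
    master are excluded with a log entry (weak fragments must not dilute
    the columns). Raises on a degenerate family with no surviving member.
    """
    master = seeds.master
    L = len(master)
    member_ids: list[str] = []
    rows: dict[str, np.ndarray] = {}
    insertion_counts: dict[str, int] = {}
    for member in seeds.members:
        if member.id == master.id and set(master.residues) != {"X"}:
            aln = PairwiseAlignment(
                score=0, master_start=1, master_end=L, member_start=1,
                member_end=L,
                columns={i + 1: int(v) for i, v in enumerate(master.encoded())})
            aln.score = 1  # self row is always kept
        else:
            aln = align_to_master(master, member, matrix, gap_open, gap_extend)
        if aln.empty:
            logger.info("%s/%s: no alignment to master, excluded",
                        seeds.family, member.id)
            continue
        covered = aln.master_end - aln.master_start + 1
        if covered < min_coverage * L:
            logger.info("%s/%s: HSP covers %d/%d of master (< %.0f%%), excluded",
                        seeds.family, member.id, covered, L, 100 * min_coverage)
            continue
        row = np.full(L, NOT_COVERED, dtype=np.int8)
        row[aln.master_start - 1 : aln.master_end] = GAP
        for pos, code in aln.columns.items():
            if code != GAP:
                row[pos - 1] = code
        member_ids.append(member.id)
        rows[member.id] = row
        insertion_counts[member.id] = aln.insertions
    if not member_ids:
        raise ValueError(f"{seeds.family}: degenerate family, no member "
                         f"survives the coverage filter")
    return MasterSlaveMSA(master=master, member_ids=member_ids, rows=rows,
                          insertion_counts=insertion_counts)


def position_based_weights(msa: MasterSlaveMSA) -> dict[str, float]:
    """Henikoff position-based member weights, normalised to sum 1.

    In a column with r distinct residue types where s members share a
    type, each of those members collects 1/(r*s); a member's weight is
    the mean of its contributions over the columns where it has a
    residue. X and gaps contribute nothing.
    """
    sums = {m: 0.0 for m in msa.member_ids}
    counts = {m: 0 for m in msa.member_ids}
    for c in range(msa.length):
        col = {m: int(msa.rows[m][c]) for m in msa.member_ids
               if 0 <= msa.rows[m][c] < 20}
        if not col:
            continue
        type_counts: dict[int, int] = {}
        for code in col.values():
            type_counts[code] = type_counts.get(code, 0) + 1
        r = len(type_counts)
        for m, code in col.items():
            sums[m] += 1.0 / (r * type_counts[code])
            counts[m] += 1
    weights = {m: (sums[m] / counts[m]) if counts[m] else 0.0
               for m in msa.member_ids}
    total = sum(weights.values())
    if total <= 0:  # degenerate: all rows masked; fall back to uniform
        return {m: 1.0 / msa.n_members for m in msa.member_ids}
    return {m: w / total for m, w in weights.items()}


def _distinct_types(msa: MasterSlaveMSA) -> np.ndarray:
    """Distinct residue types per column (X/gaps excluded), minimum 1."""
    out = np.ones(msa.length, dtype=float)
    for c in range(msa.length):
        types = {int(msa.rows[m][c]) for m in msa.member_ids
                 if 0 <= msa.rows[m][c] < 20}
        out[c] = max(1, len(types))
    return out


def _block_bounds(msa: MasterSlaveMSA) -> list[tuple[int, int]]:
    """Per column, the (start, end) of its alignment block: the maximal
    contiguous run of columns covered by the same member set."""
    cov = msa.coverage_sets()
    bounds: list[tuple[int, int]] = [None] * msa.length  # type: ignore
    start = 0
    for c in range(1, msa.length + 1):
        if c == msa.length or cov[c] != cov[start]:
            for i in range(start, c):
                bounds[i] = (start, c - 1)
            start = c
    return bounds


def effective_observations(msa: MasterSlaveMSA, column: int) -> float:
    """Effective observation count N_c for a column (0-based index).

    The mean number of distinct residue types per column over the
    alignment block containing the column (never below 1); drives the
    pseudocount mix through alpha = N_c - 1.
    """
    if not 0 <= column < msa.length:
        raise IndexError(column)
    counts = _distinct_types(msa)
    s, e = _block_bounds(msa)[column]
    return float(counts[s : e + 1].mean())


def pseudo_frequencies(observed: np.ndarray, matrix: SubstitutionMatrix,
                       alpha: float, beta: float) -> np.ndarray:
    """Altschul pseudocount mixture Q = (alpha*f + beta*g) / (alpha+beta).

    g is the matrix-derived target distribution
    g_a ∝ sum_b f_b * p_a * exp(lambda_u * s_ab), normalised to sum 1.
    """
    if alpha < 0 or beta < 0 or alpha + beta <= 0:
        raise ValueError("need alpha, beta >= 0 with alpha + beta > 0")
    f = np.asarray(observed, dtype=float)
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("observed frequencies must sum to 1")
    p = matrix.background_freqs
    lam = matrix.ungapped_lambda
    S = matrix.scores[:20, :20].astype(float)
    g = p * (np.exp(lam * S) @ f)
    g /= g.sum()
    q = (alpha * f + beta * g) / (alpha + beta)
    return q / q.sum()


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class PSSM:
    """A family position-specific scoring matrix.

    ``scores`` are integer log-odds in units of ``scale_lambda`` nats
    (half-bits by default); ``stats_lambda``/``gapped_K`` are the gapped
    Karlin-Altschul parameters used to turn raw alignment scores into bit
    scores and E-values (composition-based statistics rescale
    ``stats_lambda`` per subject at search time).
    """

    family: str
    length: int
    consensus: str
    scores: np.ndarray  # (L, 20) int
    weighted_freqs: np.ndarray  # (L, 20)
    background_freqs: np.ndarray  # (20,)
    scale_lambda: float = HALF_BIT
    stats_lambda: float = DEFAULT_GAPPED_LAMBDA
    gapped_K: float = DEFAULT_GAPPED_K
    gap_open: int = 11
    gap_extend: int = 1
    pseudocount_beta: float = 10.0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int32)
        self.weighted_freqs = np.asarray(self.weighted_freqs, dtype=float)
        self.background_freqs = np.asarray(self.background_freqs, dtype=float)
        if self.scores.shape != (self.length, 20):
            raise ValueError("scores shape mismatch")
        if len(self.consensus) != self.length:
            raise ValueError("consensus length mismatch")

    def search_profile(self) -> np.ndarray:
        """(L, 21) int32 score matrix for the DP kernel; X scores -1."""
        out = np.full((self.length, 21), -1, dtype=np.int32)
        out[:, :20] = self.scores
        return out

    def row_normalization(self) -> np.ndarray:
        """Per row, sum_a p_a * exp(scale_lambda * s_a); ~1 up to integer
        rounding (the type invariant allows [0.8, 1.25])."""
        return (self.background_freqs[None, :]
                * np.exp(self.scale_lambda * self.scores)).sum(axis=1)

    def relative_entropy(self) -> float:
        """Mean per-column relative entropy H of the implied target
        frequencies vs background, in nats; drives the BLAST-style
        effective-length correction."""
        lam = self.stats_lambda
        w = self.background_freqs[None, :] * np.exp(lam * self.scores)
        z = w.sum(axis=1, keepdims=True)
        q = w / z
        h = (q * lam * self.scores).sum(axis=1).mean()
        return float(max(h, 0.01))


def pssm_from_msa(msa: MasterSlaveMSA, matrix: SubstitutionMatrix,
                  family: str | None = None, beta: float = 10.0,
                  scale: float = HALF_BIT, gap_open: int = 11,
                  gap_extend: int = 1,
                  stats_lambda: float | None = None) -> PSSM:
    """Summarise a master-slave MSA into an integer PSSM.

    Per column: Henikoff-weighted observed frequencies -> pseudocount mix
    with alpha = N_c - 1 (N_c = effective observations of the column's
    block) -> s_a = round(log(Q_a / p_a) / scale), half away from zero.
    Columns with zero residue coverage fall back to the substitution
    matrix row of the master residue, with a warning.
    """
    weights = position_based_weights(msa)
    counts = _distinct_types(msa)
    bounds = _block_bounds(msa)
    p = matrix.background_freqs
    L = msa.length
    scores = np.zeros((L, 20), dtype=np.int32)
    freqs = np.zeros((L, 20), dtype=float)
    master_codes = msa.master.encoded()
    fallback = 0
    for c in range(L):
        obs = np.zeros(20)
        total = 0.0
        for m in msa.member_ids:
            code = int(msa.rows[m][c])
            if 0 <= code < 20:
                obs[code] += weights[m]
                total += weights[m]
        if total <= 0:
            code = int(master_codes[c])
            scores[c] = matrix.scores[code, :20]
            freqs[c] = p
            fallback += 1
            continue
        obs /= total
        s, e = bounds[c]
        n_c = float(counts[s : e + 1].mean())
        alpha = n_c - 1.0
        if alpha + beta > 0:
            q = pseudo_frequencies(obs, matrix, alpha=alpha, beta=beta)
        else:  # beta = 0 on a fully conserved block: keep raw observations
            q = obs
        freqs[c] = q
        with np.errstate(divide="ignore"):
            raw = np.log(q / p) / scale
        raw[~np.isfinite(raw)] = MIN_SCORE
        scores[c] = np.clip(_round_half_away(raw), MIN_SCORE, None).astype(np.int32)
    if fallback:
        logger.warning("%s: %d column(s) without coverage fell back to "
                       "matrix scores", family or msa.master.id, fallback)
    if stats_lambda is None:
        stats_lambda = DEFAULT_GAPPED_LAMBDA * scale / HALF_BIT
    return PSSM(family=family or msa.master.id, length=L,
                consensus=msa.master.residues, scores=scores,
                weighted_freqs=freqs, background_freqs=p.copy(),
                scale_lambda=scale, stats_lambda=stats_lambda,
                gapped_K=DEFAULT_GAPPED_K, gap_open=gap_open,
                gap_extend=gap_extend, pseudocount_beta=beta)


def build_family_pssm(seeds: FamilySeedSet, matrix: SubstitutionMatrix,
                      **kwargs) -> PSSM:
    """Convenience: build_msa then pssm_from_msa, named after the family."""
    msa = build_msa(seeds, matrix,
                    gap_open=kwargs.get("gap_open", 11),
                    gap_extend=kwargs.get("gap_extend", 1),
                    min_coverage=kwargs.pop("min_coverage", 0.5))
    return pssm_from_msa(msa, matrix, family=seeds.family, **kwargs)


# --- ASCII serialisation -------------------------------------------------

_FORMAT_VERSION = 1


def write_pssm(pssm: PSSM, path: str | Path) -> None:
    """Write the ASCII PSSM format (bit-exact round-trip with read_pssm).

    Header lines carry the family, length, statistics and gap penalties;
    each row holds the 1-based position, consensus residue, 20 integer
    scores and 20 frequencies at 4 decimals, tab-separated.
    """
    lines = [
        f"# profscan-pssm v{_FORMAT_VERSION}",
        f"# family:{pssm.family}",
        f"# length:{pssm.length}",
        f"# lambda:{pssm.scale_lambda!r}",
        f"# stats_lambda:{pssm.stats_lambda!r}",
        f"# K:{pssm.gapped_K!r}",
        f"# gap:{pssm.gap_open},{pssm.gap_extend}",
        f"# beta:{pssm.pseudocount_beta!r}",
        "# background:" + ",".join(repr(float(v)) for v in pssm.background_freqs),
        "# columns: pos consensus " + " ".join(AMINO_ACIDS) + " freqs...",
    ]
    for i in range(pssm.length):
        row = [str(i + 1), pssm.consensus[i]]
        row += [str(int(v)) for v in pssm.scores[i]]
        row += [f"{v:.4f}" for v in pssm.weighted_freqs[i]]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_pssm(path: str | Path) -> PSSM:
    """Parse the ASCII PSSM format written by :func:`write_pssm`."""
    text = Path(path).read_text()
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        rows.append(line.split("\t"))
    try:
        family = meta["family"]
        length = int(meta["length"])
        scale_lambda = float(meta["lambda"])
        stats_lambda = float(meta.get("stats_lambda", DEFAULT_GAPPED_LAMBDA))
        K = float(meta["K"])
        gap_open, gap_extend = (int(v) for v in meta["gap"].split(","))
        beta = float(meta.get("beta", 10.0))
        background = np.array([float(v) for v in meta["background"].split(",")])
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{path}: malformed or truncated PSSM header") from exc
    if text.splitlines()[0] != f"# profscan-pssm v{_FORMAT_VERSION}":
        raise ValueError(f"{path}: unknown PSSM format version")
    if len(rows) != length:
        raise ValueError(f"{path}: header says {length} rows, found {len(rows)}")
    consensus = []
    scores = np.zeros((length, 20), dtype=np.int32)
    freqs = np.zeros((length, 20), dtype=float)
    for i, row in enumerate(rows):
        if len(row) != 42:
            raise ValueError(f"{path}: row {i + 1}: expected 42 fields, got {len(row)}")
        if int(row[0]) != i + 1:
            raise ValueError(f"{path}: row {i + 1}: position index mismatch")
        consensus.append(row[1])
        scores[i] = [int(v) for v in row[2:22]]
        freqs[i] = [float(v) for v in row[22:42]]
    return PSSM(family=family, length=length, consensus="".join(consensus),
                scores=scores, weighted_freqs=freqs, background_freqs=background,
                scale_lambda=scale_lambda, stats_lambda=stats_lambda,
                gapped_K=K, gap_open=gap_open, gap_extend=gap_extend,
                pseudocount_beta=beta)
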