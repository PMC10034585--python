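"""Proteome scanning with a PSSM.

Exhaustive position-specific Smith-Waterman with affine gaps over every
subject (no seeding heuristics — full dynamic programming at desk
scale), Karlin-Altschul bit scores and E-values with a BLAST-style
effective-length correction, an optional per-subject composition-based
rescaling of lambda, and ranked hit lists in the 12-column BLAST tabular
dialect (qseqid sseqid pident length mismatch gapopen qstart qend sstart
send evalue bitscore).

The composition-based statistics implemented here are an explicit
dialect, not a bit-exact clone of any BLAST mode: the subject's residue
composition q (pseudocount 1 per residue) replaces the background in the
profile's partition identity and lambda is re-solved so that a subject
of background composition keeps the global lambda exactly; subjects
enriched in high-scoring residues get a smaller lambda and hence lower
bit scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _dp
from .pssm import PSSM
from .sequences import ALPHABET, ProteinSequence, SequenceDB

logger = logging.getLogger("profscan")

LN2 = math.log(2)

#: Minimum subject length for composition-based rescaling; shorter
#: subjects have too noisy a composition estimate and keep the global lambda.
CBS_MIN_LENGTH = 30


@dataclass
class HSP:
    """One profile-vs-subject high-scoring segment pair.

    Query coordinates are 1-based PSSM positions, subject coordinates
    1-based residue positions (0 = coordinates unavailable, e.g. hits
    ingested from coordinate-free summary formats).
    """

    family: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    raw_score: int
    bit_score: float
    evalue: float
    identity_fraction: float = 0.0
    align_length: int = 0
    mismatches: int = 0
    gap_openings: int = 0

    def __post_init__(self) -> None:
        if self.query_end < self.query_start or self.subject_end < self.subject_start:
            raise ValueError("HSP end before start")
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass
class HitTable:
    """Ranked hits of one profile against one proteome."""

    family: str
    proteome_id: str
    hits: list[HSP] = field(default_factory=list)
    search_space: tuple[int, int, int] = (0, 0, 0)  # (m, db residues, db seqs)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def subject_ids(self) -> list[str]:
        return [h.subject_id for h in self.hits]


def bit_score(raw: int, lam: float, K: float) -> float:
    """Karlin-Altschul normalised score S' = (lambda*S - ln K) / ln 2."""
    if lam <= 0 or K <= 0:
        raise ValueError("lambda and K must be positive")
    return (lam * raw - math.log(K)) / LN2


def evalue(bit: float, m: int, n: int) -> float:
    """Expected chance hits E = m * n * 2^(-S')."""
    if m <= 0 or n <= 0:
        raise ValueError("search space must be positive")
    return float(m) * float(n) * math.pow(2.0, -bit)


def effective_search_space(pssm: PSSM, db_residues: int, db_seqs: int) -> tuple[int, int]:
    """BLAST-style edge correction: subtract the expected HSP length
    l = floor(ln(K*m*n) / H) from the profile and from every subject."""
    m = pssm.length
    H = pssm.relative_entropy()
    kmn = pssm.gapped_K * m * db_residues
    ell = int(math.log(kmn) / H) if kmn > 1 else 0
    m_eff = max(1, m - ell)
    n_eff = max(db_seqs, db_residues - db_seqs * ell)
    return m_eff, n_eff


def _composition_from_enc(enc: np.ndarray) -> np.ndarray:
    counts = np.bincount(enc[enc < 20], minlength=20).astype(float) + 1.0
    return counts / counts.sum()


def _composition(subject: ProteinSequence) -> np.ndarray:
    """Subject residue composition over the 20 amino acids, one
    pseudocount per residue; X positions are ignored."""
    return _composition_from_enc(subject.encoded())


def _score_histogram(pssm: PSSM) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue histogram of profile scores: values v and (20, |v|)
    matrix C with C[a, k] = fraction of positions scoring v_k for residue
    a. Lets the CBS partition g(lambda) = sum_a q_a sum_k C[a,k] e^(lambda v_k)
    be evaluated cheaply at many lambdas."""
    values = np.arange(pssm.scores.min(), pssm.scores.max() + 1)
    C = np.zeros((20, values.size))
    for a in range(20):
        idx = pssm.scores[:, a] - values[0]
        np.add.at(C[a], idx, 1.0)
    C /= pssm.length
    return values.astype(float), C


def _cbs_target(pssm: PSSM, values: np.ndarray, C: np.ndarray) -> float:
    """Partition value the profile attains at the global lambda under the
    background composition — the fixed point of the rescaling."""
    g = C @ np.exp(pssm.stats_lambda * values)
    return float(pssm.background_freqs @ g)


def _cbs_lambdas(pssm: PSSM, comps: np.ndarray) -> np.ndarray:
    """Vectorised composition-based lambda for many subjects.

    comps: (n, 20) compositions. Solves g(lambda; q) = g(lambda0; p) for
    the largest root in (0, 10*lambda0] by bracketing on a log grid and
    bisection; rows without a bracket fall back to the global lambda.
    """
    lam0 = pssm.stats_lambda
    values, C = _score_histogram(pssm)
    target = _cbs_target(pssm, values, C)
    grid = np.geomspace(0.02 * lam0, 10 * lam0, 256)
    G = np.exp(np.outer(grid, values)) @ C.T  # (256, 20)
    F = comps @ G.T - target  # (n, 256)
    below = F <= 0
    cross = below[:, :-1] & ~below[:, 1:]
    has_root = cross.any(axis=1)
    # last grid interval where F crosses from <=0 to >0 (the largest root)
    idx = np.where(has_root,
                   (grid.size - 2) - np.argmax(cross[:, ::-1], axis=1), 0)
    lo = grid[idx].copy()
    hi = grid[idx + 1].copy()
    for _ in range(45):  # vectorised bisection across all subjects
        mid = 0.5 * (lo + hi)
        g = (comps * (np.exp(np.outer(mid, values)) @ C.T)).sum(axis=1) - target
        le = g <= 0
        lo = np.where(le, mid, lo)
        hi = np.where(le, hi, mid)
    out = np.where(has_root, 0.5 * (lo + hi), lam0)
    return out


def composition_rescale(pssm: PSSM, subject: ProteinSequence) -> float:
    """Composition-adjusted lambda for one subject.

    Subjects shorter than CBS_MIN_LENGTH keep the global lambda; so do
    subjects for which no root exists in (0, 10*lambda] (with a warning).
    """
    if len(subject) < CBS_MIN_LENGTH:
        return pssm.stats_lambda
    return float(_cbs_lambdas(pssm, _composition(subject)[None, :])[0])


def sw_pssm_align(pssm: PSSM, subject: ProteinSequence,
                  gap_open: int | None = None,
                  gap_extend: int | None = None) -> HSP | None:
    """Best local alignment of the profile against one subject.

    Match score of PSSM position i vs subject residue b is scores[i][b];
    X in the subject scores -1 everywhere. Returns None when no
    positive-scoring alignment exists (e.g. an all-X subject). The
    returned HSP carries raw score and coordinates; bit score and E-value
    are filled with the profile's global statistics against this single
    subject (search_proteome recomputes them for the database context).
    """
    go = pssm.gap_open if gap_open is None else gap_open
    ge = pssm.gap_extend if gap_extend is None else gap_extend
    profile = pssm.search_profile()
    enc = subject.encoded()
    score, qs, qe, ss, se, qpath, spath = _dp.sw_traceback(profile, enc, go, ge)
    if score <= 0:
        return None
    ident, mism, gaps, length = _alignment_stats(pssm, enc, qpath, spath)
    bit = bit_score(int(score), pssm.stats_lambda, pssm.gapped_K)
    return HSP(family=pssm.family, subject_id=subject.id,
               query_start=qs + 1, query_end=qe + 1,
               subject_start=ss + 1, subject_end=se + 1,
               raw_score=int(score), bit_score=bit,
               evalue=evalue(bit, pssm.length, len(subject)),
               identity_fraction=ident / length if length else 0.0,
               align_length=length, mismatches=mism, gap_openings=gaps)


def _alignment_stats(pssm: PSSM, enc: np.ndarray, qpath: np.ndarray,
                     spath: np.ndarray) -> tuple[int, int, int, int]:
    """(identities, mismatches, gap openings, alignment length) for a
    traceback path; identity is subject residue == profile consensus."""
    ident = mism = gaps = 0
    in_gap = False
    for q, s in zip(qpath, spath):
        if q >= 0 and s >= 0:
            in_gap = False
            if pssm.consensus[q] == ALPHABET[enc[s]]:
                ident += 1
            else:
                mism += 1
        else:
            if not in_gap:
                gaps += 1
            in_gap = True
    return ident, mism, gaps, len(qpath)


def search_proteome(pssm: PSSM, db: SequenceDB, evalue_cutoff: float = 10.0,
                    max_target_sequences: int = 20, max_hsps: int = 1,
                    cbs: bool = True, proteome_id: str = "") -> HitTable:
    """Scan every subject of a proteome with the profile.

    All subjects are scored exhaustively; the best HSP per subject is
    kept (max_hsps = 1 semantics), hits with E <= cutoff are sorted by
    ascending E (ties: higher bit score, then lexicographic subject id)
    and truncated to ``max_target_sequences``. With ``cbs`` on, each
    subject's bit score uses its composition-adjusted lambda.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    if max_hsps != 1:
        raise NotImplementedError("only max_hsps=1 (best HSP per subject) is supported")
    profile = pssm.search_profile()
    go, ge = pssm.gap_open, pssm.gap_extend
    n_res = db.total_residues
    m_eff, n_eff = effective_search_space(pssm, n_res, len(db))

    encodings = db.encodings()
    raws = np.zeros(len(db), dtype=np.int64)
    for k, enc in enumerate(encodings):
        raws[k], _, _ = _dp.sw_score(profile, enc, go, ge)

    lams = np.full(len(db), pssm.stats_lambda)
    if cbs:
        long_idx = [k for k, s in enumerate(db.sequences)
                    if len(s) >= CBS_MIN_LENGTH and raws[k] > 0]
        if long_idx:
            comps = np.stack([_composition_from_enc(encodings[k]) for k in long_idx])
            lams[long_idx] = _cbs_lambdas(pssm, comps)

    lnK = math.log(pssm.gapped_K)
    bits = (lams * raws - lnK) / LN2
    evalues = m_eff * n_eff * np.power(2.0, -bits)

    candidates = [(float(evalues[k]), -float(bits[k]), db.sequences[k].id, k)
                  for k in range(len(db))
                  if raws[k] > 0 and evalues[k] <= evalue_cutoff]
    candidates.sort()
    hits: list[HSP] = []
    for ev, negbit, sid, k in candidates[:max_target_sequences]:
        enc = encodings[k]
        score, qs, qe, ss, se, qpath, spath = _dp.sw_traceback(profile, enc, go, ge)
        ident, mism, gaps, length = _alignment_stats(pssm, enc, qpath, spath)
        hits.append(HSP(family=pssm.family, subject_id=sid,
                        query_start=qs + 1, query_end=qe + 1,
                        subject_start=ss + 1, subject_end=se + 1,
                        raw_score=int(score), bit_score=float(-negbit),
                        evalue=ev,
                        identity_fraction=ident / length if length else 0.0,
                        align_length=length, mismatches=mism,
                        gap_openings=gaps))
    return HitTable(family=pssm.family, proteome_id=proteome_id, hits=hits,
                    search_space=(pssm.length, n_res, len(db)))


# --- BLAST tabular (outfmt-6 dialect) ------------------------------------

def write_tabular(table: HitTable, path: str | Path) -> None:
    """Write hits as 12-column BLAST tabular (qseqid = family)."""
    lines = []
    for h in table.hits:
        lines.append("\t".join([
            table.family, h.subject_id,
            f"{100.0 * h.identity_fraction:.3f}", str(h.align_length),
            str(h.mismatches), str(h.gap_openings),
            str(h.query_start), str(h.query_end),
            str(h.subject_start), str(h.subject_end),
            f"{h.evalue:.3g}", f"{h.bit_score:.1f}",
        ]))
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_tabular(path: str | Path, proteome_id: str = "") -> HitTable:
    """Parse the 12-column BLAST tabular dialect back into a HitTable."""
    hits: list[HSP] = []
    family = ""
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
        try:
            family = fields[0]
            length = int(fields[3])
            hits.append(HSP(
                family=fields[0], subject_id=fields[1],
                identity_fraction=float(fields[2]) / 100.0,
                align_length=length, mismatches=int(fields[4]),
                gap_openings=int(fields[5]),
                query_start=int(fields[6]), query_end=int(fields[7]),
                subject_start=int(fields[8]), subject_end=int(fields[9]),
                evalue=float(fields[10]), bit_score=float(fields[11]),
                raw_score=0))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
    return HitTable(family=family, proteome_id=proteome_id, hits=hits)
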