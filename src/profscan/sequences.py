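"""Protein sequence and substitution-matrix data model.

The atoms shared by every stage of the toolkit: validated protein
sequences, an id-indexed sequence collection, FASTA reading/writing
(via Biopython) and NCBI-format substitution matrix loading with
Karlin–Altschul ungapped statistics.

Coordinates everywhere in this package are 1-based inclusive (the BLAST
tabular convention); internal arrays are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.optimize import brentq

logger = logging.getLogger("profscan")

#: The 20 standard amino acids, in the order used by every score/frequency
#: array in this package, followed by the mask/ambiguity character X.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

#: Ambiguity codes degraded to X on input (B=Asx, Z=Glx, J=Xle, U=Sec, O=Pyl).
AMBIGUITY_CODES = set("BZJUO")

#: Robinson & Robinson amino-acid background frequencies (the standard
#: BLAST background), order matching AMINO_ACIDS.
_ROBINSON = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

#: Published ungapped K for BLOSUM62 with Robinson background.
BLOSUM62_UNGAPPED_K = 0.134


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence: id, free-text description, residues, optional taxon.

    Residues are stored uppercase over the alphabet of 20 standard amino
    acids plus X; construction validates and normalises.
    """

    id: str
    residues: str
    description: str = ""
    taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be non-empty, no whitespace: {self.id!r}")
        residues = self.residues.upper()
        if not residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(residues) - set(ALPHABET)
        if bad:
            raise ValueError(f"{self.id}: illegal residue characters {sorted(bad)}")
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)

    def encoded(self) -> np.ndarray:
        """Residues as int8 indices into ALPHABET (X = 20)."""
        return np.fromiter((AA_INDEX[c] for c in self.residues), dtype=np.int8,
                           count=len(self.residues))


class SequenceDB:
    """An ordered, id-indexed collection of protein sequences."""

    def __init__(self, sequences: Iterable[ProteinSequence] = ()):
        self.sequences: list[ProteinSequence] = list(sequences)
        self.index: dict[str, int] = {}
        self._encodings: list[np.ndarray] | None = None
        for pos, seq in enumerate(self.sequences):
            if seq.id in self.index:
                raise ValueError(f"duplicate sequence id {seq.id!r}")
            self.index[seq.id] = pos

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self.sequences)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.index

    def __getitem__(self, seq_id: str) -> ProteinSequence:
        return self.sequences[self.index[seq_id]]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    @property
    def total_residues(self) -> int:
        return sum(len(s) for s in self.sequences)

    def encodings(self) -> list[np.ndarray]:
        """Cached int8 encodings of every sequence (scan hot path)."""
        if self._encodings is None:
            self._encodings = [s.encoded() for s in self.sequences]
        return self._encodings


def _clean_residues(seq_id: str, raw: str) -> str | None:
    """Normalise one record's residues; None means reject the record."""
    s = raw.upper().replace("*", "")
    if not s:
        logger.warning("record %s: empty sequence after cleanup, rejected", seq_id)
        return None
    out = []
    ambiguous = 0
    for c in s:
        if c in AA_INDEX:
            out.append(c)
        elif c in AMBIGUITY_CODES:
            out.append("X")
            ambiguous += 1
        else:
            logger.warning("record %s: illegal character %r, record rejected", seq_id, c)
            return None
    if ambiguous:
        logger.warning("record %s: %d ambiguity code(s) mapped to X", seq_id, ambiguous)
    return "".join(out)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a protein FASTA file.

    The header token before the first whitespace is the id, the remainder
    the description. Sequences are uppercased and '*' stop characters
    stripped; ambiguity codes B/Z/J/U/O become X with a warning; records
    with other illegal characters are rejected with a log message. An empty
    file yields an empty list with a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        logger.warning("%s: no FASTA records found", path)
    out = []
    for rec in records:
        residues = _clean_residues(rec.id, str(rec.seq))
        if residues is None:
            continue
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        out.append(ProteinSequence(id=rec.id, residues=residues, description=desc))
    return out


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path,
                line_width: int = 60) -> None:
    """Write sequences as FASTA, wrapped at ``line_width`` columns."""
    seqs = list(seqs)
    seen: set[str] = set()
    for s in seqs:
        if s.id in seen:
            raise ValueError(f"duplicate sequence id {s.id!r}")
        seen.add(s.id)
    records = [SeqRecord(Seq(s.residues), id=s.id, description=s.description)
               for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)


@dataclass
class SubstitutionMatrix:
    """A symmetric amino-acid substitution matrix with ungapped statistics.

    ``scores`` is a 21x21 integer table over AMINO_ACIDS + X; the X
    row/column is the constant -1 (BLAST convention — masked residues must
    not contribute positive signal). ``ungapped_lambda`` is root-found at
    load time so the Karlin–Altschul identity
    sum_ab p_a p_b exp(lambda * s_ab) = 1 holds for the stored background.
    """

    name: str
    scores: np.ndarray
    background_freqs: np.ndarray
    ungapped_lambda: float
    ungapped_K: float

    def score(self, a: str, b: str) -> int:
        return int(self.scores[AA_INDEX[a], AA_INDEX[b]])

    def row(self, a: str) -> np.ndarray:
        """The 20 scores of residue ``a`` against each standard amino acid."""
        return self.scores[AA_INDEX[a], :20].copy()


def _solve_ungapped_lambda(scores20: np.ndarray, p: np.ndarray) -> float:
    """Positive root of sum_ab p_a p_b exp(lambda*s) = 1."""
    pp = np.outer(p, p)

    def f(lam: float) -> float:
        return float((pp * np.exp(lam * scores20)).sum() - 1.0)

    # f(0)=0; the scoring system has negative expectation so f dips below 0
    # then rises: bracket the positive root from above.
    hi = 2.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 64:
            raise ValueError("no positive lambda: scoring system not valid")
    lo = 1e-4
    while f(lo) > 0:
        lo /= 4.0
        if lo < 1e-12:
            raise ValueError("no positive lambda: scoring system not valid")
    return float(brentq(f, lo, hi, xtol=1e-12))


def _parse_matrix_file(text: str, name: str) -> dict[tuple[str, str], int]:
    scores: dict[tuple[str, str], int] = {}
    header: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if not header:
            header = fields
            if any(len(f) != 1 for f in header):
                raise ValueError(f"{name}:{lineno}: malformed matrix header")
            continue
        row_aa = fields[0]
        if len(row_aa) != 1 or len(fields) != len(header) + 1:
            raise ValueError(f"{name}:{lineno}: malformed matrix row")
        try:
            values = [int(v) for v in fields[1:]]
        except ValueError as exc:
            raise ValueError(f"{name}:{lineno}: non-integer score") from exc
        for col_aa, v in zip(header, values):
            scores[(row_aa, col_aa)] = v
    if not header:
        raise ValueError(f"{name}: empty matrix file")
    return scores


def load_substitution_matrix(name_or_path: str | Path = "BLOSUM62") -> SubstitutionMatrix:
    """Load a bundled matrix by name ("BLOSUM62") or an NCBI-format file.

    The X row/column is forced to the constant -1 and lambda is recomputed
    against the Robinson–Robinson background so the type invariants hold
    exactly for any loaded matrix.
    """
    name = str(name_or_path)
    if name.upper() == "BLOSUM62":
        text = resources.files("profscan.data").joinpath("BLOSUM62").read_text()
        name = "BLOSUM62"
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise FileNotFoundError(f"matrix {name_or_path!r}: not a bundled name or file")
        text = path.read_text()
        name = path.stem
    table = _parse_matrix_file(text, name)

    scores = np.full((21, 21), -1, dtype=np.int32)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if (a, b) not in table:
                raise ValueError(f"{name}: missing pair {a}/{b}")
            scores[i, j] = table[(a, b)]
    if not np.array_equal(scores[:20, :20], scores[:20, :20].T):
        raise ValueError(f"{name}: asymmetric score table")

    p = np.array([_ROBINSON[a] for a in AMINO_ACIDS])
    p = p / p.sum()
    lam = _solve_ungapped_lambda(scores[:20, :20].astype(float), p)
    K = BLOSUM62_UNGAPPED_K  # exact for the bundled matrix; nominal otherwise
    return SubstitutionMatrix(name=name, scores=scores, background_freqs=p,
                              ungapped_lambda=lam, ungapped_K=K)
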