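"""Detection benchmarking: expected composition, ranks, TPR/FNR.

The evaluation protocol is rank-based: a family member in a proteome
counts as detected only when the true protein is the FIRST hit of that
family's profile against that proteome (top-hit criterion); a true
protein ranking lower, or absent from the capped hit list, is a false
negative. Expected-absent (species, family) cells contribute true
negatives, or false positives when any hit reaches the FP E-value
threshold. TPR = 100*TP/(TP+FN), FNR its complement.

HMMER3 ``--tblout`` summaries can be ingested for cross-method
comparison (profile-HMM search itself is not re-implemented here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .search import HSP, HitTable

logger = logging.getLogger("profscan")


@dataclass
class ExpectedComposition:
    """The gold standard: which families each species is expected to have.

    ``truth_map`` gives the true protein id(s) for every expected-true
    (species, family) cell — and only for those cells.
    """

    species: list[str]
    families: list[str]
    expected: Mapping[tuple[str, str], bool]
    truth_map: Mapping[tuple[str, str], tuple[str, ...]]

    def __post_init__(self) -> None:
        cells = {(s, f) for s in self.species for f in self.families}
        if set(self.expected) != cells:
            raise ValueError("expected matrix does not cover species x families")
        true_cells = {c for c, v in self.expected.items() if v}
        if set(self.truth_map) != true_cells:
            raise ValueError("truth_map must be defined exactly on expected-true cells")
        if any(not ids for ids in self.truth_map.values()):
            raise ValueError("empty truth id tuple")

    @property
    def n_cells(self) -> int:
        return len(self.species) * len(self.families)

    @property
    def n_expected(self) -> int:
        return sum(bool(v) for v in self.expected.values())

    @property
    def n_absent(self) -> int:
        return self.n_cells - self.n_expected

    def true_cells(self) -> list[tuple[str, str]]:
        return sorted(c for c, v in self.expected.items() if v)

    def absent_cells(self) -> list[tuple[str, str]]:
        return sorted(c for c, v in self.expected.items() if not v)


def write_expected_composition(ec: ExpectedComposition, path: str | Path) -> None:
    """TSV: species, family, expected(0/1), truth_ids (comma-separated)."""
    lines = ["species\tfamily\texpected\ttruth_ids"]
    for s in ec.species:
        for f in ec.families:
            exp = ec.expected[(s, f)]
            ids = ",".join(ec.truth_map.get((s, f), ()))
            lines.append(f"{s}\t{f}\t{int(exp)}\t{ids}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_expected_composition(path: str | Path) -> ExpectedComposition:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    species = list(dict.fromkeys(df["species"]))
    families = list(dict.fromkeys(df["family"]))
    expected: dict[tuple[str, str], bool] = {}
    truth: dict[tuple[str, str], tuple[str, ...]] = {}
    for _, row in df.iterrows():
        cell = (row["species"], row["family"])
        exp = bool(int(row["expected"]))
        expected[cell] = exp
        if exp:
            truth[cell] = tuple(t for t in row["truth_ids"].split(",") if t)
    return ExpectedComposition(species=species, families=families,
                               expected=expected, truth_map=truth)


@dataclass(frozen=True)
class DetectionRecord:
    """Outcome for one expected-true (species, family) cell."""

    species: str
    family: str
    rank: int | None
    detected: bool
    evalue_of_true: float | None = None

    def __post_init__(self) -> None:
        if self.detected and self.rank != 1:
            raise ValueError("detected requires rank 1")
        if self.rank is None and self.detected:
            raise ValueError("no rank implies not detected")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.FP, self.TN) < 0:
            raise ValueError("negative confusion count")


def _round1(x: float) -> float:
    """Round half-up to one decimal (the convention of printed rates)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tpr(c: ConfusionCounts) -> float:
    """True positive rate 100*TP/(TP+FN), one decimal, half-up."""
    if c.TP + c.FN == 0:
        raise ZeroDivisionError("TPR undefined: no expected-true cells")
    return _round1(100.0 * c.TP / (c.TP + c.FN))


def fnr(c: ConfusionCounts) -> float:
    """False negative rate 100*FN/(TP+FN), one decimal, half-up."""
    if c.TP + c.FN == 0:
        raise ZeroDivisionError("FNR undefined: no expected-true cells")
    return _round1(100.0 * c.FN / (c.TP + c.FN))


def compare_methods(a: ConfusionCounts, b: ConfusionCounts) -> float:
    """TPR difference of method a over method b, in percentage points."""
    return _round1(tpr(a) - tpr(b))


def rank_true_hits(hits: HitTable, truth_ids: Iterable[str]) -> DetectionRecord:
    """Rank of the first true protein in a profile's hit list.

    rank is the 1-based position of the first hit whose subject is a
    truth id, None when no truth id appears in the (capped) list;
    detected means rank 1 exactly. With multiple truth ids (duplicated
    genes) the best-ranked one counts.
    """
    truth = set(truth_ids)
    if not truth:
        raise ValueError("empty truth_ids: expected-absent cells are never ranked")
    rank = None
    ev = None
    for pos, h in enumerate(hits, start=1):
        if h.subject_id in truth:
            rank = pos
            ev = h.evalue
            break
    return DetectionRecord(species=hits.proteome_id, family=hits.family,
                           rank=rank, detected=rank == 1, evalue_of_true=ev)


def confusion(ec: ExpectedComposition,
              records: Mapping[tuple[str, str], DetectionRecord],
              absent_cell_calls: Mapping[tuple[str, str], HitTable] | None = None,
              fp_evalue: float = 1e-5) -> ConfusionCounts:
    """Fold per-cell outcomes into TP/FN/FP/TN.

    ``records`` must cover every expected-true cell. Expected-absent
    cells score FP when their hit table contains any hit with
    E <= fp_evalue, else TN; cells without a supplied table are TN.
    """
    missing = [c for c in ec.true_cells() if c not in records]
    if missing:
        raise ValueError(f"missing detection records for cells: {missing}")
    tp = sum(1 for c in ec.true_cells() if records[c].detected)
    fn = ec.n_expected - tp
    fp = 0
    calls = absent_cell_calls or {}
    for cell in ec.absent_cells():
        table = calls.get(cell)
        if table is not None and any(h.evalue <= fp_evalue for h in table):
            fp += 1
    tn = ec.n_absent - fp
    return ConfusionCounts(TP=tp, FN=fn, FP=fp, TN=tn)


def rank_matrix_report(records: Mapping[tuple[str, str], DetectionRecord],
                       ec: ExpectedComposition) -> pd.DataFrame:
    """Species x family grid of ranks; "–" where the family is not
    expected, "ND" for expected-but-unranked cells, plus a summary row
    counting rank-1 detections per family."""
    grid = pd.DataFrame("–", index=list(ec.species), columns=list(ec.families),
                        dtype=object)
    for (s, f), rec in records.items():
        grid.loc[s, f] = "ND" if rec.rank is None else rec.rank
    summary = {}
    for f in ec.families:
        summary[f] = sum(1 for (s, fam), r in records.items()
                         if fam == f and r.detected)
    grid.loc["detected"] = [summary[f] for f in ec.families]
    return grid


def report_to_markdown(grid: pd.DataFrame) -> str:
    return grid.to_markdown()


# --- End-to-end evaluation -----------------------------------------------

def run_detection_benchmark(proteomes: Mapping[str, "SequenceDB"],
                            families: Mapping[str, "FamilySeedSet"],
                            ec: ExpectedComposition,
                            matrix: "SubstitutionMatrix",
                            mask: bool = False, mask_threshold: int = 15,
                            fp_evalue: float = 1e-5,
                            evalue_cutoff: float = 10.0,
                            max_target_sequences: int = 20,
                            cbs: bool = True):
    """Build every family profile, scan every proteome, score the grid.

    Profiles are built from the (unmasked) seed members; with ``mask``
    on, proteome subjects are hard-masked for compositional bias before
    searching (the masked re-run of the evaluation protocol). Returns
    (records, absent_calls, ConfusionCounts).
    """
    from .mask import mask_compositional_bias
    from .pssm import build_family_pssm
    from .search import search_proteome
    from .sequences import SequenceDB

    profiles = {f: build_family_pssm(seeds, matrix)
                for f, seeds in families.items()}
    dbs: dict[str, "SequenceDB"] = {}
    for s, db in proteomes.items():
        if mask:
            dbs[s] = SequenceDB(
                [mask_compositional_bias(seq, matrix, mask_threshold).to_sequence()
                 for seq in db])
        else:
            dbs[s] = db
    records: dict[tuple[str, str], DetectionRecord] = {}
    absent_calls: dict[tuple[str, str], HitTable] = {}
    for f, profile in profiles.items():
        for s in ec.species:
            table = search_proteome(profile, dbs[s], evalue_cutoff=evalue_cutoff,
                                    max_target_sequences=max_target_sequences,
                                    cbs=cbs, proteome_id=s)
            cell = (s, f)
            if ec.expected[cell]:
                records[cell] = rank_true_hits(table, ec.truth_map[cell])
            else:
                absent_calls[cell] = table
    counts = confusion(ec, records, absent_calls, fp_evalue=fp_evalue)
    return records, absent_calls, counts


# --- HMMER tblout ingestion ----------------------------------------------

def read_hmmer_tblout(path: str | Path, proteome_id: str = "") -> HitTable:
    """Parse an HMMER3 ``hmmsearch --tblout`` summary into a HitTable.

    Keeps the target id, full-sequence E-value and score; hits are
    sorted ascending by E-value (ties: higher score, then target id).
    The format is identical whether or not the run used ``--max``
    (heuristic filters off), so both dialects parse. Alignment
    coordinates are absent from tblout; HSP coordinate fields are 0.
    """
    hits: list[HSP] = []
    family = ""
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 10:
            raise ValueError(f"{path}:{lineno}: truncated tblout line")
        try:
            target = fields[0]
            family = fields[2]
            ev = float(fields[4])
            score = float(fields[5])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed tblout line ({exc})") from exc
        hits.append(HSP(family=family, subject_id=target, query_start=0,
                        query_end=0, subject_start=0, subject_end=0,
                        raw_score=0, bit_score=score, evalue=ev))
    hits.sort(key=lambda h: (h.evalue, -h.bit_score, h.subject_id))
    return HitTable(family=family, proteome_id=proteome_id, hits=hits)
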