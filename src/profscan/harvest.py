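"""Iterative family delineation against a local labelled database.

Automates the iterative profile-search harvesting protocol: build a
profile from the current members, scan the database, admit hits below
the family-specific inclusion E-value that pass a reciprocal-search
check, rebuild, repeat. The run stops on convergence (an iteration
admits nothing), on an iteration budget, or when a majority of an
iteration's would-be admissions fail the reciprocal check — the
automated analogue of a curator noticing that an iteration "started to
retrieve unrelated hits" (that iteration's admissions are rolled back).

Queries are hard-masked for compositional bias (threshold 15) before
profile building during the iterations; the final enlarged seed set
holds the original, unmasked sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from .mask import DEFAULT_THRESHOLD, mask_compositional_bias
from .pssm import FamilySeedSet, align_to_master, build_family_pssm
from .search import HSP, search_proteome
from .sequences import ProteinSequence, SequenceDB, SubstitutionMatrix

logger = logging.getLogger("profscan")

DEFAULT_KEYWORD_BLACKLIST = ("fragment", "partial")


@dataclass
class HarvestIteration:
    iteration: int
    new_member_ids: list[str]
    flagged_ids: list[str]  # candidates that failed the reciprocal check


@dataclass
class HarvestRun:
    """Audit trail of one iterative family search."""

    family: str
    inclusion_evalue: float
    max_iterations: int
    iterations: list[HarvestIteration] = field(default_factory=list)
    stop_reason: str = ""  # converged | max_iterations | unrelated_hits

    def all_new_ids(self) -> list[str]:
        return [i for it in self.iterations for i in it.new_member_ids]


def prefilter_complete(db: SequenceDB, min_len_fraction: float = 0.5,
                       keyword_blacklist=DEFAULT_KEYWORD_BLACKLIST,
                       master_length: int | None = None) -> SequenceDB:
    """Drop fragments and partial entries before harvesting.

    Removes sequences whose description contains a blacklisted keyword
    (case-insensitive) or — when ``master_length`` is given — whose
    length is below ``min_len_fraction`` of it. Removals are logged.
    """
    kept = []
    for seq in db:
        desc = seq.description.lower()
        if any(kw.lower() in desc for kw in keyword_blacklist):
            logger.info("prefilter: %s removed (keyword match in description)", seq.id)
            continue
        if master_length is not None and len(seq) < min_len_fraction * master_length:
            logger.info("prefilter: %s removed (length %d < %.0f%% of master)",
                        seq.id, len(seq), 100 * min_len_fraction)
            continue
        kept.append(seq)
    return SequenceDB(kept)


def reciprocal_check(candidate_hsp: HSP, candidate: ProteinSequence,
                     seed_db: SequenceDB, matrix: SubstitutionMatrix,
                     family: str | None = None,
                     family_of: Mapping[str, str] | None = None) -> bool:
    """Reverse-search validation of a candidate hit.

    The matching part of the candidate (subject_start..subject_end) is
    locally aligned against every seed; the candidate passes iff the
    best-scoring seed belongs to the harvesting family. ``family_of``
    maps seed ids to family names (defaults to the seed's taxon field,
    then to ``family`` itself, which makes a single-family seed set a
    tautological pass — supply the full multi-family seed collection for
    a meaningful check).
    """
    family = family if family is not None else candidate_hsp.family
    lo, hi = candidate_hsp.subject_start, candidate_hsp.subject_end
    if lo < 1 or hi > len(candidate) or hi < lo:
        logger.warning("reciprocal: %s region %d..%d invalid", candidate.id, lo, hi)
        return False
    region = candidate.residues[lo - 1 : hi]
    if set(region) <= {"X"}:
        logger.warning("reciprocal: %s region is entirely masked", candidate.id)
        return False
    try:
        fragment = ProteinSequence(id="__region__", residues=region)
    except ValueError:
        return False
    best_score = 0
    best_family: str | None = None
    for seed in seed_db:
        aln = align_to_master(seed, fragment, matrix)
        if aln.score > best_score:
            best_score = aln.score
            if family_of is not None:
                best_family = family_of.get(seed.id)
            elif seed.taxon is not None:
                best_family = seed.taxon
            else:
                best_family = family
    return best_family == family and best_score > 0


def iterative_family_search(seeds: FamilySeedSet, db: SequenceDB,
                            matrix: SubstitutionMatrix,
                            max_iterations: int = 10,
                            unrelated_fraction: float = 0.5,
                            reference_db: SequenceDB | None = None,
                            family_of: Mapping[str, str] | None = None,
                            mask_queries: bool = True,
                            mask_threshold: int = DEFAULT_THRESHOLD,
                            max_target_sequences: int = 1000,
                            cbs: bool = True) -> tuple[FamilySeedSet, HarvestRun]:
    """Iteratively enlarge a family seed set from a prefiltered database.

    Each iteration builds a PSSM from the current members (hard-masked
    queries when ``mask_queries``), scans ``db``, and admits new hits
    with E <= the family's inclusion threshold that pass the reciprocal
    check against ``reference_db`` (default: the seeds themselves).
    Stops when nothing is admitted (converged), when ``max_iterations``
    is hit, or when more than ``unrelated_fraction`` of an iteration's
    would-be admissions fail the reciprocal check (unrelated_hits; the
    iteration is rolled back).
    """
    if not any(m.id in db for m in seeds.members):
        logger.warning("%s: no seed member present in the database", seeds.family)
    members = list(seeds.members)
    member_ids = {m.id for m in members}
    run = HarvestRun(family=seeds.family,
                     inclusion_evalue=seeds.inclusion_evalue,
                     max_iterations=max_iterations)
    check_db = reference_db if reference_db is not None else SequenceDB(seeds.members)
    if family_of is None and reference_db is None:
        family_of = {m.id: seeds.family for m in seeds.members}

    for iteration in range(1, max_iterations + 1):
        if mask_queries:
            profile_members = [mask_compositional_bias(m, matrix, mask_threshold).to_sequence()
                               for m in members]
        else:
            profile_members = members
        current = FamilySeedSet(family=seeds.family, members=profile_members,
                                master_id=seeds.master_id,
                                inclusion_evalue=seeds.inclusion_evalue,
                                notes=seeds.notes)
        profile = build_family_pssm(current, matrix)
        table = search_proteome(profile, db,
                                evalue_cutoff=max(seeds.inclusion_evalue, 0),
                                max_target_sequences=max_target_sequences,
                                cbs=cbs)
        candidates = [h for h in table
                      if h.evalue <= seeds.inclusion_evalue
                      and h.subject_id not in member_ids]
        admitted: list[ProteinSequence] = []
        flagged: list[str] = []
        for hsp in candidates:
            candidate = db[hsp.subject_id]
            if reciprocal_check(hsp, candidate, check_db, matrix,
                                family=seeds.family, family_of=family_of):
                admitted.append(candidate)
            else:
                flagged.append(hsp.subject_id)
        if candidates and len(flagged) / len(candidates) > unrelated_fraction:
            run.iterations.append(HarvestIteration(iteration, [], flagged))
            run.stop_reason = "unrelated_hits"
            logger.info("%s: iteration %d rolled back (%d/%d reciprocal failures)",
                        seeds.family, iteration, len(flagged), len(candidates))
            break
        run.iterations.append(
            HarvestIteration(iteration, [s.id for s in admitted], flagged))
        if not admitted:
            run.stop_reason = "converged"
            break
        members.extend(admitted)
        member_ids.update(s.id for s in admitted)
    else:
        run.stop_reason = "max_iterations"
    enlarged = FamilySeedSet(family=seeds.family, members=members,
                             master_id=seeds.master_id,
                             inclusion_evalue=seeds.inclusion_evalue,
                             notes=seeds.notes)
    return enlarged, run
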