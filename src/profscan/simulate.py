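"""Synthetic protein families, decoy proteomes and gold standards.

A download-free test surface for every stage: families of divergent
homologs sharing a conserved core (substitutions sampled from
substitution-matrix-derived conditional probabilities, so homologs stay
detectable by score, as real divergence does), optional FG-repeat or
low-complexity tracts inserted at homologous positions (with small
per-member jitter, so profiles learn them unless masked), decoy
proteomes drawn from background residue frequencies, and a species x
family expected-composition matrix with held-out truth proteins
embedded in the proteomes.

All outputs are pure functions of their spec: randomness comes from a
counter-based Philox generator keyed by the spec's 64-bit seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .benchmark import ExpectedComposition, write_expected_composition
from .pssm import FamilySeedSet
from .sequences import (AMINO_ACIDS, ProteinSequence, SequenceDB,
                        SubstitutionMatrix, load_substitution_matrix,
                        write_fasta)


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Recipe for one synthetic family.

    divergence is the expected substitutions per site in [0, 1);
    indel_rate the per-site indel event probability (geometric lengths,
    mean 2). ``repeat_motif``/``repeat_copies`` inject a repeat tract
    (e.g. 12 x "FG"), ``lcr_residue``/``lcr_length`` a homopolymeric
    low-complexity tract; both are placed at a homologous position
    across members with +-2 jitter.
    """

    family: str
    core_length: int = 150
    n_members: int = 10
    divergence: float = 0.25
    indel_rate: float = 0.01
    repeat_motif: str | None = None
    repeat_copies: int = 0
    lcr_residue: str | None = None
    lcr_length: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")
        if self.core_length <= 0 or self.n_members <= 0:
            raise ValueError("counts must be positive")
        if self.indel_rate < 0 or self.repeat_copies < 0 or self.lcr_length < 0:
            raise ValueError("rates and counts must be non-negative")


def inject_repeats(seq: ProteinSequence, motif: str, copies: int,
                   position: int) -> ProteinSequence:
    """Insert ``copies`` tandem copies of ``motif`` before 1-based
    ``position``; the length grows by copies * len(motif)."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    if not 1 <= position <= len(seq) + 1:
        raise ValueError("position out of range")
    tract = motif.upper() * copies
    residues = seq.residues[: position - 1] + tract + seq.residues[position - 1 :]
    return ProteinSequence(id=seq.id, residues=residues,
                           description=seq.description, taxon=seq.taxon)


def _substitution_probs(matrix: SubstitutionMatrix) -> np.ndarray:
    """P(b | a, substitution happened): the matrix-implied conditional
    target distribution p_b * exp(lambda * s_ab), b != a, renormalised."""
    lam = matrix.ungapped_lambda
    S = matrix.scores[:20, :20].astype(float)
    W = matrix.background_freqs[None, :] * np.exp(lam * S)
    np.fill_diagonal(W, 0.0)
    return W / W.sum(axis=1, keepdims=True)


def _mutate(core: np.ndarray, spec: SyntheticFamilySpec, rng: np.random.Generator,
            sub_probs: np.ndarray, background: np.ndarray) -> np.ndarray:
    seq = core.copy()
    mutate = rng.random(seq.size) < spec.divergence
    for i in np.nonzero(mutate)[0]:
        seq[i] = rng.choice(20, p=sub_probs[seq[i]])
    if spec.indel_rate > 0:
        events = np.nonzero(rng.random(seq.size) < spec.indel_rate)[0]
        for pos in events[::-1]:  # right to left keeps indices valid
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # deletion
                seq = np.delete(seq, slice(pos, pos + length))
            else:  # insertion of background residues
                ins = rng.choice(20, size=length, p=background)
                seq = np.insert(seq, pos, ins)
    return seq


def _decode(codes: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[c] for c in codes)


def sample_family(spec: SyntheticFamilySpec,
                  matrix: SubstitutionMatrix | None = None) -> list[ProteinSequence]:
    """Draw a synthetic family; member 0 is the ancestral core itself.

    The core is sampled from background frequencies; every other member
    mutates it independently (substitutions at rate ``divergence`` with
    matrix-conditional target residues, indels at ``indel_rate``). The
    repeat/LCR tracts of the spec are inserted into every member at a
    homologous position with +-2 jitter.
    """
    matrix = matrix or load_substitution_matrix("BLOSUM62")
    rng = _rng(spec.rng_seed)
    background = matrix.background_freqs
    sub_probs = _substitution_probs(matrix)
    core = rng.choice(20, size=spec.core_length, p=background)
    tract = ""
    if spec.repeat_motif and spec.repeat_copies:
        tract += spec.repeat_motif.upper() * spec.repeat_copies
    if spec.lcr_residue and spec.lcr_length:
        tract += spec.lcr_residue.upper() * spec.lcr_length
    tract_pos = int(rng.integers(1, spec.core_length + 2)) if tract else 0

    members: list[ProteinSequence] = []
    for k in range(spec.n_members):
        codes = core if k == 0 else _mutate(core, spec, rng, sub_probs, background)
        seq = ProteinSequence(id=f"{spec.family}_m{k:03d}",
                              residues=_decode(codes), taxon=spec.family)
        if tract:
            jitter = 0 if k == 0 else int(rng.integers(-2, 3))
            pos = min(max(1, tract_pos + jitter), len(seq) + 1)
            seq = inject_repeats(seq, tract, 1, pos)
        members.append(seq)
    return members


@dataclass
class SyntheticBenchmark:
    """A complete synthetic evaluation fixture.

    Training members form the seed sets; each expected-true (species,
    family) cell has exactly one held-out member embedded in that
    species' decoy proteome. The manifest records the full ground truth.
    """

    proteomes: dict[str, SequenceDB]
    families: dict[str, FamilySeedSet]
    expected: ExpectedComposition
    manifest: dict = field(default_factory=dict)


def make_benchmark(n_species: int = 15, n_families: int = 10,
                   absent_fraction: float = 0.25,
                   decoys_per_proteome: int = 200,
                   spec_defaults: dict | None = None,
                   rng_seed: int = 0, n_train: int = 8,
                   family_overrides: dict[str, dict] | None = None,
                   decoy_length_range: tuple[int, int] = (100, 400),
                   matrix: SubstitutionMatrix | None = None) -> SyntheticBenchmark:
    """Build the default benchmark fixture.

    Exactly round(absent_fraction * n_species * n_families) cells are
    sampled as expected-absent (each family keeps at least one
    expected-true cell). By default two families carry compositional
    bias — one FG-repeat family and one poly-Q low-complexity family,
    with distinct motifs so cross-family repeat matches cannot occur by
    construction; repeat-flagged families get the stricter inclusion
    E-value used for repeat-rich families (1e-10 vs 1e-5).
    """
    if not 0 <= absent_fraction < 1:
        raise ValueError("absent_fraction must be in [0, 1)")
    if decoys_per_proteome == 0 and n_families == 0:
        raise ValueError("empty proteomes: no decoys and no families")
    matrix = matrix or load_substitution_matrix("BLOSUM62")
    rng = _rng(rng_seed)
    species = [f"sp{i + 1:02d}" for i in range(n_species)]
    family_names = [f"fam{i + 1:02d}" for i in range(n_families)]

    n_cells = n_species * n_families
    n_absent = int(round(absent_fraction * n_cells))
    cells = [(s, f) for s in species for f in family_names]
    absent: set[tuple[str, str]] = set()
    for _ in range(100):  # resample until every family keeps a true cell
        idx = rng.choice(n_cells, size=n_absent, replace=False)
        absent = {cells[i] for i in idx}
        per_family_true = {f: sum(1 for s in species if (s, f) not in absent)
                           for f in family_names}
        if all(v > 0 for v in per_family_true.values()) or n_absent == 0:
            break

    defaults = dict(core_length=150, n_members=0, divergence=0.25,
                    indel_rate=0.01)
    defaults.update(spec_defaults or {})
    overrides = dict(family_overrides or {})
    if family_overrides is None and n_families >= 2:
        overrides[family_names[0]] = dict(repeat_motif="FG", repeat_copies=12)
        overrides[family_names[1]] = dict(lcr_residue="Q", lcr_length=30)

    families: dict[str, FamilySeedSet] = {}
    heldout: dict[tuple[str, str], ProteinSequence] = {}
    truth: dict[tuple[str, str], tuple[str, ...]] = {}
    specs: dict[str, SyntheticFamilySpec] = {}
    for f in family_names:
        true_species = [s for s in species if (s, f) not in absent]
        kw = dict(defaults)
        kw.update(overrides.get(f, {}))
        kw["n_members"] = n_train + len(true_species)
        spec = SyntheticFamilySpec(family=f, rng_seed=int(rng.integers(2 ** 31)),
                                   **kw)
        specs[f] = spec
        members = sample_family(spec, matrix)
        train = members[:n_train]
        biased = bool(spec.repeat_motif or spec.lcr_residue)
        families[f] = FamilySeedSet(
            family=f, members=train, master_id=train[0].id,
            inclusion_evalue=1e-10 if biased else 1e-5,
            notes="repeat-flagged" if biased else "")
        for s, member in zip(true_species, members[n_train:]):
            heldout[(s, f)] = member
            truth[(s, f)] = (member.id,)

    lo, hi = decoy_length_range
    proteomes: dict[str, SequenceDB] = {}
    for s in species:
        seqs: list[ProteinSequence] = []
        for d in range(decoys_per_proteome):
            length = int(rng.integers(lo, hi + 1))
            codes = rng.choice(20, size=length, p=matrix.background_freqs)
            seqs.append(ProteinSequence(id=f"{s}_d{d + 1:04d}",
                                        residues=_decode(codes), taxon=s))
        for f in family_names:
            if (s, f) in heldout:
                seqs.append(heldout[(s, f)])
        order = rng.permutation(len(seqs))
        proteomes[s] = SequenceDB([seqs[i] for i in order])

    expected = ExpectedComposition(
        species=species, families=family_names,
        expected={c: c not in absent for c in cells}, truth_map=truth)
    manifest = {
        "rng_seed": rng_seed,
        "n_species": n_species, "n_families": n_families,
        "n_absent": n_absent, "n_train": n_train,
        "decoys_per_proteome": decoys_per_proteome,
        "family_specs": {f: asdict(specs[f]) for f in family_names},
        "heldout_ids": {f"{s}:{f}": p.id for (s, f), p in heldout.items()},
        "absent_cells": sorted(f"{s}:{f}" for (s, f) in absent),
    }
    bench = SyntheticBenchmark(proteomes=proteomes, families=families,
                               expected=expected, manifest=manifest)
    assert bench.expected.n_absent == n_absent
    return bench


def write_benchmark(bench: SyntheticBenchmark, outdir: str | Path) -> None:
    """Materialise a fixture: one FASTA per proteome and per seed set,
    the expected-composition TSV and the JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s, db in bench.proteomes.items():
        write_fasta(db.sequences, outdir / f"proteome_{s}.fasta")
    for f, seeds in bench.families.items():
        write_fasta(seeds.members, outdir / f"seeds_{f}.fasta")
    write_expected_composition(bench.expected, outdir / "ec.tsv")
    (outdir / "manifest.json").write_text(json.dumps(bench.manifest, indent=2))
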