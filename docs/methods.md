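# Methods

This note documents the models and numerical choices behind
`profscan`: how profiles are built, how bias masking and search
statistics work, what the synthetic benchmark emulates (and does not),
and where the design was genuinely open.

## Sequence model and conventions

Sequences are over the 20 standard amino acids plus X. Ambiguity codes
B/Z/J/U/O are degraded to X on input with a warning (scoring stays
defined; the information loss is one residue); records containing other
illegal characters are rejected. X scores −1 against everything (the
BLAST convention), so masked or ambiguous residues can never contribute
positive signal. All serialised coordinates are 1-based inclusive
(BLAST tabular convention); internal arrays are 0-based.

The bundled substitution matrix is BLOSUM62 in half-bit units with the
Robinson–Robinson background frequencies. The ungapped Karlin–Altschul
λ is root-found at load time from Σ_ab p_a p_b e^(λ·s_ab) = 1 (giving
0.3176), so the normalisation invariant holds exactly for any matrix a
user loads; the ungapped K (0.134) is exact for BLOSUM62 and used as a
nominal default for user-supplied matrices, whose K a full
Karlin–Altschul computation would otherwise have to estimate.

## Profile construction

A family profile lives in the coordinates of a designated master
sequence (the curated representative; by convention the first/seed
member). Every member is aligned to the master by Smith–Waterman with
affine gaps (open 11, extend 1, gap of length k costs open + k·extend),
best HSP only. Members whose HSP covers less than half the master are
excluded: fragments must not dilute columns. Insertions relative to the
master are dropped from the profile (classic checkpoint-PSSM
semantics) and only counted for diagnostics.

Column summarisation:

- **Weights** — Henikoff position-based: in a column with r distinct
  residue types, a member whose type is shared by s members collects
  1/(r·s); a member's weight is its mean contribution over columns
  where it has a residue, normalised to sum 1. This makes profiles
  invariant to duplicated members and to member order.
- **Effective observations** — N_c for a column is the mean number of
  distinct residue types per column over the column's alignment block
  (the maximal contiguous run of columns covered by the same member
  set), floored at 1. It drives the pseudocount weight α = N_c − 1:
  shallow or uniform blocks lean on the prior, diverse blocks on the
  data.
- **Pseudocounts** — Altschul mixture Q = (α·f + β·g)/(α+β) with
  β = 10, where g_a ∝ Σ_b f_b·p_a·e^(λ_u·s_ab) is the matrix-implied
  target distribution (renormalised; with integer scores the raw rows
  do not sum exactly to 1). β = 0 with a fully conserved single-member
  block degenerates to α+β = 0; the column then keeps its raw observed
  frequencies.
- **Scores** — s_a = round(log(Q_a/p_a)/scale) with scale = ln2/2
  (half-bits), rounding half away from zero, clamped below at −32
  (the log-odds of an unobserved residue under β = 0). Columns with no
  residue coverage (possible when members are hard-masked) fall back to
  the substitution-matrix row of the master residue, with a warning.

The exported ASCII format carries family, length, statistics, gap
penalties, and per position the consensus residue, 20 integer scores
and 20 frequencies at 4 decimals; write∘read is byte-stable.

## Bias masking

Compositional bias is detected by optimal ungapped local alignment of
the sequence against an infinite homopolymer of each residue type
(maximum-scoring contiguous subsequence of per-position scores
s(type, seq_i)); this windowless formulation can flag tracts spanning a
whole sequence. Masking iterates: find the best-scoring tract over all
20 types; if it exceeds the threshold, replace the occurrences of that
residue type inside the tract with X and repeat. Ties break
alphabetically; tract ties resolve to the smallest end, then smallest
start. A tract only counts if it actually contains its residue type —
a rare corner (e.g. an I/V run scoring high against L) that would
otherwise loop forever. The working threshold is 15 in matrix units,
aggressive enough that a 12-copy FG repeat (score ≈ 60) or any
4-residue glutamine run (score 20) is masked, while a maximally diverse
sequence (best self-score 11, for W) is untouched. Masking is hard (X),
because searches use composition-sensitive statistics and soft-masked
residues would still perturb them.

## Search statistics

Scanning is exhaustive dynamic programming — every subject is fully
aligned against the profile (position score of PSSM column i vs subject
residue b is scores[i][b]); there are no seeding or x-drop heuristics.
Desk-scale proteomes (10³–10⁴ proteins) scan in seconds via the
numba-compiled kernel; determinism is part of the contract (first
strictly-maximal cell in row-major order; traceback prefers
diagonal > up > left), so ranked hit lists are reproducible across
platforms and database orderings.

Raw scores become bit scores S′ = (λS − ln K)/ln 2 and E-values
E = m′·n′·2^(−S′), with the BLAST-style edge correction
ℓ = ⌊ln(K·m·n)/H⌋ (H = mean per-column relative entropy of the
profile's implied target frequencies, floored at 0.01 nats),
m′ = max(1, m−ℓ), n′ = max(#seqs, n − #seqs·ℓ).

**Gapped statistics.** Profile scores are half-bit log-odds, but the
statistical λ of gapped alignment is smaller than the score scale: for
BLOSUM62-family scoring with gaps 11/1 the published gapped parameters
are λ = 0.267, K = 0.041, and those are the defaults here (scaled
proportionally if a different score scale is chosen). Using the score
scale itself as λ would overstate bit scores of chance alignments by
~30% and make E-values anti-conservative by orders of magnitude —
enough to manufacture false positives at stringent cutoffs. A
per-profile simulation calibration hook would be the rigorous
alternative; the fixed published pair keeps runs deterministic and is
accurate for the default scoring.

**Composition-based statistics (a dialect).** With CBS on, each subject
of length ≥ 30 gets its own λ: writing the profile partition as
g(λ; q) = Σ_a q_a · (1/L)Σ_i e^(λ·s_ia) with q the subject's residue
composition (one pseudocount per residue), we solve
g(λ_adj; q) = g(λ_global; p) for the largest root in (0, 10·λ_global].
Anchoring to the value the profile attains under the background makes
the background composition an exact fixed point (integer-rounded
scores mean the textbook "= 1" normalisation only holds approximately),
and subjects enriched in high-scoring residues get λ_adj < λ_global,
hence lower bit scores — the intended penalty for biased subjects.
Rootless cases (profile positively biased under the subject
composition) fall back to the global λ with a warning. This is an
explicit dialect of composition-based statistics, not a bit-exact
clone of any BLAST mode. The solver brackets on a 256-point geometric
grid and refines by vectorised bisection (45 iterations, ~1e-9
accuracy), using a per-residue score histogram so the cost is
independent of profile length.

Hit lists keep the best HSP per subject, drop hits above the E-value
cutoff (default 10), sort by ascending E (ties: higher bit score, then
lexicographic subject id) and truncate to max_target_sequences
(default 20).

## Iterative harvesting

Starting from a curated seed set with a family-specific inclusion
E-value (default 1e-5; 1e-10 for repeat-flagged families), each
iteration builds a profile from the current members — hard-masked at
threshold 15, so repeat tracts cannot steer the search, while the final
returned seed set keeps the original unmasked sequences — scans the
(prefiltered) database, and admits new hits under the threshold that
pass a reciprocal check: the matching region of the candidate is
aligned back against a reference seed collection and must hit its own
family best. The run stops when an iteration admits nothing
(converged), at the iteration budget (default 10), or when more than
half of an iteration's would-be admissions fail the reciprocal check —
an automated stand-in for the curator's judgement that a search has
begun pulling unrelated proteins; that iteration is rolled back.
Prefiltering drops entries whose description contains "fragment" or
"partial" (case-insensitive) or whose length is below half the master.

## Benchmark protocol

The gold standard is a species × family boolean matrix with truth
protein ids on the expected-true cells. Detection uses the top-hit
criterion: a cell scores TP only when a truth id is the first hit of
that family's profile against that species' proteome; lower ranks are
reported in the rank matrix but scored FN — this matches the arithmetic
of headline "detected as top hits" counts. Expected-absent cells score
FP when any hit reaches E ≤ 1e-5 (the published evaluations report
FP = 0 without printing their criterion; a significance threshold is
the natural reading), else TN. With multiple truth ids (duplicated
genes) the best-ranked one counts. TPR and FNR are rounded half-up to
one decimal, so they complement to 100 ± 0.1. HMMER3 `--tblout` files
are ingested for cross-method comparison (same format with heuristic
filters on or off); profile-HMM search itself is out of scope, and
tblout carries no alignment coordinates, so those HSP fields are 0.

## Synthetic benchmark

The generator emulates what makes this detection problem hard:
families of homologs diverged from a common core, with substitutions
sampled from the matrix-implied conditional
P(b|a) ∝ p_b·e^(λ_u·s_ab), b ≠ a — so homologs remain detectable by
score, as real divergence keeps them — plus geometric indels
(mean length 2, rate 0.01/site), and repeat/LCR tracts inserted at a
homologous position across members (±2 jitter), so profiles learn them
unless masked. Decoy proteomes are i.i.d. background sequences of
100–400 residues. All outputs are pure functions of a Philox
counter-based seed; an independent identity count (divergence 0.2,
substitutions only) puts mean member-to-core identity at ≈ 0.80,
frozen as the regression band [0.75, 0.88].

The default benchmark is 15 species × 10 families, divergence 0.25,
8 training members per family, 200 decoys per proteome, 25% absent
cells, one held-out member embedded per expected-true cell. Two
families carry compositional bias — one FG-repeat family (12 × "FG")
and one poly-Q family (30 × Q) — with deliberately distinct motifs:
sharing a motif across families reproduces the real cross-family
repeat-match failure mode and would make a zero-false-positive outcome
unattainable by construction; that failure mode is exercised
separately in the masking tests. Biased families carry the stricter
1e-10 inclusion threshold.

What passing this benchmark does **not** show about real data: decoys
are i.i.d. — real proteomes contain paralogs, shared promiscuous
domains (WD40, TPR) and pervasive low-complexity sequence, all of
which generate harder negatives than background noise; divergence is
homogeneous (no rate variation across sites or lineages, no
phylogenetic structure); and family sizes are uniform. Real-data TPRs
should be expected to sit below the synthetic ones.

## Numerical choices and degenerate inputs

- Rounding half away from zero for integer scores; rates rounded
  half-up to 1 decimal.
- Alignment tie-breaks (first strictly-maximal cell; diagonal > up >
  left) and hit-list tie-breaks (E, then bit, then subject id) are
  fixed for cross-platform determinism.
- All-X subjects/members yield empty alignments and are flagged;
  an all-X master makes the family degenerate (error).
- A zero inclusion E-value makes harvesting converge immediately with
  no additions; an empty database is an error for search.
- Effective-length correction floors H at 0.01 nats and never lets
  m′ < 1 or n′ < #sequences.

## Known limitations

- E-values are calibrated to the default half-bit/11/1 scoring; other
  scales reuse proportionally scaled gapped constants rather than a
  per-profile calibration.
- The CBS dialect rescales λ only; it does not re-optimise the
  alignment under per-subject rescaled scores.
- Master-coordinate profiles discard insertions relative to the
  master, so families whose conservation lives in master-absent
  segments lose that signal (the classic PSSM-vs-profile-HMM
  trade-off).
- `ungapped_K` for user-supplied matrices is nominal (BLOSUM62's
  value), affecting only ungapped statistics, which nothing downstream
  currently consumes.
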