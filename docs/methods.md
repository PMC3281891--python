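# Methods

This note documents the models, parameter choices and numerical decisions
behind `pqloop`, and what the synthetic benchmarks do and do not show.

## Synthetic family model

`FamilySpec` describes a 7-TM membrane-protein architecture:

| parameter | default | meaning |
|---|---|---|
| `n_helices` | 7 | TM helices per full-length protein |
| `helix_len` | 21 aa | length of each helix |
| `loop_len_range` | 3–19 aa | connecting loops (short, < 20 aa) |
| `n_term_len` / `c_term_len` | 1 / 15 aa | lumenal N-tail / cytoplasmic C-tail |
| `duplication` | on | C-terminal 3-helix block is a diverged copy of the N-terminal block |
| `motif_spec` | PQ in loops 1 and 5 | planted loop doublets, substitution rate ×0.05 |
| `conserved_cols` | 2 basic + 1 serine | near-invariant columns, rate ×0.05 |
| `n_members` | 20 | family size |
| `divergence` | 0.5 subst./site | helix substitution rate; loops ×1.5 |
| `indel_rate` | 0.01/site | loop/termini only, geometric length (mean 2) |
| `min_helix_kd` | 3.0 | hydrophobicity floor for ancestral helices |

Helices draw from a composition with 85% of the mass on Kyte–Doolittle-
positive residues, dominated by I/L/V as in real TM segments; the 15%
remainder is small/polar (G, T, and deliberately little serine — 2% — so
that near-invariant serine columns are overwhelmingly the planted ones).
Loops and termini draw from a database-average background composition.
Ancestral helices are rejection-sampled until their mean Kyte–Doolittle
value reaches `min_helix_kd`: a TM helix must be hydrophobic enough to
partition into the bilayer, and without this constraint the weak lower tail
of a random composition produces "annotated" helices that no hydropathy
method could or should recover.

The duplicated C-half is constructed by copying the N-half block (helices
and internal loops) and applying `divergence` substitutions, which mimics an
ancient duplication followed by family-wide divergence.  Planted features
are overwritten after the copy.  The two conserved basic columns sit at the
C-terminal ends of the loops following helices 1 and 5 — the membrane
interface, where conserved charged residues reside in real polytopic
proteins — offset a couple of residues from the helix so that a charged
side chain does not sit inside the helix's hydropathy window.  The serine
column sits at the midpoint of helix 4.

Members evolve on a star phylogeny: per-site Poisson substitutions with a
hydrophobicity-preserving proposal inside helices (proposals may silently
redraw the same residue, so realised change is slightly below nominal),
background proposals elsewhere, and indels restricted to loops/termini
outside planted features.  Every member carries a coordinate map back to
the ancestor, from which the by-construction alignment, per-member TM
spans, and motif positions are derived (`FamilyTruth`).

What the generator does **not** model: phylogenetic structure (no tree,
only a star), codon-level evolution, length variation of helices,
orthologue-specific domains, signal peptides and re-entrant loops.
Benchmark results therefore show that the pipeline recovers planted
structure under idealised divergence, not that it matches PolyPhobius or
HHsearch on real proteomes.

## Profiles and scoring

A profile is a per-column emission model over the 20 amino acids.  Match
columns are alignment columns with ≤ 50% gaps (ties count as match).
Sequences are weighted by the Henikoff position-based scheme; the effective
sequence count is the number of distinct rows, so duplicated rows do not
sharpen the profile.  Emissions are `(n_eff·freq + α·background)/(n_eff+α)`
with pseudocount weight α = 1 by default.  Non-standard residues map to X,
which scores 0 (background) everywhere.

Local alignment uses affine gaps (open 11 bits, extend 1 bit) with
log₂-odds emission scores; profile–profile alignment scores column pairs by
the co-emission ratio `log₂ Σₐ pₐqₐ/fₐ`.  The dynamic program is vectorised
along the target axis; the horizontal gap state is computed exactly with a
cumulative-max scan (valid because gap-open ≥ gap-extend, so an optimal
path never opens a horizontal gap out of a cell whose best path already
ends in one).  Ties in the traceback resolve toward the diagonal, and the
best end cell is chosen in row-major order, making results deterministic.
On profiles of ≤ 5 columns the DP is tested against exhaustive enumeration
of all local alignments.

E-values come from a maximum-likelihood Gumbel fit (`scipy.stats.gumbel_r`)
to the scores of seeded null samples: length-matched i.i.d. background
sequences in sequence mode, column-shuffled profiles in profile mode;
`E = N·exp(−λ(s−μ))`, clamped to [0, N].  Calibration requires ≥ 100 null
samples and errors on degenerate variance.

**Stratified profile shuffle.**  For duplication detection the profile-mode
null permutes TM columns among TM columns and loop columns among loop
columns, keeping positions fixed.  An unstratified shuffle destroys the
hydrophobic block architecture, and since *any* two helix-bundle profiles
align well by composition alone, it would call unrelated halves homologous
(~77% false positives in development measurements).  The stratified null
preserves composition and architecture, leaving true column-to-column
correspondence as the only signal; with it, detection power at divergence
0.5 is ≥ 90% and the false-positive rate on independently drawn halves is
≤ 5% (the package's acceptance thresholds).

## Search loop

`iterate_search` alternates: build profile (TM annotation carried through
match-column indexing) → calibrate → score all targets → include hits with
`E < 10⁻³` that satisfy the coverage rule → realign the included set to the
profile → repeat until the included set is unchanged (or 10 iterations;
oscillation is flagged).  The *reported* accepted set uses the strict dual
criterion `E < 10⁻⁵` **and** coverage of every TM segment by ≥ 5 residues
(`min_segment_overlap`; the value is a documented choice — the source
protocol requires "all 7 helices matched" without quantifying overlap).
Re-running the search seeded with the converged alignment reproduces the
same accepted set; only scores and E-values change.

`align_to_profile` places each sequence by its local-alignment traceback:
match columns become alignment columns, unaligned residues (including
tails) go into left-justified insert blocks.  The > 40%-identity direct
pairwise pre-merging hook (`identity_split`) is accepted in the
configuration but inert: all sequences are aligned via the profile, which
is simpler and makes no measurable difference on the synthetic families.

## Topology

Per sequence: Kyte–Doolittle means over a 19-residue window (clipped at the
sequence ends, so terminal helices next to the 1-residue N-tail are not
lost), threshold 1.6 marks the window's centre residue; marked runs
separated by ≤ 3 positions are bridged (a single noisy window otherwise
splits a genuine helix into two sub-minimum fragments); runs ≥ 15 residues
become helices; runs > 35 split recursively at the hydropathy minimum,
constrained to lie ≥ 15 positions from the run ends (hydropathy sags toward
run boundaries, so an unconstrained minimum erodes edges instead of cutting
the loop between merged helices).

Consensus over an alignment: a column is TM when > 50% of the sequences
with a residue there lie inside one of their predicted segments; only
columns occupied by more than half of the rows participate in run logic
(sparse insert columns would stretch runs in column space); consensus runs
≥ 12 columns become segments, with the same length-based split on the
column-mean hydropathy.  On 100 default synthetic families the consensus
returns exactly 7 helices in ≥ 95% of cases and 3 on half-protein families;
consensus accuracy is never below the mean single-sequence accuracy.

Sidedness is annotation, not prediction: the N-terminal side (default
lumen, as established experimentally for the KDEL receptor) alternates
through the helices, placing the C-terminus cytoplasmic for 7 helices.

## Duplication and half-proteins

A 7-segment profile splits at the midpoints of the loops flanking helix 4:
N-core = helices 1–3, C-core = helices 5–7, the middle helix in neither.
`detect_duplication` aligns the cores and judges the score against the
stratified shuffled null; verdict threshold `E < 10⁻³` (configurable,
deliberately separate from the search's `10⁻⁵`: the E-value scales of the
two calibrations differ).  At zero divergence the core alignment covers all
3 N-half TM segments.  `classify_half_protein` labels significant hits with
incomplete coverage as N- or C-half homologues ({1..4} / {4..7} in 1-based
segment indices) and flags sequences matching both cores — which generated
half-proteins do, since the two cores are themselves homologous (the
situation of the three short human proteins footnoted in the family table).

## Conservation, motifs, tree

Column conservation is the relative entropy (bits) of the pseudocounted
(α = 0.2), sequence-weighted column distribution against background,
masked at > 50% gaps.  The class-column detector requires score ≥ 2 bits
**and** an unweighted carrier fraction ≥ 0.9 for the majority residue; on a
shallow 20-member family, ordinary columns are moderately conserved simply
because members share a recent ancestor, and the carrier-fraction filter is
what separates planted near-invariant columns from that baseline.  Motif
search scans ungapped member sequences (optionally restricted to loop
columns) and reports column spans carried verbatim by ≥ 50% of members.

Distances are p-distances over mutually ungapped columns (optional
`-ln(1-p)` Poisson correction); pairs with no shared columns get distance 1
with a warning.  Trees are classical neighbor joining (scikit-bio), with
negative branch lengths clamped to zero and logged; two taxa produce the
single-edge convention of two d/2 branches.  On additive 4-taxon matrices
NJ recovers the generating split in 100/100 trials.

## Problem sizes and determinism

The packaged benchmarks use 20-member families, 200-decoy proteomes,
100-seed sweeps, 120–300 null samples per calibration — sizes at which
every statistic above is stable while the full test suite runs in a few
minutes.  All randomness flows from explicit integer seeds through
`numpy.random.default_rng` seed sequences; identical (spec, seed) inputs
give byte-identical outputs, and the pipeline manifest records per-stage
output hashes to make end-to-end determinism checkable.

## Known limitations

E-values are internally calibrated and not numerically comparable to
HHpred/HMMER E-values on public databases.  The simplified profile (no
insert-state emissions, fixed gap penalties) ranks homologues correctly on
the synthetic benchmark but is not a Plan-7 HMM replacement.  The topology
predictor is a transparent hydropathy rule, not a trained HMM like
Phobius; it presumes helices near the generator's architecture (15–35
marked residues) and has no concept of signal peptides or re-entrant
loops.  Orientation is taken from annotation, never inferred (no
positive-inside rule).
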