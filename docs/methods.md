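# Methods

## Model

A dimer template is a two-chain structure whose interface is the set of
contact residue pairs: one residue per chain with at least one heavy-atom
(non-hydrogen) pair within 4.5 Å, the cutoff being inclusive. Waters,
non-polymer hetero groups and hydrogens are excluded; for alternate
locations the highest-occupancy conformer of each atom is used, and only
the first model of a multi-model file is read. Modified residues are
mapped to their parent standard residue when the chemical-component
tables provide a one-letter code, else skipped with a warning.

Template quality control follows strict inequalities: resolution below
3.0 Å, each chain longer than 35 residues, more than 25 contact pairs,
and more than 5 distinct contact residues contributed by each chain.
A missing resolution fails QC by default (configurable). Domain-pair
interaction requires more than three contact residues inside each
domain's boundary; cross-chain domains accumulate counts over their
chains.

## Profiles and pairing

Each chain contributes one multiple sequence alignment with the template
sequence as a distinguished row. Rows more than 95% identical to the
template are purged; identity is counted over columns where both rows are
non-gap, divided by the shorter ungapped length (the denominator is not
dictated by the construction, so this is a documented package choice).
The estimator needs *joint* observations of the two chains, which forces
some rule for matching rows across the two alignments; we pair rows by a
source-organism key carried in the FASTA header (`key=<tag>`) or a
sidecar TSV. Keys present on one side only are dropped; duplicate keys
keep the row with fewest gaps. The two template rows are always paired —
the template's own contact pair is an observation. A row is skipped at a
contact position when either side shows a gap or non-standard residue
(no half-counts).

Observed pair frequencies are pooled as group-pair symbols under a
9-group reduced alphabet — (Ala, Gly), (Val, Met, Leu, Ile),
(Pro, Ser, Thr), (Phe, Tyr, Trp), (Cys), (His, Arg), (Lys), (Asp, Glu),
(Asn, Gln) — so conservative substitutions do not fragment the counts.
The alternative environment-based grouping of Saha et al. (Ala with Val,
Pro with the aromatics, Arg with Lys) is included for comparison, and
`group_sd_table` quantifies which partition is faithful to a pair
potential: cell (g, h) is the population standard deviation (ddof = 0;
the quantity is a descriptive spread over a fixed finite set, not a
sample estimate) of potentials over unordered residue combinations of
the two groups. Raw residue-pair counting is available via
`scheme=None`.

## Scoring

For each contact position, with f the observed symbol frequency,
`g_ij = P_i P_j e^{S_ij}` the potential-derived pseudocount frequency,
`α = n_distinct − 1` and `β = 5`:

    Q_ij = (α f + β g_ij) / (α + β),    score(i, j) = ln(Q_ij / (P_i P_j))

Scores use the natural logarithm (the base is a convention; it cancels in
the normalized energy). The full table is stored as R × 400 ordered
residue pairs (chain-A residue first); a partner-fixed 20-wide slice per
position is recoverable from it. The f term is pooled at group level
while g and P stay at residue level: the reduced alphabet expresses
tolerance in what counts as an observation, not in the prior. With
α = 0 the score equals `S_ij` exactly — the anchor identity tying the
position-specific and general scoring systems together. A column with no
usable observations falls back to α = 0 with a warning.

The pseudocount formula needs `e^{S}` to *enrich* favorable pairs, i.e. a
log-propensity convention where positive values mean interface-enriched.
Energy-like matrices (lower = more favorable) are accommodated by the
`favorable_direction` metadata on the potential; the bundled stand-in is
positive-favorable.

A candidate pair aligned onto the two chains scores the sum of
`score_r(x_r, y_r)` over contact positions with both sides aligned;
unaligned positions contribute zero, so dividing by the template
self-energy penalizes candidates that lost part of the interface — the
missing-binding-domain failure mode. Classification at normalized energy
≥ 0.4 (inclusive); 0.5 is the conservative setting for multi-organism
screens. The general interfacial energy sums `S` over the same covered
positions and serves as the baseline. A template whose self-energy is
not positive cannot normalize and is reported as unusable rather than
silently passed.

## Template libraries and related dimers

Sequence clustering and structural alignment are consumed as inputs
(cluster membership and residue-correspondence TSVs); the package
implements the selection logic. A cluster representative is the member
with the best resolution among those whose contact-pair count exceeds
the cluster mean; when no member exceeds the mean the fallback is best
resolution overall, with lexicographic id as the final tie-break (the
fallback and tie rules are package choices — the selection rule is
ambiguous when all counts are equal). Pair coverage
`PC = NCP_M² / (NCP_AB · NCP_A′B′)` is undefined (not zero) for an empty
interface; PC ≥ 0.4 (inclusive) calls two related dimers the same
interaction type, and dimer-pair identity is the minimum of the two
chain identities.

## Screening and evaluation

Candidates are the Cartesian product of per-chain homology hits at
E-value ≤ 1e-3; an identity limit removes candidates where either chain
exceeds it (strict >). Ranked lists break score ties pessimistically
(negatives before positives), so reported AP is a lower bound.
Unannotated candidates are handled in both modes used in practice:
counted as negatives, or dropped before ranking. The error sweep uses
the balanced error (FN/|pos| + FP/|neg|)/2 with predictions positive at
score ≥ t; a literal variant with transposed denominators is kept behind
a flag for comparison. The expression check computes Pearson r on
pairwise-complete observations (≥ 3 required; constant profiles dropped
and counted) and a one-sided Welch two-sample t-test — Welch rather than
pooled-variance because the prediction and null sets have no reason to
share a variance. Self-pairs must be excluded by the caller since their
correlation is identically 1.

## Synthetic study conditions

The fixture generators are pure functions of (arguments, seed) and
emulate the statistical structure the estimator assumes, not realistic
protein geometry or phylogeny:

* **Toy dimers** place compact 4–5-atom residues on a lattice: chain-A
  residues 8 Å apart, designated contact partners 4 Å across the
  interface, everything else 40 Å away. Designated pairs have minimum
  heavy-atom distances of 3.2–4.0 Å and all other inter-chain distances
  exceed 5.5 Å, so the ground-truth contact map is unambiguous at the
  4.5 Å cutoff. Defaults: 40 residues per chain, 30 contacts,
  resolution 2.0 Å — a template that passes QC.
* **Paired MSAs** (50 rows) substitute interface columns within the
  9-group alphabet at rate 0.3 and across groups at rate 0.05;
  non-interface columns substitute uniformly at rate 0.3 (a typical
  divergence for confidently homologous hits, and low enough that no row
  trips the 95% purge).
* **Screening benchmarks** designate 20 positive pairs (interface
  conserved up to within-group substitution) and 20 negative pairs that
  lose 70% of their contact positions. Negatives alternate between the
  two failure modes the method is meant to catch: *missing-domain*
  (ablated positions unaligned) and *mutated-interface* (ablated
  positions aligned but substituted across groups on one side). The
  second mode is the discriminating one — a generic potential still
  scores those pairs near the template's own general energy, while the
  position-specific profile does not. Crossed pairs (one designated
  pair's A protein with another's B protein) stay unannotated.
* **Expression profiles** give positive pairs a shared latent response
  (30 conditions, noise SD 0.5) and negatives independent noise.

Passing tests on these fixtures shows the estimator and its evaluation
machinery are correct and well-calibrated under the assumed substitution
model; it does not show performance on real structures, where contact
geometry, alignment quality and paralogy are all harder.

## Numerical choices and limitations

* Contact extraction reduces an all-atom distance matrix to per-pair
  minima; on fixtures it agrees exactly with an exhaustive atom-pair
  scan.
* Scores are finite whenever P is strictly positive; the composition
  loader enforces positivity and unit sum (1e-6 tolerance) and
  symmetrizes an asymmetric matrix by averaging, recording that in the
  potential's provenance.
* Serialization (JSON) round-trips scores, self-energy and the stored
  contact positions bit-exactly; the serialized PSSM is self-contained
  for scoring candidates without the structure.
* Replicate seeds in the acceptance script are derived as
  `seed * 1000 + replicate` (kept below 2³¹).
* The package does not run PSI-BLAST, structural alignment, biological-
  unit assignment, or domain assignment; their outputs are consumed as
  tabular inputs. Antibody-like templates — whose interaction types are
  known to be poorly conserved — are not detected automatically; use a
  blocklist.
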