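# Methods

This note documents the models and procedures implemented in
`aptasearch`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic benchmark
does and does not establish.

## Sequence encoders

All encoders map a variable-length sequence to a vector whose dimension
is a pure function of the encoder parameters. Unit order is lexicographic
over the alphabet everywhere, so serialized models are portable across
machines. Nucleotide input is normalized first: case-folded and thymine
replaced by uracil, so DNA-notation records and RNA records encode
identically. Ambiguity codes (N, X, B, Z, …) are rejected with the
offending position rather than imputed.

| family | alphabet | dimension | parameters (default) |
|---|---|---|---|
| k-mer composition (AAC/DPC/TPC and the RNA k-mer block) | either | \|A\|^k | k ∈ {1,2,3} |
| auto-covariance (DAC/TAC) | RNA | P·lag | unit 2 or 3, max lag 2 |
| cross-covariance (DCC/TCC) | RNA | P(P−1)·lag | as above |
| combined (DACC/TACC) | RNA | P·lag·P | concatenation of the two |
| PseKNC | RNA | 4^k + λ | k ∈ {2,3}, λ = 2, w = 0.05 |
| PseAAC | protein | 20 + λ | λ = 10, w = 0.05 |
| conjoint triad | protein / RNA | 343 / 64 | 7 classes / 4 bases |
| CTD | protein | 147 | 7 attributes × 3 groups |

Covariance encoders use the centered-product form
AC(p, l) = (1/(L′−l)) Σᵢ (Pₚ(i) − P̄ₚ)(Pₚ(i+l) − P̄ₚ) over the L′
overlapping units, ordered property-major/lag-minor. PseKNC/PseAAC follow
the classic type-I construction: a composition block and λ sequence-order
correlation factors θⱼ (mean squared difference of standardized property
vectors j units apart), jointly normalized by 1 + w·Σθ so the vector sums
to 1. The conjoint-triad descriptor counts class triads and rescales them
as (f − f_min)/f_max, bounding entries in [0, 1]. CTD records, per
attribute, the three group fractions, the three cross-group
adjacent-pair frequencies, and the positions (as fractions of L) of each
group's 1st/25%/50%/75%/last occurrence; the quantile occurrence index is
max(1, ⌈q·m⌉) for a group with m occurrences, zeros for absent groups.

### Property tables

The covariance and pseudo-composition encoders need numeric
physicochemical indices per unit. These are reference data, not model
code, and ship as versioned TSVs (`src/aptasearch/data/`), overridable
per encoder. The dinucleotide table carries Turner nearest-neighbour
stacking free energies (ΔG°37, kcal/mol), GC fraction and purine
fraction; the trinucleotide table uses GC fraction, purine fraction and
the mean stacking energy of the unit's two steps (trinucleotide-specific
measured indices are not as standardized, so a compositional derivation
was preferred over copying any one lab's scale). The amino-acid table
holds the classic PseAAC triple: Eisenberg consensus hydrophobicity,
Hopp–Woods hydrophilicity and side-chain mass. All property columns are
standardized to mean 0 / variance 1 across units before entering any
correlation term, so the files' measurement units cannot affect encoder
semantics. CTD groupings are the canonical 7-attribute/3-group
partitions; conjoint-triad classes the canonical 7-class
electrostatic/hydrophobic partition. Model archives record the tables'
SHA-256 checksums and verify them on load.

PseKNC's correlation factors are computed over k-mers of the same k as
its composition block (dinucleotide table for k = 2, trinucleotide for
k = 3), keeping the descriptor internally consistent; parts of the
literature always correlate dinucleotides regardless of k, which would
be a one-line change via the table parameter.

## Interaction classifier and model selection

The classifier is a scikit-learn random forest over the concatenation of
one aptamer encoding and one protein encoding. Class imbalance is
handled with `class_weight="balanced"` (inverse class frequencies). The
interaction score of a pair is the forest's positive-class probability —
the mean positive vote over trees — always in [0, 1].

Model selection trains `repeats` candidates per encoder combination
(default 2000), each with a tree count drawn uniformly from [30, 200],
evaluates each on the held-out split, and returns the MCC-best model.
MCC ties break to the fewest trees — the selected model is invoked once
per search iteration, so a slim forest directly reduces generation time —
and remaining ties to the earliest-trained candidate. Metrics with a zero
denominator are reported as 0 with a degeneracy flag rather than raising,
so selection survives candidates that collapse onto one class. The run
seed spawns one child seed per candidate (tree-count draw plus forest
RNG), making the whole selection reproducible from one integer; the full
leaderboard is retained. As a pure runtime optimization, the feature
matrix of each encoder combination is computed once and shared by its
`repeats` candidates.

## Sequence sampler

The search tree's arity is 8: each node is a *directional base*, a
nucleotide tagged prepend/append. Keeping both sides at every level
permits candidates that grow in both directions; on an empty core,
prepend-X and append-X both realize "X", a first-level redundancy that is
deliberately kept rather than collapsed, preserving the uniform 8-way
branching.

Each of the N rounds runs M iterations of: UCT selection
(s/n + C·√(ln N_parent / n); unvisited children score +∞ so every
instantiated child is tried once before re-exploitation; exact UCT ties
break uniformly at random), random expansion of one missing child,
uniform random playout to the round's depth limit, reconstruction of the
implied full-length sequence, scoring, and backpropagation (every node on
the path gains n += 1, s += score). Exactly one full-length candidate is
emitted per iteration, so a run produces N·M scored candidates. The
committed base after each round is the root child with the highest *mean*
score s/n — raw cumulative score confounds visit counts — with ties going
to the larger visit count, then the lexicographically smallest label.
Defaults are M = 5000 and C = 12; both are exposed. Scores are memoized
per sequence string (identical playouts recur), which changes no results.
The root seed derives per-round child seeds, so any round is reproducible
in isolation.

## Structure deduplication

Identity of secondary structure, as exact dot-bracket string equality, is
the redundancy criterion: within a structure group only the
highest-scoring candidate survives (score ties keep the
lexicographically smallest sequence), and survivors are ranked by score.
The default folder is a builtin Nussinov-style maximum base-pairing
dynamic program — pairs AU/UA/GC/CG/GU/UG, minimum hairpin loop of 3
unpaired bases, deterministic traceback that prefers pairing the left
end, with the leftmost admissible partner, whenever pairing attains the
optimum — chosen so the test suite and default pipeline are hermetic. A
ViennaRNA backend (python bindings or `RNAfold`) is available per
configuration and errors loudly when missing, never falling back
silently. The two backends produce different structures (maximum pairing
vs minimum free energy); this only changes which candidates merge.
Structure is used for deduplication only; no binding-affinity meaning is
attached to it, and free-energy values, suboptimal ensembles and
pseudoknots are out of scope.

## Synthetic benchmark

The generator emulates the shape of real API benchmarks: RNA aptamers of
20–90 nt, proteins of 50–400 aa, a 1:3 positive:negative ratio, and a
bounded panel of target proteins reused across pairs (default 8, as real
benchmarks repeatedly measure the same targets). The interaction rule is
planted: each protein maps, through a SHA-256 hash of its first
`motif_length` (default 4) residues, to an RNA motif; positives carry
their protein's motif at a uniform position; negatives are panel-level
non-binders, sampled to contain no length-3 substring of *any* panel
protein's motif (built base-by-base, drawing uniformly among bases that
do not complete a forbidden trigram). Excluding the whole panel's
trigram vocabulary — not merely the pair's own motif — makes the true
labelling rule exactly representable by trinucleotide-level aptamer
features, so classifier failures indicate implementation defects rather
than an unlearnable construction. Label noise flips training labels with
probability `noise_rate`; held-out splits are generated with clean labels
(configurable), because held-out metrics are meant to measure recovery of
the true rule — against noisy test labels even a Bayes-perfect classifier
at a 1:3 ratio and 10% flips caps near MCC ≈ 0.76, which would conflate
label corruption with model quality.

What passing the synthetic suite shows: encoders, training, selection,
search and deduplication compose correctly, and a recoverable signal is
in fact recovered end to end. What it does not show: performance on real
aptamer data — real binding depends on structure and chemistry far beyond
a planted sequence motif, real negatives are not motif-free by
construction, and real benchmark metrics (typically MCC ≈ 0.4–0.5)
should not be compared with the near-perfect synthetic values.

## Problem sizes and numerical choices

The test suite exercises the pipeline at deliberately modest scales
chosen as the smallest sizes at which each property is meaningful:
selection sanity checks use a few-hundred-pair dataset with the
64-dimension aptamer conjoint triad and amino-acid composition (fast to
encode, fully learnable); the default-settings checks run one genuine
M = 5000 round and one genuine 2000-candidate selection on a tiny
dataset; sampler convergence uses N = 15, M = 2000 with a rigged 3-mer
scorer over 5 seeds; end-to-end learnability uses 200/600 training pairs
with 10% label noise at 50 selection repeats. The exhaustive structure
oracle enumerates all nested pairings for lengths ≤ 12, where
enumeration is exact and cheap.

Edge conventions worth knowing: metrics with empty denominators are 0
(flagged); scoring rejects values outside [0, 1]; folding of sequences
shorter than 5 bases is all-dots by construction; `top_k` on a smaller
set returns the whole set; encoder preconditions (minimum lengths, λ
bounds, k ∈ {2, 3}) raise informative errors rather than truncating.

## Known limitations

- The builtin folder maximizes pairings, not free energy; its structures
  are coarser than ViennaRNA's MFE structures.
- Composition-style encoders ignore positional and structural context;
  the classifier cannot express rules beyond what these features carry.
- The sampler commits greedily (one base per round); it cannot revise an
  earlier commitment, and diversity across the final list comes only
  from within-round playouts.
- Docking, 3D structure prediction and any experimental validation are
  explicitly outside this package's scope.
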