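# Methods

## Problem setting

Ligand-based virtual screening ranks a large compound deck by similarity
to known actives. This package implements and evaluates strategies for
combining two complementary similarity channels — 2D fingerprint
similarity and 3D shape similarity — which are known to retrieve
substantially different active chemotypes early in their hit lists.

## Library preparation

Raw compounds pass through a fixed pipeline:

1. **Salt stripping** before any other check: the largest organic
   (carbon-containing) fragment by heavy-atom count is retained; ties
   are broken by lexicographic order of canonical SMILES. The retained
   fragment's charge state is preserved (no neutralization); this choice
   is recorded here rather than assumed, since either convention is
   defensible and only scaffold/fingerprint identity matters downstream.
2. **Molecular weight window** 250–1500 Da (inclusive).
3. **Element filter**: only H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I.
4. **Stereo completeness**, applied to active candidates only: an
   active with an unassigned tetrahedral stereocenter is discarded,
   because actives may serve as single-conformer 3D queries and must be
   fully defined. Library compounds with undefined centers are retained;
   stereoisomer enumeration is a conformer-generation concern.

Activity labels come from potency records: a compound measured in Kd,
AC50, IC50, Ki, EC50 or Potency below 10,000 nM is *active*; above
20,000 nM, *inactive*. Values in the [10,000, 20,000] nM gap, and any
other measurement type, are left *unlabeled* and excluded from both
classes — the conservative reading of the two one-sided rules.

Scaffolds are plain Bemis–Murcko frameworks (ring systems plus linkers,
atom and bond types retained, substituents removed); acyclic molecules
map to the sentinel `ACYCLIC`. Scaffold equality is string equality of
canonical SMILES.

## Screening channels

**2D.** Morgan circular fingerprints, radius 2, 1024 bits, binary.
Ranking by Tanimoto coefficient c/(|a|+|b|−c). Hashed bit patterns are
toolkit-specific and deliberately not an interchange contract; only
similarity values and rankings are.

**3D.** The shape channel is an interface with the two-component score
contract `total = shape + color ∈ [0, 2]`, each component in [0, 1].
The shipped reference scorer is alignment-free: a conformer is reduced
to twelve USR distance-distribution moments (mean, standard deviation
and cube-rooted third central moment of the atom distances to four
reference points: centroid, closest-to-centroid atom, farthest atom,
farthest-from-farthest atom) plus the analogous twelve moments per
pharmacophore class (donor, acceptor, aromatic, hydrophobe; SMARTS
definitions shipped as a versioned YAML config). Similarity between
descriptors a, b is `1 / (1 + mean |Δ moments|)` for shape, the same
expression over the concatenated class moments for color. The
descriptor is exactly invariant under rigid rotation and translation;
reflection is not a symmetry (the skew moments can distinguish
enantiomeric conformers), which mirrors the behavior of overlay-based
shape engines. A class with no atoms contributes zero moments — two
molecules both lacking donors agree perfectly on the donor term, which
is the desired behavior for a similarity score.

Library compounds are conformer ensembles (at most 200 conformers); a
compound's score is the best total over its ensemble (best-overlay
convention). Queries are single conformations. Scores computed by an
external engine can be injected via `load_external_scores`, bypassing
the reference scorer but keeping every downstream contract.

## Fusion strategies

**MAX fusion** (multi-query): each library compound receives the
maximum of its per-query scores; compounds are re-ranked by the fused
score, ties broken by ascending compound id. With one query this is the
identity; it is invariant to query order, and adding a query can only
raise a compound's fused score.

**Parallel selection** (two methods): an empty list is filled by rounds
that transfer the next `from_a` not-yet-included compounds of list A,
then the next `from_b` of list B. A compound already present is skipped
and replaced by the next unique entry *from the same source list*.
Rounds repeat until the requested size is reached; an exhausted source
cedes its slots to the other. The 2D list contributes first within each
round by convention (the alternative shifts ranks by at most one
position); block interleaving is used for imbalanced ratios (e.g. nine
from A, then one from B, per round). The combined list is rank-only:
scores from different methods are incommensurable.

**Integrated**: balanced (1:1) parallel selection applied to the
MAX-fused multi-query lists of the two channels. With single-query
inputs it coincides exactly with balanced parallel selection of the two
baselines.

Because evaluation of a combined list needs a full ordering, parallel
selection is run to full library size, which yields a permutation of
the deck; AUC on such rank-only lists uses positions as scores (no ties
are possible by construction). Whether a combined-list AUC should
instead be defined via score normalization is an open modeling choice;
full-library interleaving is the reading implemented here.

## Metrics

All metrics are computed over the labeled universe; compounds present
in a ranking but absent from the label map (the removed queries) are
ignored in both numerator and denominator.

- **AUC**: probability that a random active outranks a random decoy,
  computed by exact integer pair counting (Mann–Whitney form).
- **EFk%**: active rate in the top `ceil(n·k/100)` compounds (minimum
  one, so small decks always have a non-empty top list) divided by the
  deck's active rate. Its attainable maximum is n/actives.
- **SRRk%**: fraction of the distinct scaffolds of library actives that
  appear among the actives in the top k%.
- **Scaffold overlap**: with recovered-scaffold sets A and B of two
  rankings and T total active scaffolds, the report gives |A\B|/T,
  |B\A|/T, |A∩B|/T and |A∪B|/T; the first three sum to the fourth by
  construction.
- **Paired Wilcoxon signed-rank test**, two-sided: zero differences are
  dropped; for ≤ 25 non-zero pairs the p-value is exact, computed by
  dynamic programming over the signed-rank-sum distribution conditional
  on the observed |difference| midranks (valid under ties; doubled
  ranks keep the arithmetic integral); beyond 25 pairs the normal
  approximation with tie correction is used. No multiple-testing
  correction is applied; reports state this.

## The synthetic benchmark

Absolute screening performance on real decks depends on the particular
targets, decks and engines used; what the synthetic benchmark reproduces
is the *structure* of the problem and the *qualitative ordering* of the
strategies, at desk scale.

**Latent deck.** Default study conditions: 200 actives in 20 scaffold
families (10 members each), 5000 decoys, channel overlap 0.2. Every
compound carries unit latent vectors: one for channel A (fingerprint
analogue) and two for channel B (shape and color halves, so channel B's
score is a genuine two-component total in [0, 2]). Channel similarity is
cosine mapped to [0, 1] per component. Families are *recognizable* in
both channels (fraction `channel_overlap`), A only, or B only (remainder
split equally, A first on odd remainders). Family members in a
recognizable channel sit at `normalize(centroid + 0.05·g + 0.02·h)` with
standard-normal g, h in 32 dimensions — tight enough that within-family
similarity (~0.96 cosine) clears the upper tail of 5000 background
cosines (~0.65). Centroids carry a weak shared "actives direction"
(weight 0.3), so actives of *other* recognizable families score mildly
above background, lifting baseline AUC above chance, as observed on real
decks. In a channel where its family is not recognizable, an active
still carries the shared direction but no family clustering — it behaves
like a singleton chemotype there. This last choice matters: if such
actives were pure background, queries from them would inject pure noise
into MAX fusion and adding queries could *degrade* the fused ranking,
which contradicts how real queries behave (any informative
representation retrieves at least the query's close analogs).

An optional `contamination` flag plants latent actives among the decoys
(default off), emulating the small fraction of presumed-inactive
screening compounds that would test active.

**Protocol.** A query pool of 30 actives is drawn once (dataset seed,
default 2506) and removed from the evaluated deck, so the deck is
identical across repeats and sizes. Each of 30 repeats (seeds 0–29)
draws 5 queries from the pool; the size-s query set is the first s of
the draw, so smaller sets are nested in the five-query set. Strategies
`2d`/`3d` are evaluated at every size (size 1 is the baseline; the
`_multi` names are aliases), giving 5 × 30 × 2 = 300 single-method
screens; `parallel` combines the single-query baselines (reported at
size 1, optionally over a ratio sweep); `integrated` combines the fused
lists at every size and coincides with `parallel` at size 1. Summaries
report mean and standard deviation over repeats; with several decks
("targets"), values are first averaged within deck, then across decks.

**What passing tests show — and what they do not.** The latent deck
reproduces, by construction, partial channel orthogonality, family
structure and actives-vs-background separation; trends measured on it
(parallel selection beating each baseline on EF1%, monotone multi-query
gains, union scaffold recovery exceeding either channel, a few-percent
both-channel overlap) are scaled-down analogues, not predictions of
absolute performance on real decks. The generator does not emulate
activity cliffs, analog-series bias in decoy selection, assay noise, or
target-to-target variability.

**SMILES fixture.** Six family templates and ten decoy templates
(synthetic constructions, chosen so every template × R-group combination
parses, passes all preparation filters, carries no stereocenters, and
yields one shared Murcko scaffold per template, all sixteen distinct)
are enumerated with ten acyclic R-groups. The default fixture (3
families × 5 R-groups + 50 decoys) drives the real RDKit screening stack
end to end in seconds.

## Numerical conventions and problem sizes

- Top-k cutoff: `ceil(n·k/100)`, minimum 1; recorded in every report.
- Ranking ties: descending score, then ascending compound id —
  deterministic everywhere.
- All randomness flows through explicit seeds (dataset-level default
  2506; per-repeat plan seeds 0..29 by default); the entire experiment
  table is bit-reproducible given the config.
- Test and acceptance runs use the default study conditions above
  (5200-compound deck, 30 repeats), which complete in well under a
  minute; the generator scales linearly in deck size if larger decks
  are wanted.
- Degenerate inputs fail loudly: empty conformer sets, rankings without
  actives or without decoys, all-zero Wilcoxon differences and
  mismatched universes raise instead of imputing.

## Known limitations

- The reference shape scorer is a moment-based stand-in with the same
  score contract as overlay engines, not a reimplementation of any
  engine's values; absolute 3D scores are not comparable across
  scorers (hence the `method_tag` and descriptor version checks).
- Conformer generation is out of scope by design: any embedder that
  produces ≤ 200 conformers per compound can feed the SDF reader.
- The latent channels are linear-geometry models of similarity; they
  carry no chemistry. Conclusions about specific chemotypes require the
  chemistry path (fixture or real decks).
- Combined-list AUC is defined via full-library interleaving (see
  above); alternative definitions would change absolute AUC values for
  the parallel and integrated strategies, though not the trend tests.
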