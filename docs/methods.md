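# Methods

This note documents the models, conventions and numerical choices behind
`nutriferm`, and what its synthetic-data tests do and do not demonstrate
about real measurements.

## Digestibility accounting

In vitro digestibility of an amino acid is inferred from the mass balance
of a simulated gastric + intestinal digestion: what remains in the
insoluble pellet was not digested,

    D_aa (%) = (food − pellet) / food × 100,

with food and pellet in mg per 100 g of food on a common basis.
Tryptophan's colorimetric assay works on the soluble fraction, so its
accounting is inverted: `D_Trp = supernatant / food × 100`.

Conventions:

- **Dilution bookkeeping.** Laboratory workflows back-calculate pellet and
  supernatant quantities to the food basis through several dilution steps
  whose factors vary by protocol. Records therefore carry named dilution
  factors as an audit trail plus a declared mass basis, and the pipeline
  refuses to aggregate records on different bases. No factor is hard-coded.
- **Out-of-range values.** Measurement noise can put the pellet above the
  food content, giving negative digestibility. Values outside [0, 100] are
  kept and flagged rather than silently clamped — clamping hides assay
  problems. A `clamp` option truncates when a cleaned table is wanted.
- **Undefined, not zero.** An amino acid with zero food content, or
  tryptophan without a supernatant measurement, has *undefined*
  digestibility; it is excluded with a warning rather than scored 0.
- **Summary digestibility** is the unweighted mean over scored amino
  acids; a content-weighted variant is available. The choice matters
  little for meat matrices, where contents are of similar magnitude.

## DIAAR / DIAAS

For each of the nine scoring units (His, Ile, Leu, Lys, SAA = Met+Cys,
AAA = Phe+Tyr, Thr, Trp, Val):

    DIAAR_u = content_u (mg per g protein) × D_u/100 / requirement_u × 100
    DIAAS   = min_u DIAAR_u,   limiting unit = argmin

- **Composites.** SAA and AAA contents are sums of their members; their
  digestibility is the content-weighted mean of member digestibilities.
- **Protein basis.** "mg per g protein" defaults to the product's declared
  protein content (the FAO convention); normalising by total amino-acid
  content is available (`basis="total_aa"`) since composition tables
  sometimes lack a declared value and the two bases differ when non-amino
  nitrogen is present.
- **Reference patterns.** The FAO 2013 requirement patterns for the three
  age groups ship as an editable YAML file; the default age group is
  older children / adolescents / adults.
- **No truncation by default.** DIAAS is reported raw; the FAO convention
  of capping at 100 for mixed diets is behind a `truncate` flag.
- **Spread propagation.** With replicate digestibility measurements, the
  DIAAR/DIAAS spread is obtained by rescoring each replicate and taking
  mean ± sd of the scores, not by a delta-method linearisation — at n = 2
  (the usual duplicate determination) a linearisation would be spurious
  precision.
- **Ties** in the minimum are broken by the fixed scoring-unit order and
  flagged.

A consequence of the declared-protein basis worth knowing: a product with
lower declared protein but similar amino-acid content scores *higher*
per gram of protein, so reformulations that add protein can lower mg/g
contents even as digestibility rises.

## Community statistics

- **Relative abundance** at phylum/genus/OTU rank; taxa without an
  assignment pool into "Unclassified"; rows sum to 100 %.
- **Alpha diversity** (per sample, on raw integer counts): observed
  richness; Chao1 `S + F1²/(2 F2)` with the bias-corrected
  `S + F1(F1−1)/(2(F2+1))` when no doubletons exist; ACE after Chao & Lee
  with the conventional rare-species threshold of 10; Shannon with natural
  log on proportions of observed taxa; Simpson `1 − Σp²` and its inverse;
  Fisher's α solving `S = α ln(1 + N/α)` by bracketed root-finding to
  1e−10 relative tolerance. Configurations where ACE or Fisher's α are
  undefined (all rare taxa singletons; every taxon a singleton) yield NaN
  rather than aborting a pipeline run; non-integer counts are a hard error
  for the richness estimators. No rarefaction is applied by default.
- **Beta diversity.** Bray–Curtis is the shipped metric
  (`d = Σ|x−y| / Σ(x+y)`); phylogenetic metrics need a tree, which is out
  of scope, but any externally computed square distance matrix is accepted
  by the ordination and PERMANOVA stages.
- **PCoA** is classical scaling of the double-centred −d²/2 matrix;
  coordinates are returned for positive eigenvalues and negative
  eigenvalues are reported, not dropped.
- **PERMANOVA.** Pseudo-F from sums of squared distances
  (`SS_total = Σ_{i<j} d²/n`, within-group analogues, between = total −
  within). The sampled test draws label permutations from a seeded
  generator and reports `p = (1 + #{F* ≥ F}) / (1 + n_perm)` (default
  n_perm = 999; the seed is mandatory). An exact mode enumerates every
  distinct label assignment — feasible for the small flask counts typical
  of fermentation experiments — and returns the exact permutation p.
  Zero within-group variation makes F infinite; p is then reported at its
  `1/(1 + n_perm)` lower bound with a degeneracy flag.
- **Per-taxon tests** run the shared one-way ANOVA on relative abundances
  per taxon, with no multiple-testing correction by default (mirroring
  common practice in small fermentation studies); a Benjamini–Hochberg
  flag is available. Taxa with a single replicate per group or no variance
  get an undefined p rather than a fabricated one.

## Group statistics

ANOVA runs from summary statistics (n, mean, sd per group) because
published tables expose only those; raw data are reduced to the same
summaries first, so the two entry points agree exactly. Tukey's HSD uses
the studentized-range distribution uniformly (two groups reduce to the
pooled-variance t test via `q = t√2`), with the Tukey–Kramer standard
error for unequal n. Compact letters come from the insert-and-absorb
algorithm; the share-a-letter-iff-not-significant property is verified
exhaustively in tests for up to four groups. With all group sds zero the
test is undefined (equal means) or infinitely significant (unequal means),
both flagged explicitly.

With duplicate determinations (n = 2 per group) post-hoc letters are
fragile: tiny sd perturbations flip significance. Letter patterns
re-derived from published summaries are therefore checked for consistency
of pattern, not asserted as exact reproductions.

## SCFA accounting

HPLC concentrations in ppm (mg/L of fermentation fluid) convert as
`mmol/L = ppm / M` (M = 60.05, 74.08, 88.11 g/mol for acetic, propionic,
butyric acid) and `mmol/kg faeces = (mmol/L) / (kg faeces per L)`. The
default faecal load, 16/70 × 2/10 ≈ 0.0457 kg/L, derives from the
fermentation recipe (16 g faeces in 70 mL buffer; 2 mL slurry in a ~10 mL
flask) and is an overridable documented default, not a constant. The unit
of input records is carried through to output tables and never relabelled.
24 h production is the increase over the shared control baseline; negative
increases are kept and flagged. Whether a published table reports raw 24 h
concentrations or baseline-subtracted increases is often ambiguous, so the
table writer can produce both views.

## Synthetic-data generators

The generators emulate the study's three data layers with known truth:

- **Digestion**: pellet = food × (1 − d) × (1 + ε) and Trp supernatant =
  food × d × (1 + ε), ε ~ N(0, cv) with the factor floored at zero.
  Multiplicative truncated Gaussian noise is the least structured
  sign-safe error model; nothing in the emulated assays suggests more
  structure. Defaults: duplicate determinations (n = 2), cv = 0.05.
  Note the estimator-noise asymmetry this implies: pellet-based estimates
  have SE ∝ (1 − d), the supernatant-based tryptophan SE ∝ d.
- **Communities**: per sample, proportions ~ Dirichlet(c·p_group), counts
  ~ Multinomial(depth); group proportions are the baseline renormalised
  after per-taxon fold changes. Defaults mirror a small flask experiment
  (a few samples per group, depth 2×10⁴, log-normal rank-abundance
  baseline). No phylogenetic signal is simulated.
- **SCFA**: 24 h values Gaussian around group means truncated at zero,
  plus a shared exact baseline.

All generators are bit-for-bit reproducible under a fixed seed.

What passing these tests shows: the accounting, scoring and testing
machinery is correct on data whose generating process is known. What it
does not show: robustness to real assay pathologies — matrix effects,
correlated errors across amino acids, compositional artefacts of
sequencing, chromatographic drift — none of which the generators emulate.

## Verification problem sizes

The test suite and the acceptance script verify, among others: exact
noise-free digestibility recovery; 3-SE coverage ≥ 99 % at cv = 0.05 with
10 replicates over 1000 seeded trials; exact-enumeration PERMANOVA against
a brute-force oracle on every two-group layout up to 8 samples, and a
null type-I error within [0.03, 0.07] over 1000 datasets at 999
permutations; summary-vs-raw ANOVA agreement on 100 random fixtures and
exhaustive compact-letter checks up to four groups; and a ≥ 99 % DIAAS
win rate over 500 trials when true digestibility is raised uniformly by
15 points. These sizes keep the whole suite in the seconds-to-a-minute
range on a laptop while leaving the binomial tolerances meaningful.

## Known limitations

- Published composition and score tables are transcription inputs; totals
  printed in such tables are reproduced within 1 % (they were computed
  before rounding), not bit-exactly.
- The report's default synthetic digestion uses flat true-digestibility
  vectors; it demonstrates plumbing, not biology.
- No enzyme kinetics, no 16S read processing, no tree-based (UniFrac)
  metrics, no PDCAAS, no chromatogram handling.
- Optional figure export is not implemented; outputs are CSV/JSON tables,
  which are the analysis surface.
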