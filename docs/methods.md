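# Methods

This note documents the models, rules and numerical choices behind
`avipurge`, and what the simulation-based tests do and do not establish
about real comparative screens.

## The screening model

The package operates on *best-hit tables*: for each species (labelled
`neoaves`, `galloanserae`, `palaeognathae` or `other`) and each reference
gene, either the length (and optionally sequence) of the best protein hit,
or an explicit no-hit row. Orthology is assumed resolved upstream — genes
are matched by symbol — and hit quality is summarised by length alone. No
alignment-coverage or pseudogene analysis is attempted: a fragment of 26%
of the reference length and a clean two-thirds-length ortholog are both
"truncated", which matches how screens against protein databases report
partial sequences.

### Status classification

`present` ⇔ hit_length / ref_length ≥ `present_threshold`. The default
0.70 is a deliberate operational choice: reported worked cases put severe
truncations at retained fractions of roughly 0.10–0.65, while genuine
full-length hits sit near 1.0, so 0.70 separates the two regimes with
margin on both sides. It is exposed as a parameter because the boundary is
a convention, not a biological constant. Hits longer than the reference are
classified present rather than flagged, absorbing isoform and annotation
slack.

Truncations are modelled as N-terminal loss (the retained fragment is the
C-terminal end), which is the geometry observed for the motivating
amino-acid-transporter truncations and makes "number of TM domains
removed" well defined: TM spans (1-based inclusive UniProt-style residue
intervals) are counted when they end strictly before the retained region.
A `n_terminal_truncation=False` switch flips the geometry and affects only
the TM count, never the status.

### Clade-level purge rule

Per gene, species statuses are collapsed (a species with any present
paralog counts present), then:

- purged — not found in any sampled avian species, **or** full-length in
  ≥ `outgroup_present_min` (default 0.50) of sampled outgroup species and
  absent-or-truncated in > `neoave_majority` (default 0.70, strict) of
  sampled Neoave species;
- retained — found in Aves with a Neoave lost fraction ≤ the majority;
- ambiguous — lost in most Neoaves but without outgroup support.

Two decisions are worth calling out. First, the majority comparison is
strict (> 70%; exactly 70% is retained) because the rule this encodes is
stated as an exceedance. Second, "present largely in extant Aves" is
quantified as full-length in at least half the sampled outgroup species;
the screens this mirrors gave examples but no threshold, so the value is a
package choice and a parameter. Denominators use only species with a row
for the gene: sampled coverage varies wildly across hundreds of species,
and treating unsequenced species as absences would inflate loss fractions.
No phylogenetic correction for species non-independence is applied — calls
are descriptive tallies, not ancestral-state inferences.

### Module and family statistics

Module loss is 100 · purged members / scored members; members without any
clade call are dropped from the denominator with a warning. The
cross-module dispersion uses the sample SD (n−1), the standard convention
for a "mean ± SD over k modules" summary, and outliers are |x − mean| >
3·SD with strict inequality (so an all-equal set has none). The
nonredundant union counts distinct symbols across modules and is invariant
to duplicated modules. Family percentages round half-away-from-zero to
integers, reproducing conventional printed values such as 9/14 → 64% and
16/42 → 38%; a member counts as lost when purged *or* when
absent-or-truncated in a Neoave majority regardless of outgroup support,
matching "absent or severely truncated" family tallies.

### Paralogs and phylograms

Percent identity is fixed to one auditable definition: Needleman–Wunsch
global alignment with match +1, mismatch 0, linear gap −1, identity =
100 · matches / alignment columns (gap columns in the denominator, so
`A` vs `AA` is 50%). Duplication is flagged per gene when the median
Neoave species carries ≥ 2 paralogs with hits. Phylograms are
neighbour-joining (scikit-bio) on 100 − identity distances: NJ rather than
a clock-assuming method because paralog pairs typically pair a conserved
copy with a rapidly evolving one. Determinism comes from sorting sequences
alphabetically by label and truncating to `max_sequences` (default 100)
before any computation; negative NJ branch lengths are clamped to zero.
Clusters are single-linkage components at a percent-identity cutoff
(default 80, inclusive). Tests verify NJ against exhaustive
minimum-evolution enumeration (all unrooted topologies, OLS branch
lengths) on ≤ 5 taxa, where additive matrices force a unique answer.

### Metabolite ratios and labeling

The KO/WT ratio for a metabolite is computed per knockout replicate
against the wild-type mean: r_j = KO_j / mean(WT), summarised as mean(r_j)
± sample SD with n = number of KO replicates. This matches the
"mean ± SD (n = 6)" convention of replicate metabolomics panels; a
ratio-of-means variant with first-order error propagation is available via
`method="ratio_of_means"`. A zero WT mean yields a flagged undefined
ratio. Fractional labeling divides each isotopologue intensity (M+0..M+k)
by the within-sample total; sums are exactly 1 and the operation is
scale-invariant and idempotent. No natural-abundance isotope correction is
applied — outputs are raw fractional distributions, a documented
limitation for low-enrichment data.

## The simulator

`simulate_panel` draws exactly one event per species × gene — retain,
truncate (uniform retained fraction, default range 0.10–0.65, kept below
the classifier threshold so simulated truncations always classify
truncated), lose, or duplicate (2–3 full-length paralogs) — with
probabilities that are scalars or per-gene arrays; outgroup species have
their own (default zero) loss/truncation rates and never duplicate.
Sequences, when requested, use a uniform random reference per gene,
per-paralog bases mutated at rate 1 − paralog identity (default expected
identity 70%), and per-species copies mutated so that two species sit near
the configured ortholog identity (default 95%). Randomness uses one global
seed with an independent child stream per species and per gene, so outputs
are byte-identical for identical configurations.

The generator deliberately omits phylogenetically correlated loss (no
birth–death process on a tree), indels, and rate heterogeneity across
sites. Passing parameter-recovery tests therefore shows the pipeline's
counting and thresholds are correct under independent-loss conditions; it
does not validate behaviour under lineage-correlated loss, fragmentary
assemblies, or annotation artefacts in real proteomes.

`simulate_metab` produces strictly positive intensities
baseline · fold^(KO) · exp(σZ) with default σ = 0.2 (a realistic
replicate CV for LC–MS intensities) and n = 6 replicates per genotype, the
replicate count of the panels this mirrors; isotopologue mode splits each
intensity by a Dirichlet-drawn true fractional-labeling vector.

## Problem sizes and determinism

The repository's end-to-end checks run a 45-module × 60-gene panel over
150 Neoave + 8 outgroup species with a gene-level purge probability of
0.174 (the regime recovers the generating rate to within binomial
sampling error, SE ≈ 0.73 percentage points); repeated-seed calibration
tests use 300 small panels; Monte-Carlo ratio checks use 400–1000 seeds of
six-replicate tables. These sizes keep the whole suite in the
tens-of-seconds range on one CPU while leaving sampling error well inside
the asserted tolerances. All stochastic tests are seeded; the acceptance
script derives every stream from its `--seed` argument.

## Known limitations

- Length-ratio classification cannot distinguish genuine truncation from
  incomplete gene models or assembly gaps.
- The purge rule treats species as independent samples; shared ancestry
  inflates effective certainty.
- Percent identities are alignment-parameter-dependent; values from other
  aligners or web viewers will differ by a few points.
- Family percentages depend on the curated member list supplied by the
  user; the package does not define family membership.
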