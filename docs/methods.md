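# Methods

## Motif model and scanning

A motif is a position count matrix over {A, C, G, T}. Frequencies are
smoothed with a total pseudocount `pc` (default 0.8) split across bases in
proportion to the background `b` (default uniform):
`f[i, x] = (c[i, x] + pc·b[x]) / (Σ_x c[i, x] + pc)`. Scoring is summed
log2(f/b) per window, in bits. Both strands are scanned by default; a
reverse-strand window is scored with the reverse-complemented matrix and
reported in forward-strand 0-based half-open coordinates. Windows containing
N are skipped; other non-ACGT characters are errors.

A window is a hit when its **relative score**
`(S − S_min)/(S_max − S_min)` reaches the threshold (default **0.80**,
configurable). Relative-score thresholding was chosen because the original
site-mapping tool's cutoff convention is not published; consequently any
genome-scale match count is threshold-sensitive, and the package treats such
counts as conditional on (θ, pseudocount, background). No p-value
calibration of thresholds is attempted. A small numerical guard (1e-12) on
the threshold comparison keeps consensus windows at exactly rel = 1.0
regardless of floating-point summation order.

All overlapping hits are retained at scan time: the binding matrix needs
only presence, and the syntax stage resolves multiplicity itself.

## Rule mining

Transactions are sequences; items are TF names; presence is binary (no
multiplicity weighting). Frequent itemsets are found with a classical
level-wise Apriori search returning *exact* supports; tests verify
equivalence with exhaustive enumeration. Rules are emitted for every
antecedent/consequent split of every frequent itemset of size ≥ 2 with
confidence ≥ the threshold (defaults: support 0.1, confidence 0.6). Ordering
is deterministic: support desc, confidence desc, lift desc, rule string.
The minimal regulatory code is the first rule over ≥ 3 distinct TFs in that
order; when only pairwise rules exist (the expected negative-control
outcome) a dedicated `NoMinimalCodeError` is raised and composite runs
record it rather than failing.

## Adjacency, arrangements, Fisher tests, spacing

Sites of the analysis TF set are sorted by (start, end, name); hits of the
same TF tying at a start coordinate collapse to the highest-scoring one. An
adjacent triad is any three *consecutive* sites covering the triad exactly
(one site per TF) — consecutive in the analyzed set, so an intervening site
of any analyzed TF breaks adjacency. Each sequence contributes one
arrangement, its leftmost occurrence: the study design counts sequences,
not occurrences, and the resolution rule for multi-occurrence sequences is
otherwise unspecified.

Arrangement proportions are compared with two-sided Fisher's exact tests on
`[[a, n−a], [b, n−b]]` (minimum-likelihood two-sided rule, delegated to
scipy and checked against direct hypergeometric enumeration). This table
construction reproduces the published arrangement p-values (0.0091 and
0.0732 for 10 vs 2 and 10 vs 4 of 16) exactly, which is how the ambiguity
in "comparing two arrangements" was adjudicated.

Spacing is **edge-to-edge** (gap between one site's end and the next site's
start), the natural reading of "spacing between adjacent binding sites";
centre-to-centre is available behind a flag since the alternative cannot be
excluded. Gaps are floored at 0 for overlapping adjacent sites. The standard
deviation is the sample sd (ddof = 1) by default with a population-sd
option. Pair labels are flank-centre (`GATA3-FOXP2`, `HES5-FOXP2`).
`spacing_from_table` accepts an externally supplied per-pair distance table
(seq_id, pair, distance) for re-analysis of published distances.

## Genome-wide triad scan

Each catalog CRM is scanned with the three triad motifs; a CRM matches when
a centre-TF site lies strictly between a left-TF and a right-TF site.
Defaults: **mirror orientation accepted** (a segment read from the other
strand reverses apparent order, and strand handling of the original scan is
unstated; `allow_mirror=False` gives the strict one-orientation search),
**adjacency not required** (the genome-stage pattern demands order, not
adjacency — the opposite default from the syntax stage), and no gap bound
(a 250 bp preset mirrors the spacer rule used to build such catalogs).
Matched CRMs are reported once with their smallest-span match, sorted by
id, so output is independent of catalog order.

## Conservation classification

Per-CRM means are taken over *covered* bases only; uncovered bases are
excluded from numerator and denominator, because zero-filling would bias
sparsely covered regions downward. A fully uncovered CRM yields an explicit
no-coverage record, never 0.0. Bins: primate < 0.2 ≤ mammalian ≤ 0.5 <
birds ≤ 0.6 < amphibian/teleost. The four-bin scheme is primary (the
published sub-bins); collapsing birds + amphibian/teleost recovers the
three-threshold view. Classification is a total partition of [0, 1];
boundary inclusivity is pinned by tests at 0.2, 0.5 and 0.6. Reported
fractions are always computed from counts, never hard-coded — note that one
published fraction (128/2614 as "4.5%") disagrees with its own counts
(≈ 4.9%); this package reports the arithmetic.

## Epigenomic overlap and the core set

Intersection uses half-open arithmetic with a ≥ 1 bp criterion (the
BEDtools default, no minimum-overlap fraction being specified anywhere).
Chromosome names are normalized across the "chr" prefix. Same-class tracks
(e.g. the three histone marks) are unioned into class indicators before
core-set logic; the default core rule is **≥ 3 distinct feature classes**
(`k_of`, k = 3), with `all_of` available for stricter readings — the
published core-set membership rule is phrased both ways, so both are
first-class. SNPs are 1 bp half-open intervals: a SNP at a CRM's start
coordinate is inside, at its end coordinate it is not.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions the analysis targets:

| parameter | default | meaning |
|---|---|---|
| n_positive / n_negative | 160 / 100 | positive and control sequence counts |
| seq_length | 1500 bp | typical validated-enhancer scale |
| p_triad | 0.28 | fraction of positives with a planted adjacent triad |
| p_center | 0.625 / 0.25 / 0.125 | FOXP2 / HES5 / GATA3 centre split |
| gap_range | uniform(35, 504) bp | inter-site gaps, the published spacing range |
| marginals (triad TFs) | 0.30 / 0.15 / 0.15 | independent, scattered extra sites |
| marginals (other 20 TFs) | 0.25 | independent site-planting probability |
| catalog | 500 CRMs, 120 planted | genome-scan recovery conditions |
| category weights | 2051/414/21/128 ÷ 2614 | conservation mixture |
| track coverage | 0.22–0.95 per track | published per-track overlap rates |

Planted sites are motif consensus strings, so recovery is independent of the
scan threshold (a degraded-site mode samples sites from the PWM instead).
Synthetic motifs are sharp (one dominant base per position, width 12–16),
giving chance hit rates of roughly 0.01–0.1 expected presences per sequence
— comparable to curated high-information motifs, and low enough that the
mined structure reflects planting rather than noise. The flanking TFs of a
planted triad are placed in random left/right orientation; only the centre
identity is the controlled arrangement variable, matching how arrangements
are counted.

Two structural choices keep the ground truth self-consistent. First,
independent "marginal" sites of the *triad* TFs are never placed inside a
planted triad block: such a site would silently rewrite the planted
arrangement (e.g. an extra HES5 between FOXP2 and GATA3 turns a
FOXP2-centred block into a HES5-centred adjacent window), making the truth
table wrong about its own sequence. Second, each generator stage draws from
its own child RNG stream spawned from the master seed, so changing one
stage's size never perturbs another's output.

The synthetic data deliberately does **not** model real genomic sequence
composition (repeats, isochores, higher-order Markov structure), degenerate
or overlapping real motifs, correlated track placement, or within-CRM
conservation heterogeneity (per-base scores are constant at the drawn CRM
mean, which makes category recovery exact by construction). Passing
recovery tests therefore demonstrates correctness of the analysis machinery
under known truth — not performance on real enhancer data, where motif
quality and threshold choice dominate.

Adjacency recovery is intentionally partial under the defaults: with ~6
independently planted sites per 1.5 kb sequence and triad spans averaging
~580 bp, most planted triads acquire an intervening site and are correctly
*excluded* by the adjacency screen (as in the real analysis, where the
adjacency screen retains 16 of ~28 co-occurring sequences). Surviving
triads are an unbiased sample with respect to centre identity — gap draws
are i.i.d. across centres — so centre-split recovery is tested on pooled
counts across 20 replicates against central 95% binomial bands, plus a
strict ranking check. Scattered co-occurrence of the three TFs additionally
produces a small number of chance adjacent triads with approximately
uniform centres (about 5–10% of detected triads under the defaults), which
slightly attenuates the recovered split; the binomial bands absorb this at
the pooled sample size.

## Numerical and degenerate-input conventions

- Coordinates are 0-based half-open everywhere internally; BED interchange
  is native, wiggle headers are converted from their 1-based convention.
- A motif wider than its sequence scans to an empty hit list, not an error;
  an empty motif file parses to an empty collection with a warning.
- Tie-breaks are always total and documented (lexicographic last), so every
  output is deterministic for fixed inputs; composite-run manifests record
  content digests of all inputs and outputs to make this checkable.
- Probability-type inputs are validated to [0, 1]; mixture weights must sum
  to 1 within 1e-9.

## Known limitations

- Site-count reproduction on real data is conditional on the unpublished
  scoring threshold of the original mapping tool; the package exposes the
  threshold rather than guessing a calibration.
- The rule-mining support denominator for the published metrics is
  ambiguous (the printed support is not an integer count over 100
  transactions); reproduction tests compare count-based metrics and report
  the discrepancy rather than forcing agreement.
- Strand grammar (site orientation) is not analyzed; order and spacing only.
- The CRM catalog, motif set and epigenomic tracks are inputs; constructing
  them is out of scope.
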