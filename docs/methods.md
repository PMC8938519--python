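# Methods

`arcirc` re-implements, as a tested library, the computational workflow used
to ask how the ADAR RNA-editing enzymes regulate circular RNA (circRNA)
biogenesis: which circRNAs respond to ADAR1/ADAR2 perturbation and in which
direction, which of those responses require catalytic (deaminase) activity,
where A-to-I editing sites and reverse-complementary matches (RCMs) sit
relative to back-splice junctions (BSJs), how editing is predicted to change
the stability of the RCM duplex, and which RNA-binding-protein (RBP) motifs
are created or destroyed by editing. Every stage runs on synthetic data with
a full truth table, so the statistical behaviour of each rule can be
measured rather than assumed.

## Coordinate conventions

All in-memory coordinates are 1-based, fully closed; a BSJ is keyed
`chrom:start-end:strand` with `start < end`, and circRNA *identity* for set
comparisons is `(chrom, start, end)` — strand is retained but excluded, so
two catalogues agree only on exact junction positions. BED output uses the
standard 0-based half-open convention. BSJ-relative offsets put `-1` at the
intronic base adjacent to the back-splice acceptor and `+1` adjacent to the
donor; there is no position 0.

## circRNA quantification and classification

A chimeric-junction record counts as one BSJ read iff both segments map to
the same chromosome and strand, the acceptor lies gene-upstream of the donor
(head-to-tail), and both breakpoints coincide with annotated exon boundaries
(tolerance 0 nt by default; a `tolerance` parameter exists). The catalogue
keeps junctions with >= 1 read in >= 1 sample of a comparison batch.

Classification is deliberately threshold-based, not model-based (no
dispersion estimation or hypothesis testing): a junction is called for a
regulator when the read-sum gates hold — (EV + OE) >= 10 **and**
(Scr + KD) >= 10, interpreted as sums of per-condition totals — and the
reciprocal criteria are met:

* promoted: OE/EV >= 2 and KD/Scr <= 0.5;
* repressed: OE/EV <= 0.5 and KD/Scr >= 2.

Thresholds are closed (exactly 2.0 or 0.5 qualifies). Fold changes use raw
per-condition totals with no pseudocount; a zero denominator with a positive
numerator is +inf (which satisfies ">= 2"), and 0/0 is reachable only behind
the read gate, where it is carried as NaN and never interpreted. Optional
per-sample depth factors are supported but default to equal depth.

Editing dependence uses the deaminase-dead (DeAD) overexpression, gated on
(EV + DeAD) >= 10 (otherwise `undetermined`): a call is **dependent** when
0.8 < DeAD/EV < 1.25 (no or minor change) or when the DeAD shift is opposite
in sign (on the log scale) to the wildtype OE shift; **independent** when the
DeAD shift has the same sign and magnitude >= 1.25-fold (equivalently
<= 0.8). The band is open, so exactly 0.8 or 1.25 in the wildtype direction
is independent. Dependence is resolved per regulator; a circRNA regulated by
both ADARs may carry different labels for each.

## Editing-site calling

Per-sample variant candidates need >= 2 alt-supporting reads (the evidence
contract assumes mapping quality < 20 reads and PCR duplicates were removed
upstream). The cascade then removes, in order: known SNP positions; sites
whose alt support falls below 2 after subtracting reads with the variant in
the first six read bases (random-hexamer mispriming — the subtraction form
means a site is removed only when mispriming explains essentially all of its
support); and, **for sites outside Alu-like elements only**, sites <= 4 nt
into an intron from a splice site, inside homopolymer runs of >= 5 identical
bases, inside annotated simple repeats, or in non-unique regions. Finally
only A->G on the annotated gene strand is kept (a minus-strand A->G appears
as T->C on the plus strand). The non-unique test is deterministic: the
50-mer centred on the site must occur exactly once in the genome over both
strands (window length configurable) — a reproducible stand-in for a
BLAT-style mappability check. High-confidence sites additionally need
>= 10x coverage in at least one sample and an editing-level change strictly
greater than 10 percentage points between treatment and control.

Editing level is alt/(alt + ref) reads, the binomial maximum-likelihood
estimate. The mismatch spectrum is tabulated over the 12 gene-strand
substitution types before the A->G-only step; the +/- 2 nt sequence context
is reverse complemented for minus-strand sites before being turned into a
4 x 5 position probability matrix.

## RCM discovery

For each circRNA the upstream flanking intron (immediately gene-upstream of
the acceptor) is locally aligned against the reverse complement of the
downstream flanking intron. Scoring is megablast-like — match +1, mismatch
-3, gap open -5, gap extend -2, a gap of length g costing
`open + (g-1)*extend` — and configurable.

The aligner is an exact affine-gap Smith-Waterman, vectorised row-wise in
integer arithmetic (vertical gaps by the standard per-column recurrence;
horizontal gaps resolved within a row by a running prefix maximum, which is
exact whenever `gap_open <= gap_extend <= 0` because chaining a gap onto a
gap can never beat the single longer gap it shadows). Secondary,
non-overlapping RCMs are produced Waterman-Eggert style: bases consumed by
an accepted alignment are masked and the DP re-run until scores drop below
`min_score` (default 20). This is a deliberate design choice over a
seed-and-extend heuristic: at the intron sizes handled here (a few kb) the
exact DP costs tens of milliseconds, and exactness makes the oracle
equivalence property (agreement with an independent Smith-Waterman
implementation on every instance) hold by construction instead of
probabilistically. Equal top scores break ties toward the arm pair with the
smaller summed distance to the BSJ, then the leftmost up-arm, so output is
deterministic and BSJ-proximal RCMs — the mechanistically relevant ones —
are preferred.

CircRNAs qualify for the final RCM set when both flanking introns are
>= 1500 bp (boundary inclusive) and at least one RCM exists. The coverage
profile counts top-scoring RCM arms per base over the +/- 1500 nt window
(each arm contributes to its own side; portions outside the window are
clipped); editing sites are profiled as a histogram **density** (bin width
50 nt, integrating to 1), since sites are points while RCMs are regions of
variable length.

## Duplex model and editing effects

The duplex implied by an RCM alignment is scored per column with pair-class
weights: G-C 3, A-U 2, G.U wobble 1, mismatch 0, gap -2. The weights are not
thermodynamic; they are chosen so that the two editing mechanisms have
opposite signs by construction — A:C -> I(G)-C correction gains +3, A-U ->
I(G).U conversion loses -1 — which is the package's operationalisation of
"more compact" versus "looser" duplexes (the source analysis used
free-energy folding, which is out of scope here; the claims being modelled
are about pair-class transitions). Per-site effects are the score change of
editing that site alone; the circRNA-level verdict is the sign of the joint
change with all sites edited, and a synergy flag marks joint changes
exceeding the sum of individual ones (impossible under pure relabelling,
possible under re-alignment). The optional re-alignment mode re-aligns the
edited arm sequences and reports the better-scoring duplex, a bounded
approximation to structural rearrangement of neighbouring regions; it never
reports a lower score than relabelling.

## Motif gain/loss

Windows of +/- 10 nt around each editing site are retrieved on the gene
strand with A (reference) or G (edited) at the centre. Each PWM (JASPAR-style
PFMs via Bio.motifs, or near-deterministic consensus PWMs built in-repo) is
scanned single-strandedly for its best log-odds score (uniform background by
default, zero probabilities floored at 1e-3, leftmost tie-break). Affinity
change is assessed either as a z-score shift against a dinucleotide-shuffle
null (Altschul-Erikson shuffling, 100 seeded shuffles, "changed" = any
nonzero shift by default, matching the published wording; degenerate
zero-variance nulls fall back to raw score comparison) or in a stricter
significance mode where the PWM threshold must be crossed in exactly one
allele. This log-odds + shuffle scheme is a documented stand-in for RBPmap's
proprietary weighted-rank score, so absolute per-RBP counts from that tool
are explicitly not reproduced — only the gain/loss logic and the circRNA-
level tally (a circRNA counts once per RBP regardless of how many of its
sites changed).

## Assay arithmetic

qPCR fold change is 2^-ddCt with dCt = Ct_target - Ct_reference and ddCt
against the mean control dCt (invariant to plate-wide Ct shifts); RIP
recovery is %input = 2^-(Ct_RIP - (Ct_input - dilution factor)) x 100, the
dilution factor being a required input; TA-clone editing frequency is
G/(A+G) with an exact Clopper-Pearson interval; native-gel migration maps
distances linearly onto [0, 1] between the slowest and fastest probes;
xenograft volume is 0.5 x length x width^2. Patient stratification splits
tumor/normal pairs into ADAR1-up (tumor > NT) and ADAR1-down, counting
within each group the patients with a circRNA tumor/NT ratio >= 2 (up) or
<= 0.5 (down); an ADAR1 ratio of exactly 1 goes to ADAR1-down and is flagged
ambiguous.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
raw sequencing:

* **Genome** — one gene per chromosome (default 16 genes x 4 exons of
  150 nt, 2 kb introns), alternating strands. The first `n_circ` genes carry
  a designed circRNA over their interior exons. Each circRNA gets an
  inverted-repeat arm pair (one arm per flanking intron, exact reverse
  complements, 80-300 nt, placed entirely within 500 nt of the BSJ and
  annotated as Alu-like), flanked by 2-nt guard bases chosen so one-step
  alignment extension always mismatches — this makes planted-arm recovery an
  exact-coordinate check. Decoy features (one per filter class per
  requested replicate: SNP, mispriming, splice-proximal, homopolymer run,
  simple repeat, duplicated segment) are hosted in introns of plus-strand
  non-circRNA genes so they never collide with arms or true sites.
* **Counts** — negative binomial (variance mu + alpha*mu^2; the RNA-seq
  standard) with mean `base_mean` (default 50); promoted circRNAs get mean
  x`fc_effect` (default 4) in OE and /`fc_effect` in KD, repressed the
  inverse; editing-dependent circRNAs keep DeAD mean equal to EV,
  independent ones shift DeAD by 2-fold (>= 1.25 as required) in the
  wildtype direction. `zero_noise` emits rounded means for exact-limit
  checks; `nb_dispersion <= 0` falls back to Poisson.
* **Site evidence** — Poisson coverage (default mean 50), alt counts
  Binomial(coverage, level) with control/OE levels 0.05/0.25, sequencing
  errors Binomial(coverage, error/substitution), SNP decoys at level 0.5.
  True sites are planted only at gene-strand adenosines that pass every
  regional filter (or inside the Alu-exempt arms), so cascade sensitivity is
  measurable; each decoy is engineered to fail exactly its own filter.
  First-six-base support is Binomial(alt, 0.06), i.e. a uniform site
  position in 100-nt reads; the mispriming decoy has all its support there.
* **Assay tables** — Ct values from chosen true fold changes
  (Ct_target = baseline - log2(FC) + noise), Bernoulli clone draws, and
  tumor/NT patient pairs with a planted up/down and concordance structure.

Randomness is a single top-level seed with fixed per-stage sub-streams
(genome 0, counts 1, site evidence 2, assays 3, shuffles 5), so identical
configurations are byte-identical and stages are independently
reproducible.

What the simulation does **not** capture: read-level artifacts (mapping
bias, soft-clipping, duplicates), realistic repeat content and Alu family
structure, correlated library-size effects (per-sample depth factors exist
but default to equal), overdispersion heterogeneity across circRNAs, and
linear host-gene expression. Passing tests therefore demonstrate that the
decision rules are implemented faithfully and behave as intended under
their own assumptions — not that the pipeline is robust to every real-data
failure mode.

## Problem sizes and numerical notes

The test-suite and acceptance-script simulations use 300 circRNAs with
20 promoted + 20 repressed per regulator (fc 4, mean 100, dispersion 0.01)
for classification recovery; 200 true editing sites and 30 decoys per filter
class for the cascade; 100 random pairs up to 300 nt for the alignment
oracle; and the 10-circRNA default genome for arm recovery and profiles —
sizes chosen so each property is measured with comfortable margins while a
full run stays in the seconds-to-minutes range on one CPU. All alignment
arithmetic is integer, so score comparisons in tracebacks are exact; PWM
scanning floors zero probabilities at 1e-3 to keep log-odds finite;
degenerate nulls, empty catalogues, all-N sequences, 0/0 fold changes and
contig-edge windows are all explicit, tested cases rather than silent NaNs.

## Known limitations

Classification is threshold-based by design and inherits the instability of
ratio thresholds at low counts (mitigated only by the read gates, as in the
original rules). The duplex score is ordinal, not thermodynamic: it orders
stabilising vs destabilising transitions but says nothing about magnitudes
or long-range refolding. The motif z-score is a stand-in, and per-RBP
tallies are only comparable within a motif collection. The editing caller
trusts its evidence contract (pileup-level input) and does not model
mapping artifacts itself.
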