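# arcirc

Analysis toolkit for **ADAR-regulated circular RNAs (ARcircs)**: from
back-splice-junction (BSJ) evidence to a classified circRNA catalogue,
A-to-I editing-site calls, reverse-complementary-match (RCM) discovery in
flanking introns, editing-induced duplex-stability scoring, and RBP motif
gain/loss tallies — plus a synthetic-data generator with full truth tables
so every rule can be validated against known ground truth.

## The problem

Circular RNAs arise by back-splicing: a downstream splice donor joins an
upstream acceptor, a reaction promoted when reverse-complementary segments
(RCMs, typically inverted Alu repeats) in the two flanking introns base-pair
and juxtapose the splice sites. ADAR1/ADAR2 bind exactly such double-stranded
RNA and catalyse A-to-I editing (read as A->G in sequencing), so they can
regulate circRNA biogenesis both through editing — correcting A:C mismatches
to I(G)-C pairs (stabilising the duplex) or turning A-U pairs into weaker
I(G).U wobbles (destabilising it), and rewriting RBP binding motifs — and
independently of it, through binding alone. `arcirc` implements the
threshold rules and sequence analyses used to dissect this, for anyone who
wants to run them on tabular junction/pileup evidence or to study their
statistical behaviour on simulated data.

## The core rules

With per-condition junction read totals (EV/OE for overexpression, Scr/KD
for knockdown), a circRNA is called for a regulator when
`EV + OE >= 10` and `Scr + KD >= 10` and

```
promoted:  OE/EV >= 2    and  KD/Scr <= 0.5
repressed: OE/EV <= 0.5  and  KD/Scr >= 2
```

Against a deaminase-dead (DeAD) mutant (gated on `EV + DeAD >= 10`), the
call is *editing-dependent* when `0.8 < DeAD/EV < 1.25` or the DeAD shift
opposes the wildtype direction, and *editing-independent* when it follows
the wildtype direction by >= 1.25-fold. Editing sites pass a filter cascade
(>= 2 alt reads; SNP removal; first-six-bases mispriming subtraction; and,
outside Alu-like elements, splice-proximal/homopolymer/simple-repeat/
non-unique removal; A->G on the gene strand only), with high-confidence
sites needing >= 10x coverage and > 10-point editing-level change. RCMs are
optimal local alignments of the upstream intron against the reverse
complement of the downstream intron (match +1, mismatch -3, gap -5/-2),
profiled over +/- 1500 nt of the BSJ. See `docs/methods.md` for the full
model description and design rationale.

## Worked example

Run the whole pipeline on a fresh simulation (16 genes, 10 circRNAs, 9 of
them planted as ADAR-regulated, negative-binomial counts, binomial editing
evidence):

```python
import json
from arcirc.pipeline import PipelineConfig, run_pipeline, report
from arcirc.simulate import SimConfig

results = run_pipeline(PipelineConfig(sim=SimConfig(seed=7)))
print(json.dumps(report(results), indent=2))
```

prints

```json
{
  "ADAR1": {
    "n_called": 5, "promoted_pct": 40.0, "repressed_pct": 60.0,
    "n_dependent": 4, "n_independent": 1, "n_undetermined": 0
  },
  "ADAR2": {
    "n_called": 4, "promoted_pct": 75.0, "repressed_pct": 25.0,
    "n_dependent": 3, "n_independent": 1, "n_undetermined": 0
  },
  "concordance": {"n_common": 2, "n_same_direction": 2, "n_opposite_direction": 0},
  "n_editing_sites": 40,
  "n_high_confidence_sites": 35,
  "rcm_coverage": {"total_mass": 4482, "proximal_fraction": 1.0},
  "duplex_verdicts": {"destabilizing": 5},
  "rbp_tally": {"RBP_gain1": 1, "RBP_loss2": 1}
}
```

Reading it: of the 10 simulated circRNAs, 5 were called ADAR1-regulated and
4 ADAR2-regulated (one planted effect fell below the reciprocal thresholds
under this noise draw); the two circRNAs called for both regulators moved in
the same direction, as observed in real data. All 40 planted editing sites
survived the cascade, 35 at high confidence. The entire recovered RCM
coverage mass lies within +/- 500 nt of the BSJ (`proximal_fraction: 1.0`),
reproducing the junction-proximal enrichment of inverted repeats. Because
the planted arms are perfect inverted repeats, every in-arm editing site
converts an A-U pair to a G.U wobble, so all duplex verdicts are
destabilising (joint score change < 0); the two fixture PWMs anchored on
edited/reference windows each register exactly one circRNA with a motif
gain or loss.

The same stages are exposed on the command line:

```bash
arcirc simulate --out sim/ --seed 7
arcirc quantify --junctions sim/junctions --genome sim/genome --out quant/
arcirc classify --matrix sim/counts.tsv --design sim/design.tsv --out calls/
arcirc run --out run/ --seed 7          # full pipeline + report.json
```

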