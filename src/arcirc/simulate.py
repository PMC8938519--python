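"""Synthetic data with known truth for the ARcirc analysis.

Generates a toy multi-gene genome whose circRNA-forming genes carry planted
inverted-repeat (RCM) arm pairs in their flanking introns, negative-binomial
back-splice-junction counts across EV/OE/Scr/KD/DeAD conditions for two
regulators (ADAR1/ADAR2) with planted promoted/repressed and
editing-dependent/independent circRNAs, binomial per-site editing evidence
with planted true sites plus one decoy per filter class, and the small assay
tables (qPCR Ct, TA clones, patient tumor/normal pairs).

Randomness: one top-level seed; each stage draws from its own sub-stream
(``default_rng([stage_offset, seed])`` with offsets 0 genome, 1 counts,
2 site evidence, 3 assays), so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .circquant import CircCountMatrix
from .genome import CIRC_COLUMNS, GenomeBundle, junction_key, revcomp

REGULATORS = ("ADAR1", "ADAR2")
CONDITIONS = ("EV", "OE", "Scr", "KD", "DeAD")
DECOY_CLASSES = ("snp", "first6", "near_splice", "homopolymer",
                 "simple_repeat", "non_unique")


class SimulationSizingError(ValueError):
    """Requested feature does not fit in the configured genome geometry."""


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 16
    exons_per_gene: int = 4
    exon_len: int = 150
    intron_len: int = 2000
    flank_len: int = 300
    n_circ: int = 10
    n_promoted: int = 2          # per regulator
    n_repressed: int = 2         # per regulator
    n_both: int = 1              # regulated by both ADARs, same direction
    fc_effect: float = 4.0
    dead_fc_independent: float = 2.0
    base_mean: float = 50.0
    nb_dispersion: float = 0.05
    zero_noise: bool = False
    n_edit_sites: int = 40
    n_decoys_per_class: int = 1
    edit_level_control: float = 0.05
    edit_level_oe: float = 0.25
    coverage_mean: float = 50.0
    seq_error: float = 0.001
    arm_len_min: int = 80
    arm_len_max: int = 300
    arm_max_dist: int = 500      # whole arm lies within this of the BSJ
    n_background_sites: int = 30
    depth_factors: dict | None = None  # sample -> multiplier; None = equal depth

    def __post_init__(self):
        counts = (self.n_genes, self.exons_per_gene, self.exon_len,
                  self.intron_len, self.flank_len, self.n_circ,
                  self.n_promoted, self.n_repressed, self.n_both,
                  self.n_edit_sites, self.n_decoys_per_class,
                  self.n_background_sites)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        for f in (self.edit_level_control, self.edit_level_oe, self.seq_error):
            if not 0.0 <= f <= 1.0:
                raise ValueError("frequencies must lie in [0, 1]")
        if self.fc_effect <= 1:
            raise ValueError("fc_effect must exceed 1")
        if self.dead_fc_independent < 1.25:
            raise ValueError("dead_fc_independent must be >= 1.25")
        if self.exons_per_gene < 3:
            raise ValueError("need >= 3 exons per gene to form a circRNA")
        if self.n_circ > self.n_genes:
            raise ValueError("n_circ cannot exceed n_genes")
        planted = 2 * (self.n_promoted + self.n_repressed) + self.n_both
        if planted > self.n_circ:
            raise ValueError(f"{planted} planted circRNAs exceed n_circ={self.n_circ}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.seed])


def _chrom_index(chrom: str) -> int:
    return int(chrom.lstrip("chr"))


# --------------------------------------------------------------------- genome

def make_genome(config: SimConfig) -> GenomeBundle:
    """Build the toy genome, plant RCM arms and decoy features, emit tracks."""
    rng = _rng(config, 0)
    E, ex, il, fl = (config.exons_per_gene, config.exon_len,
                     config.intron_len, config.flank_len)
    chrom_len = 2 * fl + E * ex + (E - 1) * il

    seqs: dict[str, list[str]] = {}
    genes, exons, introns, circs = [], [], [], []
    occupied: dict[str, list[tuple[int, int]]] = {}

    for g in range(config.n_genes):
        chrom = f"chr{g + 1}"
        strand = "+" if g % 2 == 0 else "-"
        seqs[chrom] = list(rng.choice(list("ACGT"), chrom_len))
        occupied[chrom] = []
        genes.append({"gene_id": f"gene{g + 1}", "chrom": chrom, "strand": strand,
                      "start": fl + 1, "end": chrom_len - fl})
        for i in range(E):
            s = fl + i * (ex + il) + 1
            exons.append({"chrom": chrom, "start": s, "end": s + ex - 1,
                          "name": f"gene{g + 1}_exon{i + 1}", "strand": strand})
            if i < E - 1:
                introns.append({"chrom": chrom, "start": s + ex,
                                "end": s + ex + il - 1,
                                "name": f"gene{g + 1}_intron{i + 1}",
                                "strand": strand})

    exons_df = pd.DataFrame(exons)
    introns_df = pd.DataFrame(introns)

    alu_rows = []
    for c in range(config.n_circ):
        chrom = f"chr{c + 1}"
        strand = "+" if c % 2 == 0 else "-"
        gene_ex = exons_df[exons_df["chrom"] == chrom].reset_index(drop=True)
        gene_in = introns_df[introns_df["chrom"] == chrom].reset_index(drop=True)
        start = int(gene_ex.loc[1, "start"])       # genomic exon 2
        end = int(gene_ex.loc[E - 2, "end"])        # genomic exon E-1
        left = gene_in.iloc[0]                      # intron left of the circ
        right = gene_in.iloc[E - 2]                 # intron right of the circ
        if strand == "+":
            up, down = left, right
        else:
            up, down = right, left
        arm_left, arm_right = _plant_arm_pair(
            seqs[chrom], (int(left["start"]), int(left["end"])),
            (int(right["start"]), int(right["end"])), config, rng)
        occupied[chrom] += [(arm_left[0] - 3, arm_left[1] + 3),
                            (arm_right[0] - 3, arm_right[1] + 3)]
        up_arm, down_arm = (arm_left, arm_right) if strand == "+" else (arm_right, arm_left)
        circ_id = f"circ{c + 1}"
        circs.append({
            "circ_id": circ_id, "gene_id": f"gene{c + 1}", "chrom": chrom,
            "start": start, "end": end, "strand": strand,
            "up_intron_start": int(up["start"]), "up_intron_end": int(up["end"]),
            "down_intron_start": int(down["start"]), "down_intron_end": int(down["end"]),
            "up_arm_start": up_arm[0], "up_arm_end": up_arm[1],
            "down_arm_start": down_arm[0], "down_arm_end": down_arm[1],
        })
        for s, e in (arm_left, arm_right):
            alu_rows.append({"chrom": chrom, "start": s, "end": e,
                             "name": circ_id, "strand": strand})

    tracks = {"alu": pd.DataFrame(alu_rows, columns=["chrom", "start", "end", "name", "strand"])}
    anchors, snps = _plant_decoy_features(seqs, introns_df, occupied, tracks, config, rng)

    bundle = GenomeBundle(
        seqs={c: "".join(s) for c, s in seqs.items()},
        genes=pd.DataFrame(genes),
        exons=exons_df,
        introns=introns_df,
        circs=pd.DataFrame(circs, columns=CIRC_COLUMNS),
        tracks=tracks,
        snps=snps,
    )
    bundle.anchors = anchors  # simulation bookkeeping (decoy site positions)
    return bundle


def _plant_arm_pair(seq: list[str], left_iv, right_iv, config: SimConfig,
                    rng: np.random.Generator) -> tuple[tuple[int, int], tuple[int, int]]:
    """Plant one inverted-repeat arm per intron, both fully within
    ``arm_max_dist`` of the BSJ, flanked by 2-nt anti-complementary guards."""
    window = min(config.arm_max_dist, config.intron_len)
    max_len = min(config.arm_len_max, window - 6)
    if max_len < config.arm_len_min:
        raise SimulationSizingError(
            f"intron window of {window} nt too short to host an arm of "
            f">= {config.arm_len_min} nt")
    L = int(rng.integers(config.arm_len_min, max_len + 1))
    d_left = int(rng.integers(2, window - L - 1))
    d_right = int(rng.integers(2, window - L - 1))
    # left intron: BSJ-proximal edge is its right end; right intron: its start
    l0 = left_iv[1] - d_left - L + 1
    l1 = left_iv[1] - d_left
    r0 = right_iv[0] + d_right
    r1 = right_iv[0] + d_right + L - 1
    arm = "".join(seq[l0 - 1 : l1])
    rc = revcomp(arm)
    seq[r0 - 1 : r1] = list(rc)
    # guard bases: make each one-step extension a guaranteed mismatch
    # (pairing partners: (l1+1, r0-1), (l1+2, r0-2), (l0-1, r1+1), (l0-2, r1+2))
    seq[r0 - 2] = seq[l1]      # l1+1 in 1-based is index l1
    seq[r0 - 3] = seq[l1 + 1]
    seq[r1] = seq[l0 - 2]
    seq[r1 + 1] = seq[l0 - 3]
    return (l0, l1), (r0, r1)


def _plant_decoy_features(seqs, introns_df, occupied, tracks, config, rng):
    """Plant one feature per decoy class x n_decoys_per_class, each carrying a
    designated gene-strand 'A' anchor position.

    Features are hosted in introns of plus-strand genes that do not form a
    circRNA, so they never collide with planted arms or the true-site pool.
    """
    hom_rows, rep_rows, dup_rows, anchor_rows, snp_rows = [], [], [], [], []
    host = introns_df[(introns_df["strand"] == "+")
                      & (introns_df["chrom"].map(_chrom_index) > config.n_circ)]
    host = host.reset_index(drop=True)
    if config.n_decoys_per_class == 0:
        cols = ["chrom", "start", "end", "name", "strand"]
        tracks["homopolymer"] = pd.DataFrame(columns=cols)
        tracks["simple_repeat"] = pd.DataFrame(columns=cols)
        tracks["non_unique"] = pd.DataFrame(columns=cols)
        return (pd.DataFrame(columns=["kind", "chrom", "pos", "strand"]),
                pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]))
    if host.empty:
        raise SimulationSizingError(
            "no plus-strand non-circRNA gene available to host decoy features")
    if config.n_decoys_per_class > 3 * len(host):
        raise SimulationSizingError("too many near-splice decoys for the host introns")
    cursors: dict[int, int] = {}

    def free(chrom, s, e):
        return all(e < a - 6 or s > b + 6 for a, b in occupied[chrom])

    def next_slot(width: int) -> tuple[str, int]:
        for _ in range(20 * len(host)):
            k = int(rng.integers(0, len(host)))
            row = host.iloc[k]
            chrom, i_s, i_e = row["chrom"], int(row["start"]), int(row["end"])
            cur = cursors.get(k, 8)
            if i_s + cur + width + 8 > i_e - 8:
                continue
            s = i_s + cur
            cursors[k] = cur + width + 60
            if free(chrom, s, s + width):
                occupied[chrom].append((s, s + width))
                return chrom, s
        raise SimulationSizingError("introns too crowded to place decoy features")

    def set_anchor(chrom, pos):
        # C-A-G pattern kills accidental homopolymer runs around the anchor
        seqs[chrom][pos - 2] = "C"
        seqs[chrom][pos - 1] = "A"
        seqs[chrom][pos] = "G"

    for rep in range(config.n_decoys_per_class):
        chrom, p = next_slot(3)
        set_anchor(chrom, p + 1)
        snp_rows.append({"chrom": chrom, "pos": p + 1, "ref": "A", "alt": "G"})
        anchor_rows.append({"kind": "snp", "chrom": chrom, "pos": p + 1, "strand": "+"})

        chrom, p = next_slot(3)
        set_anchor(chrom, p + 1)
        anchor_rows.append({"kind": "first6", "chrom": chrom, "pos": p + 1, "strand": "+"})

        # near-splice: 2nd..4th intronic base, cycling over host introns
        row = host.iloc[rep % len(host)]
        chrom, i_s = row["chrom"], int(row["start"])
        pos = i_s + 1 + (rep // len(host)) % 3
        occupied[chrom].append((pos, pos))
        seqs[chrom][pos - 1] = "A"
        anchor_rows.append({"kind": "near_splice", "chrom": chrom,
                            "pos": pos, "strand": "+"})

        chrom, p = next_slot(7)
        seqs[chrom][p - 1 : p + 6] = list("AAAAAAA")
        hom_rows.append({"chrom": chrom, "start": p, "end": p + 6,
                         "name": f"hom{rep}", "strand": "+"})
        anchor_rows.append({"kind": "homopolymer", "chrom": chrom,
                            "pos": p + 3, "strand": "+"})

        chrom, p = next_slot(14)
        seqs[chrom][p - 1 : p + 13] = list("AT" * 7)
        rep_rows.append({"chrom": chrom, "start": p, "end": p + 13,
                         "name": f"rep{rep}", "strand": "+"})
        anchor_rows.append({"kind": "simple_repeat", "chrom": chrom,
                            "pos": p + 6, "strand": "+"})

        src_chrom, sp = next_slot(120)
        set_anchor(src_chrom, sp + 60)
        segment = seqs[src_chrom][sp - 1 : sp + 119]
        tgt_chrom, tp = next_slot(120)
        seqs[tgt_chrom][tp - 1 : tp + 119] = list(segment)
        dup_rows.append({"chrom": src_chrom, "start": sp, "end": sp + 119,
                         "name": f"dup{rep}_src", "strand": "+"})
        dup_rows.append({"chrom": tgt_chrom, "start": tp, "end": tp + 119,
                         "name": f"dup{rep}_tgt", "strand": "+"})
        anchor_rows.append({"kind": "non_unique", "chrom": tgt_chrom,
                            "pos": tp + 60, "strand": "+"})

    cols = ["chrom", "start", "end", "name", "strand"]
    tracks["homopolymer"] = pd.DataFrame(hom_rows, columns=cols)
    tracks["simple_repeat"] = pd.DataFrame(rep_rows, columns=cols)
    tracks["non_unique"] = pd.DataFrame(dup_rows, columns=cols)
    anchors = pd.DataFrame(anchor_rows, columns=["kind", "chrom", "pos", "strand"])
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "ref", "alt"])
    return anchors, snps


# --------------------------------------------------------------------- counts

def _assign_truth(config: SimConfig, circ_ids: list[str]) -> pd.DataFrame:
    """Deterministic regulator/direction/dependence assignment per circRNA."""
    rows = []
    blocks = ([("ADAR1", "promoted")] * config.n_promoted
              + [("ADAR1", "repressed")] * config.n_repressed
              + [("ADAR2", "promoted")] * config.n_promoted
              + [("ADAR2", "repressed")] * config.n_repressed
              + [("both", "promoted")] * config.n_both)
    for i, cid in enumerate(circ_ids):
        if i < len(blocks):
            reg, direction = blocks[i]
            dependence = "editing-dependent" if i % 2 == 0 else "editing-independent"
        else:
            reg, direction, dependence = "none", "none", "n/a"
        rows.append({"circ_id": cid, "regulator": reg, "direction": direction,
                     "dependence": dependence})
    return pd.DataFrame(rows)


def simulate_bsj_counts(bundle: GenomeBundle,
                        config: SimConfig) -> tuple[CircCountMatrix, pd.DataFrame]:
    """Negative-binomial BSJ counts with planted ADAR effects.

    Promoted circs: OE mean x fc_effect, KD mean / fc_effect (repressed:
    inverse).  Editing-dependent circs keep DeAD mean equal to the EV mean;
    editing-independent circs shift DeAD in the wildtype direction by
    ``dead_fc_independent``.  ``zero_noise`` emits the rounded means.
    """
    rng = _rng(config, 1)
    circs = bundle.circs
    truth = _assign_truth(config, list(circs["circ_id"]))
    truth = truth.merge(
        circs[["circ_id", "chrom", "start", "end", "strand"]], on="circ_id")
    truth["key"] = [junction_key(r.chrom, r.start, r.end, r.strand)
                    for r in truth.itertuples()]

    samples = [f"{reg}_{cond}" for reg in REGULATORS for cond in CONDITIONS]
    design = pd.DataFrame(
        [{"sample": f"{reg}_{cond}", "regulator": reg, "condition": cond}
         for reg in REGULATORS for cond in CONDITIONS])

    means = np.full((len(circs), len(samples)), float(config.base_mean))
    col = {s: k for k, s in enumerate(samples)}
    fc, dfc = config.fc_effect, config.dead_fc_independent
    for i, row in truth.iterrows():
        regs = REGULATORS if row["regulator"] == "both" else (
            (row["regulator"],) if row["regulator"] in REGULATORS else ())
        for reg in regs:
            up = row["direction"] == "promoted"
            means[i, col[f"{reg}_OE"]] = config.base_mean * (fc if up else 1 / fc)
            means[i, col[f"{reg}_KD"]] = config.base_mean * (1 / fc if up else fc)
            if row["dependence"] == "editing-independent":
                means[i, col[f"{reg}_DeAD"]] = config.base_mean * (dfc if up else 1 / dfc)
    if config.depth_factors:
        for s, f in config.depth_factors.items():
            means[:, col[s]] *= float(f)

    if config.zero_noise:
        counts = np.rint(means).astype(np.int64)
    elif config.nb_dispersion <= 0:
        counts = rng.poisson(means).astype(np.int64)
    else:
        n = 1.0 / config.nb_dispersion
        p = n / (n + means)
        counts = rng.negative_binomial(n, p).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=list(truth["key"]), columns=samples)
    junctions = truth[["key", "chrom", "start", "end", "strand"]].copy()
    matrix = CircCountMatrix(junctions=junctions, counts=counts_df, design=design)
    return matrix, truth[["circ_id", "key", "regulator", "direction", "dependence"]]


# ------------------------------------------------------------- site evidence

def _run_length_at(seq: str, pos: int) -> int:
    """Length of the homopolymer run containing a 1-based position."""
    b = seq[pos - 1]
    i = pos - 1
    while i > 0 and seq[i - 1] == b:
        i -= 1
    j = pos - 1
    while j < len(seq) - 1 and seq[j + 1] == b:
        j += 1
    return j - i + 1


def _true_site_positions(bundle: GenomeBundle, config: SimConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Choose clean gene-strand 'A' positions in circ flanking introns.

    Positions inside planted arms are accepted (they are Alu-exempt in the
    filter cascade); elsewhere a position must sit clear of every regional
    filter so the cascade retains all true sites by construction.
    """
    arm_ivs: dict[str, list[tuple[int, int]]] = {}
    for r in bundle.circs.itertuples():
        arm_ivs.setdefault(r.chrom, []).extend(
            [(r.up_arm_start, r.up_arm_end), (r.down_arm_start, r.down_arm_end)])
    avoid: dict[str, list[tuple[int, int]]] = {}
    for name in ("simple_repeat", "non_unique", "homopolymer"):
        pad = 26 if name == "non_unique" else 1
        for r in bundle.tracks.get(name, pd.DataFrame()).itertuples():
            avoid.setdefault(r.chrom, []).append((r.start - pad, r.end + pad))
    snp_pos = {(r.chrom, r.pos) for r in bundle.snps.itertuples()}

    pool = []
    for r in bundle.circs.itertuples():
        for s, e in ((r.up_intron_start, r.up_intron_end),
                     (r.down_intron_start, r.down_intron_end)):
            edge = e if e < r.start else s  # BSJ-proximal intron edge
            if edge == e:
                lo, hi = max(s, e - 1499), e
            else:
                lo, hi = s, min(e, s + 1499)
            pool.extend((r.chrom, p, r.strand, r.circ_id, s, e) for p in range(lo, hi + 1))
    order = rng.permutation(len(pool))

    chosen, used = [], set()
    for idx in order:
        chrom, pos, strand, circ_id, i_s, i_e = pool[idx]
        if len(chosen) >= config.n_edit_sites:
            break
        if (chrom, pos) in used or (chrom, pos) in snp_pos:
            continue
        if bundle.gene_strand_base(chrom, pos, strand) != "A":
            continue
        in_arm = any(a <= pos <= b for a, b in arm_ivs.get(chrom, ()))
        if not in_arm:
            if any(a - 2 <= pos <= b + 2 for a, b in arm_ivs.get(chrom, ())):
                continue  # keep clear of arm guard bases
            if min(pos - i_s, i_e - pos) + 1 <= 4:
                continue
            if _run_length_at(bundle.seqs[chrom], pos) >= 5:
                continue
            if any(a <= pos <= b for a, b in avoid.get(chrom, ())):
                continue
        used.add((chrom, pos))
        chosen.append({"chrom": chrom, "pos": pos, "strand": strand,
                       "circ_id": circ_id, "in_arm": in_arm})
    if len(chosen) < config.n_edit_sites:
        raise SimulationSizingError(
            f"only {len(chosen)} clean intronic 'A' positions available for "
            f"{config.n_edit_sites} requested true sites")
    return pd.DataFrame(chosen)


def simulate_site_evidence(bundle: GenomeBundle,
                           config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial pileup evidence for true sites, planted decoys and background.

    Alt counts are Binomial(coverage, level) at true sites and decoys and
    Binomial(coverage, seq_error) elsewhere; SNP decoys sit at level 0.5 in
    both samples; the first6 decoy's alt support lies entirely within the
    first six read bases.
    """
    rng = _rng(config, 2)
    lv_c, lv_o = config.edit_level_control, config.edit_level_oe

    sites = []
    true_pos = _true_site_positions(bundle, config, rng)
    for r in true_pos.itertuples():
        sites.append({"chrom": r.chrom, "pos": r.pos, "strand": r.strand,
                      "circ_id": r.circ_id, "in_arm": r.in_arm, "is_true": True,
                      "decoy_class": "none", "level_ctrl": lv_c, "level_oe": lv_o})
    anchors = getattr(bundle, "anchors", pd.DataFrame(columns=["kind", "chrom", "pos", "strand"]))
    for r in anchors.itertuples():
        lev = (0.5, 0.5) if r.kind == "snp" else (lv_c, lv_o)
        sites.append({"chrom": r.chrom, "pos": r.pos, "strand": r.strand,
                      "circ_id": "", "in_arm": False, "is_true": False,
                      "decoy_class": r.kind, "level_ctrl": lev[0], "level_oe": lev[1]})
    for _ in range(config.n_background_sites):
        g = int(rng.integers(0, config.n_genes))
        gene = bundle.genes.iloc[g]
        pos = int(rng.integers(gene["start"], gene["end"] + 1))
        sites.append({"chrom": gene["chrom"], "pos": pos, "strand": gene["strand"],
                      "circ_id": "", "in_arm": False, "is_true": False,
                      "decoy_class": "none", "level_ctrl": 0.0, "level_oe": 0.0})
    truth = pd.DataFrame(sites)
    truth.insert(0, "site_id", [f"site{i + 1}" for i in range(len(truth))])

    bases = "ACGT"
    rows = []
    for r in truth.itertuples():
        ref = bundle.base(r.chrom, r.pos)
        edit_alt = ("G" if r.strand == "+" else "C")  # gene-strand A->G
        for sample, level in (("EV", r.level_ctrl), ("OE", r.level_oe)):
            cov = max(1, int(rng.poisson(config.coverage_mean)))
            alt = {b: 0 for b in bases}
            if level > 0 and edit_alt != ref:
                if config.zero_noise:
                    alt[edit_alt] = int(round(cov * level))
                else:
                    alt[edit_alt] = int(rng.binomial(cov, level))
            for b in bases:
                if b != ref and b != edit_alt and config.seq_error > 0:
                    alt[b] += int(rng.binomial(cov, config.seq_error))
            main_alt = alt[edit_alt]
            if r.decoy_class == "first6":
                first6 = main_alt
            else:
                first6 = int(rng.binomial(main_alt, 0.06)) if main_alt else 0
            rows.append({"chrom": r.chrom, "pos": r.pos, "strand": r.strand,
                         "ref": ref, "sample": sample, "cov": cov,
                         "alt_A": alt["A"], "alt_C": alt["C"],
                         "alt_G": alt["G"], "alt_T": alt["T"],
                         "alt_first6": first6})
    evidence = pd.DataFrame(rows)
    return evidence, truth


# ---------------------------------------------------------- chimeric records

CHIMERIC_COLUMNS = ["chrom_donor", "pos_donor", "strand_donor", "chrom_acceptor",
                    "pos_acceptor", "strand_acceptor", "junction_type",
                    "repeat_left", "repeat_right", "read_name"]


def emit_chimeric_records(bundle: GenomeBundle, matrix: CircCountMatrix,
                          seed: int = 0, n_linear_noise: int = 3) -> dict[str, pd.DataFrame]:
    """Per-sample chimeric-junction evidence tables (STAR-style columns).

    Each BSJ read becomes one head-to-tail record; ``n_linear_noise``
    linear-order chimeras per sample are added as negatives that a parser
    must reject.
    """
    rng = np.random.default_rng([4, seed])
    junctions = matrix.junctions
    out = {}
    for sample in matrix.counts.columns:
        rows = []
        k = 0
        for r in junctions.itertuples():
            n = int(matrix.counts.at[r.key, sample])
            donor, acceptor = (r.end, r.start) if r.strand == "+" else (r.start, r.end)
            for _ in range(n):
                k += 1
                rows.append((r.chrom, donor, r.strand, r.chrom, acceptor,
                             r.strand, 1, 0, 0, f"{sample}_read{k}"))
        for j in range(n_linear_noise):
            r = junctions.iloc[int(rng.integers(0, len(junctions)))]
            donor, acceptor = (r.end, r.start) if r.strand == "+" else (r.start, r.end)
            # swapped orientation = ordinary linear splice, not a back-splice
            rows.append((r.chrom, acceptor, r.strand, r.chrom, donor,
                         r.strand, 1, 0, 0, f"{sample}_noise{j}"))
        out[sample] = pd.DataFrame(rows, columns=CHIMERIC_COLUMNS)
    return out


# --------------------------------------------------------------- assay tables

def simulate_assay_tables(config: SimConfig, true_fc: float = 2.0,
                          n_replicates: int = 3, ct_noise_sd: float = 0.05,
                          clone_p: float = 0.3, n_clones: int = 25,
                          n_patients: int = 20, frac_adar1_up: float = 0.6,
                          frac_concordant: float = 0.7) -> dict[str, pd.DataFrame]:
    """Ct tables, TA-clone sets and patient tumor/NT expression pairs."""
    rng = _rng(config, 3)
    sd = 0.0 if config.zero_noise else ct_noise_sd

    qpcr = []
    for grp, fc in (("control", 1.0), ("treatment", true_fc)):
        for i in range(n_replicates):
            ct_ref = 15.0 + rng.normal(0, sd)
            ct_t = 22.0 - np.log2(fc) + rng.normal(0, sd)
            qpcr.append({"sample": f"{grp}{i + 1}", "group": grp,
                         "ct_target": ct_t, "ct_ref": ct_ref})
    qpcr = pd.DataFrame(qpcr)
    qpcr.attrs["true_fc"] = true_fc

    n_g = int(rng.binomial(n_clones, clone_p))
    clones = pd.DataFrame([{"site": "site1", "n_A": n_clones - n_g, "n_G": n_g,
                            "true_p": clone_p}])

    patients = []
    n_up = int(round(frac_adar1_up * n_patients))
    for i in range(n_patients):
        up = i < n_up
        concordant = rng.random() < frac_concordant
        adar1_ratio = rng.uniform(1.5, 3.0) if up else rng.uniform(0.3, 0.8)
        if concordant:
            circ_ratio = rng.uniform(2.0, 4.0) if up else rng.uniform(0.2, 0.5)
        else:
            circ_ratio = rng.uniform(0.8, 1.5)
        nt_a, nt_c = rng.uniform(0.5, 2.0), rng.uniform(0.5, 2.0)
        patients.append({"patient": f"P{i + 1}", "adar1_nt": nt_a,
                         "adar1_tumor": nt_a * adar1_ratio, "circ_nt": nt_c,
                         "circ_tumor": nt_c * circ_ratio,
                         "true_group": "ADAR1-up" if up else "ADAR1-down",
                         "true_concordant": concordant})
    patients = pd.DataFrame(patients)
    return {"qpcr": qpcr, "clones": clones, "patients": patients}
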