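"""A-to-I editing-site calling through the published filter cascade.

Variant candidates need >= 2 alt-supporting reads in a sample.  Candidates
are then filtered by, in order: known SNP positions; sites whose alt support
survives only within the first six read bases (random-hexamer mispriming);
and, for sites not inside Alu-like elements, splice-proximal positions
(<= 4 nt into an intron), homopolymer runs (>= 5 identical bases), simple
repeats and non-unique regions (the centred 50-mer occurs more than once in
the genome, either strand - a deterministic stand-in for a BLAT mappability
check).  Finally only A->G changes on the annotated gene strand are kept.
High-confidence sites additionally need >= 10x coverage in >= 1 sample and a
> 10 percentage-point editing-level change between treatment and control.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import GenomeBundle, revcomp

log = logging.getLogger(__name__)

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
FLAG_NAMES = ("in_alu", "near_splice_intronic", "homopolymer",
              "simple_repeat", "non_unique")


def call_candidates(evidence: pd.DataFrame, min_alt: int = 2) -> pd.DataFrame:
    """Per-sample variant candidates: alt-base rows with >= min_alt support.

    Adds gene-strand ref/alt and the editing level alt/(alt + ref reads).
    ``alt_first6`` in the evidence refers to the strongest alt base of the
    row and is propagated to that candidate only.
    """
    rows = []
    for r in evidence.itertuples():
        alts = {b: getattr(r, f"alt_{b}") for b in _BASES if b != r.ref}
        if any(a > r.cov for a in alts.values()):
            raise ValueError(f"alt exceeds coverage at {r.chrom}:{r.pos}")
        ref_reads = r.cov - sum(alts.values())
        primary = max(alts, key=lambda b: (alts[b], b)) if alts else None
        for b, n in alts.items():
            if n < min_alt:
                continue
            first6 = r.alt_first6 if b == primary else 0
            if first6 > n:
                raise ValueError(f"first6 support exceeds alt at {r.chrom}:{r.pos}")
            ref_gs = r.ref if r.strand == "+" else _COMP[r.ref]
            alt_gs = b if r.strand == "+" else _COMP[b]
            rows.append({"chrom": r.chrom, "pos": r.pos, "strand": r.strand,
                         "sample": r.sample, "ref": r.ref, "alt": b,
                         "ref_gs": ref_gs, "alt_gs": alt_gs,
                         "cov": r.cov, "n_alt": n, "alt_first6": first6,
                         "level": n / (n + ref_reads) if n + ref_reads else np.nan})
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "sample", "ref",
                                       "alt", "ref_gs", "alt_gs", "cov", "n_alt",
                                       "alt_first6", "level"])


# ----------------------------------------------------------------- flagging

def run_length_at(seq: str, pos: int) -> int:
    """Length of the homopolymer run containing the 1-based position."""
    b = seq[pos - 1]
    i = pos - 1
    while i > 0 and seq[i - 1] == b:
        i -= 1
    j = pos - 1
    while j < len(seq) - 1 and seq[j + 1] == b:
        j += 1
    return j - i + 1


def kmer_occurrences(bundle: GenomeBundle, kmer: str) -> int:
    """Exact occurrence count of a k-mer in the genome, both strands."""
    total = 0
    for query in (kmer, revcomp(kmer)):
        for seq in bundle.seqs.values():
            start = 0
            while True:
                hit = seq.find(query, start)
                if hit < 0:
                    break
                total += 1
                start = hit + 1
    return total


def annotate_flags(bundle: GenomeBundle, sites: pd.DataFrame,
                   splice_prox: int = 4, hom_min_run: int = 5,
                   uniq_k: int = 50) -> pd.DataFrame:
    """Compute the regional filter flags for unique (chrom, pos) sites."""
    track_ivs: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for name in ("alu", "simple_repeat"):
        d: dict[str, list[tuple[int, int]]] = {}
        for r in bundle.tracks.get(name, pd.DataFrame()).itertuples():
            d.setdefault(r.chrom, []).append((int(r.start), int(r.end)))
        track_ivs[name] = d
    introns: dict[str, list[tuple[int, int]]] = {}
    for r in bundle.introns.itertuples():
        introns.setdefault(r.chrom, []).append((int(r.start), int(r.end)))

    half_left = uniq_k // 2 - 1
    rows = []
    for chrom, pos in sites[["chrom", "pos"]].drop_duplicates().itertuples(index=False):
        seq = bundle.seqs[chrom]
        if pos < 1 or pos > len(seq):
            raise ValueError(f"site {chrom}:{pos} outside genome")
        in_alu = any(s <= pos <= e for s, e in track_ivs["alu"].get(chrom, ()))
        simple_rep = any(s <= pos <= e
                         for s, e in track_ivs["simple_repeat"].get(chrom, ()))
        near_splice = any(
            s <= pos <= e and min(pos - s, e - pos) + 1 <= splice_prox
            for s, e in introns.get(chrom, ()))
        hom = run_length_at(seq, pos) >= hom_min_run
        w_s, w_e = pos - half_left, pos + (uniq_k - half_left - 1)
        if w_s < 1 or w_e > len(seq):
            non_unique = False  # truncated window near a contig edge
        else:
            non_unique = kmer_occurrences(bundle, seq[w_s - 1 : w_e]) > 1
        rows.append({"chrom": chrom, "pos": pos, "in_alu": in_alu,
                     "near_splice_intronic": near_splice, "homopolymer": hom,
                     "simple_repeat": simple_rep, "non_unique": non_unique})
    return pd.DataFrame(rows, columns=["chrom", "pos", *FLAG_NAMES])


# ------------------------------------------------------------------ cascade

def filter_cascade(candidates: pd.DataFrame, snps: pd.DataFrame,
                   flags: pd.DataFrame, min_alt: int = 2
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the editing filter cascade; returns (sites, per-step audit).

    Output rows are unique (chrom, pos): A->G sites on the gene strand that
    survive every filter in at least one sample.
    """
    for name in FLAG_NAMES:
        if name not in flags.columns:
            raise ValueError(f"missing flag column {name!r}")
    cand = candidates.merge(flags, on=["chrom", "pos"], how="left", validate="m:1")
    if cand[list(FLAG_NAMES)].isna().any().any():
        missing = cand[cand[list(FLAG_NAMES)].isna().any(axis=1)]
        raise ValueError(f"sites lack flags: {missing[['chrom', 'pos']].values[:5]}")

    audit = []

    def note(step, df):
        audit.append({"step": step, "n_sites": df[["chrom", "pos"]]
                      .drop_duplicates().shape[0]})

    note("candidates", cand)
    snp_pos = {(r.chrom, r.pos) for r in snps.itertuples()}
    cand = cand[[(c, p) not in snp_pos
                 for c, p in zip(cand["chrom"], cand["pos"])]]
    note("snp_removed", cand)

    cand = cand[cand["n_alt"] - cand["alt_first6"] >= min_alt]
    note("first6_removed", cand)

    nonalu_bad = (~cand["in_alu"]) & (
        cand["near_splice_intronic"] | cand["homopolymer"]
        | cand["simple_repeat"] | cand["non_unique"])
    cand = cand[~nonalu_bad]
    note("regional_removed", cand)

    cand = cand[(cand["ref_gs"] == "A") & (cand["alt_gs"] == "G")]
    note("a_to_g_only", cand)

    sites = (cand[["chrom", "pos", "strand", "ref_gs", "alt_gs", "in_alu"]]
             .drop_duplicates(subset=["chrom", "pos"])
             .reset_index(drop=True))
    audit_df = pd.DataFrame(audit)
    log.info("filter cascade:\n%s", audit_df.to_string(index=False))
    return sites, audit_df


def summarize_sites(sites: pd.DataFrame, evidence: pd.DataFrame) -> pd.DataFrame:
    """Attach per-sample coverage and editing level (A->G) to called sites."""
    out = sites.copy()
    samples = sorted(evidence["sample"].unique())
    ev_idx = evidence.set_index(["chrom", "pos", "sample"])
    for s in samples:
        covs, levels = [], []
        for r in sites.itertuples():
            row = ev_idx.loc[(r.chrom, r.pos, s)]
            alt_base = "G" if r.strand == "+" else "C"
            n_alt = int(row[f"alt_{alt_base}"])
            ref_reads = int(row["cov"]) - sum(int(row[f"alt_{b}"]) for b in _BASES)
            covs.append(int(row["cov"]))
            levels.append(n_alt / (n_alt + ref_reads) if n_alt + ref_reads else np.nan)
        out[f"cov_{s}"] = covs
        out[f"level_{s}"] = levels
    return out


def high_confidence(sites: pd.DataFrame, control: str = "EV", treatment: str = "OE",
                    min_cov: int = 10, min_delta: float = 0.10) -> pd.DataFrame:
    """Keep sites with >= min_cov reads in >= 1 sample and a level change
    strictly greater than min_delta between treatment and control."""
    cov_cols = [c for c in sites.columns if c.startswith("cov_")]
    covered = sites[cov_cols].max(axis=1) >= min_cov
    delta = (sites[f"level_{treatment}"] - sites[f"level_{control}"]).abs()
    return sites[covered & (delta > min_delta)].reset_index(drop=True)


# ------------------------------------------------------------------ summaries

def mismatch_spectrum(candidates: pd.DataFrame) -> pd.Series:
    """Proportions of the 12 substitution types on gene strands."""
    if candidates.empty:
        raise ValueError("no candidates: mismatch spectrum undefined")
    types = [f"{r}>{a}" for r in _BASES for a in _BASES if r != a]
    labels = candidates["ref_gs"] + ">" + candidates["alt_gs"]
    counts = labels.value_counts().reindex(types, fill_value=0)
    return counts / counts.sum()


def context_ppm(sites: pd.DataFrame, bundle: GenomeBundle,
                flank: int = 2) -> pd.DataFrame:
    """Position probability matrix of the +/- ``flank`` nt context of sites.

    Contexts are taken strand-specifically (minus-strand sites are reverse
    complemented); sites too close to a contig edge are excluded with a
    warning.  Columns are positions -flank..+flank and each sums to 1.
    """
    width = 2 * flank + 1
    counts = np.zeros((4, width), dtype=float)
    n_skipped = 0
    for r in sites.itertuples():
        seq = bundle.seqs[r.chrom]
        if r.pos - flank < 1 or r.pos + flank > len(seq):
            n_skipped += 1
            continue
        ctx = seq[r.pos - flank - 1 : r.pos + flank]
        if r.strand == "-":
            ctx = revcomp(ctx)
        for k, base in enumerate(ctx):
            counts[_BASES.index(base), k] += 1
    if n_skipped:
        log.warning("context_ppm: %d sites skipped at contig edges", n_skipped)
    total = counts.sum(axis=0)
    if (total == 0).any():
        raise ValueError("no usable sites for context PPM")
    ppm = counts / total
    return pd.DataFrame(ppm, index=list(_BASES),
                        columns=range(-flank, flank + 1))
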