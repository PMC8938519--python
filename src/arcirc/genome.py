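"""Toy-genome container and coordinate helpers.

All coordinates in memory are 1-based, fully closed intervals; a back-splice
junction (BSJ) is keyed ``chrom:start-end:strand`` with ``start < end``.
BED files are written/read in the standard 0-based half-open convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

CIRC_COLUMNS = [
    "circ_id", "gene_id", "chrom", "start", "end", "strand",
    "up_intron_start", "up_intron_end", "down_intron_start", "down_intron_end",
    "up_arm_start", "up_arm_end", "down_arm_start", "down_arm_end",
]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def junction_key(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}-{end}:{strand}"


def parse_junction_key(key: str) -> tuple[str, int, int, str]:
    chrom, rest, strand = key.rsplit(":", 2)
    start, end = rest.split("-")
    return chrom, int(start), int(end), strand


@dataclass
class GenomeBundle:
    """A multi-gene toy genome plus the annotation tracks the pipeline consumes.

    ``seqs`` maps chromosome name to its plus-strand sequence.  ``genes``,
    ``exons`` and ``introns`` carry 1-based closed intervals; ``tracks`` holds
    the repeat-style annotations (``alu``, ``homopolymer``, ``simple_repeat``,
    ``non_unique``) and ``snps`` the known polymorphic positions.  ``circs``
    records the designed circRNA-forming exon pairs, their flanking introns
    and, when planted, the inverted-repeat (RCM) arm coordinates.
    """

    seqs: dict[str, str]
    genes: pd.DataFrame
    exons: pd.DataFrame
    introns: pd.DataFrame
    circs: pd.DataFrame
    tracks: dict[str, pd.DataFrame] = field(default_factory=dict)
    snps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    )

    # ------------------------------------------------------------------ seq
    def base(self, chrom: str, pos: int) -> str:
        """Plus-strand base at a 1-based position."""
        return self.seqs[chrom][pos - 1]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Plus-strand sequence of the closed interval [start, end]."""
        if start < 1 or end > len(self.seqs[chrom]):
            raise ValueError(f"interval {chrom}:{start}-{end} outside genome")
        return self.seqs[chrom][start - 1 : end]

    def gene_strand_base(self, chrom: str, pos: int, strand: str) -> str:
        b = self.base(chrom, pos)
        return b if strand == "+" else b.translate(_COMPLEMENT)

    # ------------------------------------------------------------ structure
    def gene_of_chrom(self, chrom: str) -> pd.Series:
        rows = self.genes[self.genes["chrom"] == chrom]
        if rows.empty:
            raise KeyError(f"no gene on {chrom}")
        return rows.iloc[0]

    def exon_boundaries(self, chrom: str) -> tuple[set[int], set[int]]:
        """(exon starts, exon ends) on a chromosome, 1-based closed."""
        ex = self.exons[self.exons["chrom"] == chrom]
        return set(ex["start"]), set(ex["end"])

    def splice_sites(self, chrom: str) -> list[tuple[int, int]]:
        """Intron intervals on a chromosome (their edges are splice sites)."""
        it = self.introns[self.introns["chrom"] == chrom]
        return list(zip(it["start"], it["end"]))

    # ----------------------------------------------------------------- I/O
    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "genome.fa"), "w") as fh:
            for chrom in sorted(self.seqs, key=_chrom_sort_key):
                fh.write(f">{chrom}\n")
                seq = self.seqs[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        self.genes.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
        for name, df in (("exons", self.exons), ("introns", self.introns)):
            _write_bed6(df, os.path.join(outdir, f"{name}.bed"))
        for name, df in self.tracks.items():
            _write_bed6(df, os.path.join(outdir, f"{name}.bed"))
        self.snps.to_csv(os.path.join(outdir, "snps.tsv"), sep="\t", index=False)
        self.circs.to_csv(os.path.join(outdir, "circs.tsv"), sep="\t", index=False)
        anchors = getattr(self, "anchors", None)
        if anchors is not None:
            anchors.to_csv(os.path.join(outdir, "anchors.tsv"), sep="\t",
                           index=False)

    @classmethod
    def load(cls, indir: str) -> "GenomeBundle":
        import pyfaidx

        fa = pyfaidx.Fasta(os.path.join(indir, "genome.fa"))
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        genes = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t")
        exons = _read_bed6(os.path.join(indir, "exons.bed"))
        introns = _read_bed6(os.path.join(indir, "introns.bed"))
        tracks = {}
        for name in ("alu", "homopolymer", "simple_repeat", "non_unique"):
            path = os.path.join(indir, f"{name}.bed")
            if os.path.exists(path):
                tracks[name] = _read_bed6(path)
        snps = pd.read_csv(os.path.join(indir, "snps.tsv"), sep="\t")
        circs = pd.read_csv(os.path.join(indir, "circs.tsv"), sep="\t")
        bundle = cls(seqs=seqs, genes=genes, exons=exons, introns=introns,
                     circs=circs, tracks=tracks, snps=snps)
        anchors_path = os.path.join(indir, "anchors.tsv")
        if os.path.exists(anchors_path):
            bundle.anchors = pd.read_csv(anchors_path, sep="\t")
        return bundle


def _chrom_sort_key(chrom: str):
    tail = chrom.lstrip("chr")
    return (0, int(tail)) if tail.isdigit() else (1, tail)


def _write_bed6(df: pd.DataFrame, path: str) -> None:
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"] - 1,  # to 0-based half-open
        "end": df["end"],
        "name": df.get("name", pd.Series(["."] * len(df))).fillna("."),
        "score": 0,
        "strand": df.get("strand", pd.Series(["."] * len(df))).fillna("."),
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def _read_bed6(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    df["start"] = df["start"] + 1  # back to 1-based closed
    return df


def flanking_introns(bundle: GenomeBundle, circ: pd.Series) -> tuple[str, str]:
    """Gene-oriented (5'->3') sequences of the two flanking introns of a circ.

    The upstream intron is the one immediately gene-upstream of the back-splice
    acceptor; the downstream intron immediately gene-downstream of the donor.
    On minus-strand genes the returned sequences are reverse complements of the
    plus-strand genomic slices.
    """
    up = bundle.slice(circ["chrom"], int(circ["up_intron_start"]), int(circ["up_intron_end"]))
    down = bundle.slice(circ["chrom"], int(circ["down_intron_start"]), int(circ["down_intron_end"]))
    if circ["strand"] == "-":
        up, down = revcomp(up), revcomp(down)
    return up, down
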