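"""Back-splice junction quantification and junction-set comparison.

A chimeric-junction record evidences a back-splice read when both segments
map to the same chromosome and strand, the acceptor lies gene-upstream of
the donor (head-to-tail), and both breakpoints coincide exactly with
annotated exon boundaries.  CircRNA identity is ``(chrom, start, end)``:
strand is retained on every junction but excluded from identity when two
catalogues are compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd

from .genome import junction_key

log = logging.getLogger(__name__)


class BackspliceJunction(NamedTuple):
    chrom: str
    start: int  # 1-based, start < end
    end: int
    strand: str

    @property
    def key(self) -> str:
        return junction_key(self.chrom, self.start, self.end, self.strand)

    @property
    def identity(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class CircCountMatrix:
    """Junction x sample count matrix with the condition design.

    ``junctions`` has columns key/chrom/start/end/strand in row order matching
    ``counts`` (indexed by key); ``design`` maps sample -> regulator/condition.
    """

    junctions: pd.DataFrame
    counts: pd.DataFrame
    design: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.junctions["key"]) != list(self.counts.index):
            raise ValueError("junction order must match count-matrix rows")

    def samples_for(self, regulator: str, condition: str) -> list[str]:
        d = self.design
        sel = d[(d["regulator"] == regulator) & (d["condition"] == condition)]
        return list(sel["sample"])

    def condition_total(self, regulator: str, condition: str) -> pd.Series:
        samples = self.samples_for(regulator, condition)
        if not samples:
            raise KeyError(f"no sample for {regulator}/{condition}")
        return self.counts[samples].sum(axis=1)

    def write(self, counts_path: str, junctions_path: str | None = None) -> None:
        self.counts.rename_axis("key").to_csv(counts_path, sep="\t")
        if junctions_path:
            self.junctions.to_csv(junctions_path, sep="\t", index=False)


class ParseStats(NamedTuple):
    n_records: int
    n_accepted: int
    n_rejected: int
    n_malformed: int


def parse_chimeric_junctions(records: pd.DataFrame, exons: pd.DataFrame,
                             tolerance: int = 0) -> tuple[dict[BackspliceJunction, int], ParseStats]:
    """Tally back-splice reads from a chimeric-junction evidence table.

    ``records`` uses the documented column dialect (chrom/pos/strand per
    donor and acceptor segment).  ``exons`` provides annotated boundaries;
    breakpoints must match them within ``tolerance`` nt (default 0).
    Malformed rows are logged and skipped; unknown chromosomes are an error.
    """
    known = set(exons["chrom"])
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    for r in exons.itertuples():
        starts.setdefault(r.chrom, []).append(int(r.start))
        ends.setdefault(r.chrom, []).append(int(r.end))

    def at_boundary(values: list[int], pos: int) -> bool:
        return any(abs(pos - v) <= tolerance for v in values)

    tally: dict[BackspliceJunction, int] = {}
    n_acc = n_rej = n_bad = 0
    for row in records.itertuples(index=False):
        try:
            cd, pd_, sd = row.chrom_donor, int(row.pos_donor), row.strand_donor
            ca, pa, sa = row.chrom_acceptor, int(row.pos_acceptor), row.strand_acceptor
        except (AttributeError, TypeError, ValueError):
            n_bad += 1
            log.warning("malformed chimeric record skipped: %r", (row,))
            continue
        if cd not in known or ca not in known:
            raise ValueError(f"unknown chromosome in record: {cd}/{ca}")
        if cd != ca or sd != sa or sd not in "+-":
            n_rej += 1
            continue
        # head-to-tail: acceptor gene-upstream of donor
        if sd == "+":
            if not pa < pd_:
                n_rej += 1
                continue
            start, end = pa, pd_
            ok = at_boundary(starts.get(cd, []), pa) and at_boundary(ends.get(cd, []), pd_)
        else:
            if not pa > pd_:
                n_rej += 1
                continue
            start, end = pd_, pa
            ok = at_boundary(ends.get(cd, []), pa) and at_boundary(starts.get(cd, []), pd_)
        if not ok:
            n_rej += 1
            continue
        j = BackspliceJunction(cd, start, end, sd)
        tally[j] = tally.get(j, 0) + 1
        n_acc += 1
    stats = ParseStats(len(records), n_acc, n_rej, n_bad)
    log.info("chimeric parse: %d records, %d BSJ reads, %d rejected, %d malformed",
             *stats)
    return tally, stats


def build_catalogue(tallies: dict[str, dict[BackspliceJunction, int]],
                    design: pd.DataFrame | None = None,
                    min_reads: int = 1, min_samples: int = 1) -> CircCountMatrix:
    """Assemble per-sample tallies into a count matrix, applying the detection
    rule: keep junctions with >= ``min_reads`` in >= ``min_samples`` samples."""
    samples = list(tallies)
    all_j = sorted({j for t in tallies.values() for j in t})
    rows = []
    keep = []
    for j in all_j:
        counts = [tallies[s].get(j, 0) for s in samples]
        if sum(c >= min_reads for c in counts) >= min_samples:
            keep.append(j)
            rows.append(counts)
    junctions = pd.DataFrame(
        [{"key": j.key, "chrom": j.chrom, "start": j.start, "end": j.end,
          "strand": j.strand} for j in keep],
        columns=["key", "chrom", "start", "end", "strand"])
    counts = pd.DataFrame(rows, index=list(junctions["key"]), columns=samples,
                          dtype="int64")
    return CircCountMatrix(junctions=junctions, counts=counts,
                           design=design if design is not None else pd.DataFrame())


class OverlapResult(NamedTuple):
    fraction_a_in_b: float
    fraction_b_in_a: float
    n_shared: int
    shared: list[tuple[str, int, int]]
    only_a: list[tuple[str, int, int]]
    only_b: list[tuple[str, int, int]]


def junction_set_overlap(set_a: Iterable[BackspliceJunction | tuple],
                         set_b: Iterable[BackspliceJunction | tuple]) -> OverlapResult:
    """Exact chr-start-end overlap between two junction sets.

    Raises on an empty first set rather than silently returning NaN.
    """
    def ident(j):
        return j.identity if isinstance(j, BackspliceJunction) else tuple(j)[:3]

    a = {ident(j) for j in set_a}
    b = {ident(j) for j in set_b}
    if not a:
        raise ValueError("overlap fraction undefined: first set is empty")
    shared = a & b
    frac_a = len(shared) / len(a)
    frac_b = len(shared) / len(b) if b else float("nan")
    return OverlapResult(frac_a, frac_b, len(shared), sorted(shared),
                         sorted(a - b), sorted(b - a))
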