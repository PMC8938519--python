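"""Reverse-complementary-match discovery and BSJ-proximal profiling.

For each circRNA the upstream flanking intron is locally aligned against the
reverse complement of the downstream flanking intron; every alignment found
is an RCM candidate and the top scorer is retained per circRNA (ties break
towards the BSJ-proximal, then leftmost, arm pair).  CircRNAs with either
flanking intron shorter than 1500 bp are excluded from the final RCM set.
Coverage of top-scoring RCM arms and the density of editing sites are
profiled over the +/- 1500 nt intronic window around the BSJ, where -1 is
the intronic base adjacent to the back-splice acceptor and +1 the base
adjacent to the donor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignScoring, LocalAlignment, local_alignments
from .genome import GenomeBundle, flanking_introns


@dataclass
class RCM:
    """A reverse-complement alignment between two flanking introns.

    Arm coordinates are 0-based inclusive in the gene-oriented (5'->3')
    intron sequences; ``columns`` pair up-arm indices with down-arm indices
    (None marks a gap) and ``pairs`` lists the facing bases of each column.
    """

    up_start: int
    up_end: int
    down_start: int
    down_end: int
    score: int
    columns: list[tuple[int | None, int | None]] = field(default_factory=list)
    aln_up: str = ""
    aln_down: str = ""
    is_top: bool = False
    circ_id: str | None = None

    @property
    def length(self) -> int:
        return len(self.columns)

    def pairs(self, up_seq: str, down_seq: str) -> list[tuple[str | None, str | None]]:
        """Facing bases per column: (up base, down base), gene-oriented."""
        out = []
        for ui, di in self.columns:
            out.append((up_seq[ui] if ui is not None else None,
                        down_seq[di] if di is not None else None))
        return out


def _from_alignment(aln: LocalAlignment, down_len: int) -> RCM:
    """Map an up-vs-revcomp(down) alignment back to down-intron coordinates."""
    cols = []
    for ai, bi in aln.columns:
        cols.append((ai, down_len - 1 - bi if bi is not None else None))
    return RCM(up_start=aln.a_start, up_end=aln.a_end,
               down_start=down_len - 1 - aln.b_end,
               down_end=down_len - 1 - aln.b_start,
               score=aln.score, columns=cols)


def find_rcms(intron_up: str, intron_down: str,
              scoring: AlignScoring | None = None,
              min_score: int = 20, max_rcms: int = 10) -> list[RCM]:
    """Ranked non-overlapping RCMs between two gene-oriented intron sequences.

    The top RCM is the optimal local alignment of ``intron_up`` against
    ``revcomp(intron_down)``; equal scores prefer the pair with the smaller
    summed distance of arms to the BSJ (up-intron end / down-intron start),
    then the leftmost up-arm.  All-N input yields an empty list.
    """
    from .genome import revcomp

    sc = scoring or AlignScoring()
    if not intron_up or not intron_down:
        return []
    alns = local_alignments(intron_up, revcomp(intron_down), sc,
                            min_score=min_score, max_hits=max_rcms)
    rcms = [_from_alignment(a, len(intron_down)) for a in alns]
    rcms.sort(key=lambda r: (-r.score,
                             (len(intron_up) - 1 - r.up_end) + r.down_start,
                             r.up_start))
    for k, r in enumerate(rcms):
        r.is_top = k == 0
        r.aln_up = "".join(intron_up[ui] if ui is not None else "-"
                           for ui, _ in r.columns)
        r.aln_down = "".join(intron_down[di] if di is not None else "-"
                             for _, di in r.columns)
    return rcms


def scan_circs(bundle: GenomeBundle, circ_ids: list[str] | None = None,
               scoring: AlignScoring | None = None, min_score: int = 20,
               max_rcms: int = 5) -> dict[str, list[RCM]]:
    """Run the RCM finder on every circRNA's flanking intron pair."""
    out: dict[str, list[RCM]] = {}
    circs = bundle.circs
    if circ_ids is not None:
        circs = circs[circs["circ_id"].isin(circ_ids)]
    for _, circ in circs.iterrows():
        up, down = flanking_introns(bundle, circ)
        rcms = find_rcms(up, down, scoring, min_score=min_score, max_rcms=max_rcms)
        for r in rcms:
            r.circ_id = circ["circ_id"]
        out[circ["circ_id"]] = rcms
    return out


def eligible_circs(bundle: GenomeBundle, rcms: dict[str, list[RCM]],
                   min_intron: int = 1500) -> pd.DataFrame:
    """Filter circRNAs to those with both flanking introns >= min_intron bp
    and at least one RCM; exclusion reasons are recorded per circRNA."""
    rows = []
    for _, circ in bundle.circs.iterrows():
        up_len = int(circ["up_intron_end"] - circ["up_intron_start"] + 1)
        down_len = int(circ["down_intron_end"] - circ["down_intron_start"] + 1)
        n_rcm = len(rcms.get(circ["circ_id"], []))
        if n_rcm == 0:
            reason = "no RCM above score threshold"
        elif min(up_len, down_len) < min_intron:
            reason = f"flanking intron < {min_intron} bp"
        else:
            reason = ""
        rows.append({"circ_id": circ["circ_id"], "up_intron_len": up_len,
                     "down_intron_len": down_len, "n_rcm": n_rcm,
                     "eligible": reason == "", "reason": reason})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ profiles

def _relative_positions(circ: pd.Series) -> dict:
    """Lengths needed to map gene-oriented intron indices to BSJ offsets."""
    return {
        "up_len": int(circ["up_intron_end"] - circ["up_intron_start"] + 1),
        "down_len": int(circ["down_intron_end"] - circ["down_intron_start"] + 1),
    }


def rcm_coverage_profile(bundle: GenomeBundle, rcms: dict[str, list[RCM]],
                         eligible: pd.DataFrame | None = None,
                         window: int = 1500) -> pd.Series:
    """Per-base count of top-scoring RCM arms over the BSJ window.

    Position -1 is the intronic base adjacent to the acceptor, +1 adjacent
    to the donor; arm portions outside +/- window are clipped.  Both arms of
    a top RCM contribute, each to its own side of the junction.
    """
    index = list(range(-window, 0)) + list(range(1, window + 1))
    cov = pd.Series(0, index=index, dtype="int64")
    keep = None if eligible is None else set(
        eligible[eligible["eligible"]]["circ_id"])
    circ_by_id = bundle.circs.set_index("circ_id")
    for circ_id, rcm_list in rcms.items():
        if keep is not None and circ_id not in keep:
            continue
        tops = [r for r in rcm_list if r.is_top]
        if not tops:
            continue
        lens = _relative_positions(circ_by_id.loc[circ_id])
        for r in tops:
            # up-intron index i -> BSJ offset i - up_len (negative side)
            for i in range(r.up_start, r.up_end + 1):
                rel = i - lens["up_len"]
                if -window <= rel <= -1:
                    cov.at[rel] += 1
            for i in range(r.down_start, r.down_end + 1):
                rel = i + 1
                if 1 <= rel <= window:
                    cov.at[rel] += 1
    return cov


def site_bsj_offsets(bundle: GenomeBundle, sites: pd.DataFrame,
                     circ_ids: list[str] | None = None,
                     window: int = 1500) -> pd.DataFrame:
    """BSJ-relative offsets of editing sites in circRNA flanking introns."""
    circs = bundle.circs
    if circ_ids is not None:
        circs = circs[circs["circ_id"].isin(circ_ids)]
    rows = []
    for _, circ in circs.iterrows():
        lens = _relative_positions(circ)
        for r in sites.itertuples():
            if r.chrom != circ["chrom"]:
                continue
            rel = None
            u_s, u_e = int(circ["up_intron_start"]), int(circ["up_intron_end"])
            d_s, d_e = int(circ["down_intron_start"]), int(circ["down_intron_end"])
            if u_s <= r.pos <= u_e:
                local = (r.pos - u_s) if circ["strand"] == "+" else (u_e - r.pos)
                rel = local - lens["up_len"]
            elif d_s <= r.pos <= d_e:
                local = (r.pos - d_s) if circ["strand"] == "+" else (d_e - r.pos)
                rel = local + 1
            if rel is not None and -window <= rel <= window and rel != 0:
                rows.append({"circ_id": circ["circ_id"], "chrom": r.chrom,
                             "pos": r.pos, "offset": rel})
    return pd.DataFrame(rows, columns=["circ_id", "chrom", "pos", "offset"])


def editing_density_profile(offsets: pd.DataFrame, window: int = 1500,
                            bin_width: int = 50) -> pd.DataFrame:
    """Histogram density of editing-site offsets over the BSJ window.

    Density integrates to 1 over the window (sum of bin density x width).
    Raises if there are no sites in the window.
    """
    if offsets.empty:
        raise ValueError("no editing sites in the BSJ window: empty density")
    edges = np.arange(-window, window + bin_width, bin_width)
    counts, _ = np.histogram(offsets["offset"], bins=edges)
    density = counts / (counts.sum() * bin_width)
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                         "count": counts, "density": density})
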