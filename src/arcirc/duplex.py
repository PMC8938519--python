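"""Pair-class duplex model of an RCM and in-silico A-to-I editing effects.

The duplex implied by an RCM alignment is scored with simple pair weights
(G-C 3, A-U 2, G.U wobble 1, mismatch 0, gap -2) chosen so the two editing
mechanisms have opposite signs by construction: correcting an A:C mismatch
to an I(G)-C pair strictly increases the score, while converting an A-U
pair to the weaker I(G).U wobble strictly decreases it.  This replaces
thermodynamic folding: the biological claims modelled here concern
pair-class transitions, not free energies.  An optional re-alignment mode
re-aligns the edited arms and reports the better-scoring duplex,
approximating structural rearrangement of neighbouring regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .align import AlignScoring
from .rcm import RCM

_PAIRS = {frozenset("GC"): "GC", frozenset("AT"): "AU", frozenset("GT"): "GU"}


@dataclass(frozen=True)
class PairWeights:
    gc: int = 3
    au: int = 2
    gu: int = 1
    mismatch: int = 0
    gap: int = -2

    def __post_init__(self):
        if not self.gc > self.au > self.gu > self.mismatch:
            raise ValueError("weights must order GC > AU > GU > mismatch")


@dataclass(frozen=True)
class DuplexColumn:
    up_idx: int | None
    down_idx: int | None
    up_base: str | None   # DNA alphabet; T stands for U
    down_base: str | None

    @property
    def label(self) -> str:
        if self.up_base is None or self.down_base is None:
            return "gap"
        pair = _PAIRS.get(frozenset({self.up_base, self.down_base}))
        if pair and self.up_base != self.down_base:
            return pair
        return f"mismatch({self.up_base}:{self.down_base})"

    def weight(self, w: PairWeights) -> int:
        lab = self.label
        if lab == "gap":
            return w.gap
        return {"GC": w.gc, "AU": w.au, "GU": w.gu}.get(lab, w.mismatch)


@dataclass
class DuplexModel:
    columns: list[DuplexColumn]
    weights: PairWeights = field(default_factory=PairWeights)

    @property
    def score(self) -> int:
        return sum(c.weight(self.weights) for c in self.columns)

    def label_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.columns:
            lab = c.label if c.label == "gap" or ":" not in c.label else "mismatch"
            out[lab] = out.get(lab, 0) + 1
        return out

    def alignment_score(self, scoring: AlignScoring | None = None) -> int:
        """Re-score the duplex columns with the aligner's match/mismatch/gap
        scheme (cross-module audit against the RCM aligner score)."""
        sc = scoring or AlignScoring()
        score, gap_run = 0, 0
        for c in self.columns:
            if c.up_base is None or c.down_base is None:
                gap_run += 1
                continue
            if gap_run:
                score += sc.gap_cost(gap_run)
                gap_run = 0
            paired = _PAIRS.get(frozenset({c.up_base, c.down_base}))
            is_wc = paired in ("GC", "AU") and c.up_base != c.down_base
            score += sc.match if is_wc else sc.mismatch
        if gap_run:
            score += sc.gap_cost(gap_run)
        return score


@dataclass
class EditEffect:
    arm: str
    index: int
    before: str
    after: str
    delta: int

    @property
    def effect_class(self) -> str:
        if self.delta > 0:
            return "stabilizing"
        if self.delta < 0:
            return "destabilizing"
        return "neutral"


def build_duplex(rcm: RCM, up_seq: str, down_seq: str,
                 weights: PairWeights | None = None) -> DuplexModel:
    """Label every RCM alignment column with its facing base pair."""
    w = weights or PairWeights()
    cols = []
    for ui, di in rcm.columns:
        ub = up_seq[ui].upper() if ui is not None else None
        db = down_seq[di].upper() if di is not None else None
        cols.append(DuplexColumn(ui, di, ub, db))
    return DuplexModel(columns=cols, weights=w)


def apply_editing(duplex: DuplexModel, edits: list[tuple[str, int]],
                  realign: bool = False,
                  scoring: AlignScoring | None = None) -> DuplexModel:
    """A->G substitution at the given (arm, intron index) positions.

    Each edited position must carry an A on its arm.  With ``realign`` the
    edited arm sequences are re-aligned and the better of the relabelled and
    re-aligned duplexes is returned (re-alignment never reports lower).
    """
    by_pos = {("up", c.up_idx): k for k, c in enumerate(duplex.columns)
              if c.up_idx is not None}
    by_pos.update({("down", c.down_idx): k for k, c in enumerate(duplex.columns)
                   if c.down_idx is not None})
    cols = list(duplex.columns)
    for arm, idx in dict.fromkeys(edits):  # editing a site twice equals once
        key = (arm, idx)
        if key not in by_pos:
            raise ValueError(f"edit site {arm}:{idx} not inside the duplex")
        c = cols[by_pos[key]]
        base = c.up_base if arm == "up" else c.down_base
        if base != "A":
            raise ValueError(f"edit site {arm}:{idx} is {base}, not A")
        if arm == "up":
            cols[by_pos[key]] = replace(c, up_base="G")
        else:
            cols[by_pos[key]] = replace(c, down_base="G")
    relabelled = DuplexModel(columns=cols, weights=duplex.weights)
    if not realign:
        return relabelled
    realigned = _realign(relabelled, scoring)
    return realigned if realigned.score > relabelled.score else relabelled


def _realign(duplex: DuplexModel, scoring: AlignScoring | None) -> DuplexModel:
    from .rcm import find_rcms

    # rebuild each arm in gene orientation (down indices run antiparallel)
    up = "".join(b for _, b in sorted((c.up_idx, c.up_base) for c in duplex.columns
                                      if c.up_idx is not None))
    down = "".join(b for _, b in sorted((c.down_idx, c.down_base) for c in duplex.columns
                                        if c.down_idx is not None))
    rcms = find_rcms(up, down, scoring, min_score=1, max_rcms=1)
    if not rcms:
        return duplex
    return build_duplex(rcms[0], up, down, duplex.weights)


def classify_effects(duplex: DuplexModel, edits: list[tuple[str, int]],
                     realign: bool = False) -> dict:
    """Per-site and joint editing effects plus a circRNA-level verdict.

    The verdict is the sign of the joint score change when all sites are
    edited together; ``synergy`` flags a joint change exceeding the sum of
    the individual ones.
    """
    base_score = duplex.score
    effects = []
    for arm, idx in edits:
        edited = apply_editing(duplex, [(arm, idx)], realign=realign)
        before = next(c.label for c in duplex.columns
                      if (c.up_idx if arm == "up" else c.down_idx) == idx)
        after = next((c.label for c in edited.columns
                      if (c.up_idx if arm == "up" else c.down_idx) == idx),
                     "realigned")
        effects.append(EditEffect(arm, idx, before, after,
                                  edited.score - base_score))
    joint = apply_editing(duplex, edits, realign=realign)
    joint_delta = joint.score - base_score
    verdict = ("stabilizing" if joint_delta > 0
               else "destabilizing" if joint_delta < 0 else "neutral")
    return {
        "effects": effects,
        "joint_delta": joint_delta,
        "verdict": verdict,
        "synergy": joint_delta > sum(e.delta for e in effects),
    }
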