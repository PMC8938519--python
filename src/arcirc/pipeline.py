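"""End-to-end orchestration: simulate -> quantify -> classify -> editing ->
RCM -> duplex -> motifs -> report, with provenance capture.

Every published threshold is surfaced as a named parameter with its printed
default (fold-change 2.0 / 0.5, read gate 10, DeAD band 0.8-1.25, editing
level change 0.10, minimum flanking intron 1500 bp, +/- 1500 bp profile
window, +/- 10 nt motif window, 4 nt splice proximity, >= 2 supporting
reads), so any deviation is explicit in the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from .align import AlignScoring
from .classify import ClassifyThresholds, call_arcircs, classify_dependence, concordance
from .duplex import PairWeights, build_duplex, classify_effects
from .editing import (annotate_flags, call_candidates, context_ppm, filter_cascade,
                      high_confidence, mismatch_spectrum, summarize_sites)
from .genome import GenomeBundle, flanking_introns
from .motifs import PWM, edit_window, motif_change, rbp_circ_tally
from .rcm import (editing_density_profile, eligible_circs, rcm_coverage_profile,
                  scan_circs, site_bsj_offsets)
from .simulate import SimConfig, make_genome, simulate_bsj_counts, simulate_site_evidence

log = logging.getLogger(__name__)
REGULATORS = ("ADAR1", "ADAR2")


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: ClassifyThresholds = field(default_factory=ClassifyThresholds)
    level_delta: float = 0.10
    min_cov: int = 10
    min_alt: int = 2
    splice_prox: int = 4
    min_intron: int = 1500
    profile_window: int = 1500
    motif_half_width: int = 10
    motif_mode: str = "threshold"
    null_shuffles: int = 100
    rcm_min_score: int = 20
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = SimConfig(**data.pop("sim", {}))
        th = ClassifyThresholds(**data.pop("thresholds", {}))
        return cls(sim=sim, thresholds=th, **data)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def fixture_pwms(bundle: GenomeBundle, sites: pd.DataFrame, n_gain: int = 1,
                 n_loss: int = 1, motif_len: int = 9,
                 half_width: int = 10) -> tuple[list[PWM], pd.DataFrame]:
    """Consensus PWMs anchored on editing-site windows, for self-contained
    runs without an external motif collection.

    Gain motifs match the edited (G-centre) window of a site, loss motifs
    the reference (A-centre) window, so the corresponding edit deterministically
    creates or destroys the motif.  Returns the PWMs and the planted truth
    (rbp, circ_id, direction).
    """
    arm_sites = sites[sites.get("in_arm", False) & sites.get("is_true", True)]
    pool = arm_sites if len(arm_sites) >= n_gain + n_loss else sites
    pwms, truth = [], []
    half_m = motif_len // 2
    for k, (_, r) in enumerate(pool.head(n_gain + n_loss).iterrows()):
        ref_w, edit_w = edit_window(bundle, r["chrom"], int(r["pos"]), r["strand"],
                                    half_width=half_width)
        centre = len(ref_w) // 2
        gain = k < n_gain
        src = edit_w if gain else ref_w
        consensus = src[centre - half_m : centre + half_m + 1]
        name = f"RBP_{'gain' if gain else 'loss'}{k + 1}"
        pwms.append(PWM.from_consensus(name, consensus))
        truth.append({"rbp": name, "chrom": r["chrom"], "pos": int(r["pos"]),
                      "circ_id": r.get("circ_id", ""),
                      "direction": "gain" if gain else "loss"})
    return pwms, pd.DataFrame(truth)


def _arm_site_edits(circ: pd.Series, rcm, sites: pd.DataFrame) -> list[tuple[str, int]]:
    """Map called editing sites into (arm, intron-local index) edits."""
    edits = []
    u_s, u_e = int(circ["up_intron_start"]), int(circ["up_intron_end"])
    d_s, d_e = int(circ["down_intron_start"]), int(circ["down_intron_end"])
    plus = circ["strand"] == "+"
    for r in sites.itertuples():
        if r.chrom != circ["chrom"]:
            continue
        if u_s <= r.pos <= u_e:
            local = (r.pos - u_s) if plus else (u_e - r.pos)
            if rcm.up_start <= local <= rcm.up_end:
                edits.append(("up", local))
        elif d_s <= r.pos <= d_e:
            local = (r.pos - d_s) if plus else (d_e - r.pos)
            if rcm.down_start <= local <= rcm.down_end:
                edits.append(("down", local))
    return edits


def run_pipeline(config: PipelineConfig, pwms: list[PWM] | None = None) -> dict:
    """Execute the full analysis on a fresh simulation; returns all stage
    outputs plus a provenance manifest."""
    results: dict = {"config": config}
    stage = "simulate"
    try:
        bundle = make_genome(config.sim)
        matrix, circ_truth = simulate_bsj_counts(bundle, config.sim)
        evidence, site_truth = simulate_site_evidence(bundle, config.sim)
        results.update(bundle=bundle, matrix=matrix, circ_truth=circ_truth,
                       evidence=evidence, site_truth=site_truth)

        stage = "classify"
        calls = {}
        for reg in REGULATORS:
            c = call_arcircs(matrix, reg, config.thresholds)
            calls[reg] = classify_dependence(c, matrix, reg, config.thresholds)
        results["calls"] = calls
        results["concordance"] = concordance(calls["ADAR1"], calls["ADAR2"])

        stage = "editing"
        candidates = call_candidates(evidence, min_alt=config.min_alt)
        flags = annotate_flags(bundle, candidates, splice_prox=config.splice_prox)
        sites, audit = filter_cascade(candidates, bundle.snps, flags,
                                      min_alt=config.min_alt)
        sites = summarize_sites(sites, evidence)
        hc_sites = high_confidence(sites, min_cov=config.min_cov,
                                   min_delta=config.level_delta)
        results.update(candidates=candidates, cascade_audit=audit,
                       sites=sites, hc_sites=hc_sites,
                       spectrum=mismatch_spectrum(candidates),
                       ppm=context_ppm(hc_sites if len(hc_sites) else sites, bundle))

        stage = "rcm"
        rcms = scan_circs(bundle, scoring=AlignScoring(),
                          min_score=config.rcm_min_score)
        eligible = eligible_circs(bundle, rcms, min_intron=config.min_intron)
        coverage = rcm_coverage_profile(bundle, rcms, eligible,
                                        window=config.profile_window)
        elig_ids = list(eligible[eligible["eligible"]]["circ_id"])
        offsets = site_bsj_offsets(bundle, hc_sites, elig_ids,
                                   window=config.profile_window)
        density = (editing_density_profile(offsets, window=config.profile_window)
                   if len(offsets) else None)
        results.update(rcms=rcms, eligible=eligible, coverage_profile=coverage,
                       site_offsets=offsets, density_profile=density)

        stage = "duplex"
        verdicts = []
        circ_by_id = bundle.circs.set_index("circ_id", drop=False)
        for circ_id in elig_ids:
            tops = [r for r in rcms.get(circ_id, []) if r.is_top]
            if not tops:
                continue
            circ = circ_by_id.loc[circ_id]
            up, down = flanking_introns(bundle, circ)
            dpx = build_duplex(tops[0], up, down, PairWeights())
            edits = _arm_site_edits(circ, tops[0], hc_sites)
            if not edits:
                continue
            eff = classify_effects(dpx, edits)
            verdicts.append({"circ_id": circ_id, "n_sites": len(edits),
                             "joint_delta": eff["joint_delta"],
                             "verdict": eff["verdict"], "synergy": eff["synergy"]})
        results["duplex_verdicts"] = pd.DataFrame(
            verdicts, columns=["circ_id", "n_sites", "joint_delta", "verdict", "synergy"])

        stage = "motifs"
        if pwms is None:
            pwms, motif_truth = fixture_pwms(bundle, site_truth)
            results["motif_truth"] = motif_truth
        deltas = []
        mapped = offsets.merge(hc_sites[["chrom", "pos", "strand"]],
                               on=["chrom", "pos"])
        for r in mapped.itertuples():
            ref_w, edit_w = edit_window(bundle, r.chrom, r.pos, r.strand,
                                        half_width=config.motif_half_width)
            for pwm in pwms:
                d = motif_change(pwm, ref_w, edit_w, mode=config.motif_mode,
                                 null_shuffles=config.null_shuffles,
                                 seed=config.sim.seed)
                deltas.append({"circ_id": r.circ_id, "chrom": r.chrom,
                               "pos": r.pos, "rbp": d.rbp, "changed": d.changed,
                               "direction": d.direction,
                               "score_ref": d.score_ref, "score_edit": d.score_edit})
        deltas = pd.DataFrame(deltas, columns=["circ_id", "chrom", "pos", "rbp",
                                               "changed", "direction",
                                               "score_ref", "score_edit"])
        tally, n_over = rbp_circ_tally(deltas) if len(deltas) else (
            pd.DataFrame(columns=["rbp", "n_circs"]), 0)
        results.update(motif_deltas=deltas, rbp_tally=tally, n_rbps_over=n_over)
    except Exception as exc:  # noqa: BLE001 - halt with stage-named error
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    results["manifest"] = _manifest(config)
    if config.outdir:
        write_outputs(results, config.outdir)
    return results


def _manifest(config: PipelineConfig) -> dict:
    cfg = config.to_dict()
    return {
        "package": "arcirc",
        "version": __version__,
        "seed": config.sim.seed,
        "parameters": cfg,
        "config_checksum": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
    }


def report(results: dict) -> dict:
    """Summary tables of a pipeline run (percentages, concordance, tallies)."""
    out: dict = {}
    for reg in REGULATORS:
        calls = results["calls"][reg]
        called = calls[calls["called"]]
        n = len(called)
        out[reg] = {
            "n_called": n,
            "promoted_pct": 100.0 * (called["direction"] == "promoted").sum() / n
            if n else float("nan"),
            "repressed_pct": 100.0 * (called["direction"] == "repressed").sum() / n
            if n else float("nan"),
            "n_dependent": int((called["dependence"] == "dependent").sum()),
            "n_independent": int((called["dependence"] == "independent").sum()),
            "n_undetermined": int((called["dependence"] == "undetermined").sum()),
        }
    conc = results["concordance"]
    out["concordance"] = {k: conc[k] for k in
                          ("n_common", "n_same_direction", "n_opposite_direction")}
    out["n_editing_sites"] = len(results["sites"])
    out["n_high_confidence_sites"] = len(results["hc_sites"])
    cov = results["coverage_profile"]
    total = cov.sum()
    proximal = cov.loc[[p for p in cov.index if -500 <= p <= 500]].sum()
    out["rcm_coverage"] = {
        "total_mass": int(total),
        "proximal_fraction": float(proximal / total) if total else float("nan"),
    }
    out["duplex_verdicts"] = (results["duplex_verdicts"]["verdict"]
                              .value_counts().to_dict())
    out["rbp_tally"] = dict(zip(results["rbp_tally"]["rbp"],
                                results["rbp_tally"]["n_circs"]))
    return out


def write_outputs(results: dict, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    results["bundle"].write(os.path.join(outdir, "genome"))
    results["matrix"].write(os.path.join(outdir, "counts.tsv"),
                            os.path.join(outdir, "catalogue.tsv"))
    for reg in REGULATORS:
        results["calls"][reg].to_csv(os.path.join(outdir, f"calls_{reg}.tsv"),
                                     sep="\t", index=False)
    for name in ("sites", "hc_sites", "eligible", "site_offsets",
                 "duplex_verdicts", "motif_deltas", "rbp_tally",
                 "circ_truth", "site_truth", "cascade_audit"):
        df = results.get(name)
        if isinstance(df, pd.DataFrame):
            df.to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t", index=False)
    results["coverage_profile"].rename_axis("offset").rename("coverage").to_csv(
        os.path.join(outdir, "rcm_coverage.tsv"), sep="\t")
    if results.get("density_profile") is not None:
        results["density_profile"].to_csv(
            os.path.join(outdir, "editing_density.tsv"), sep="\t", index=False)
    results["spectrum"].rename_axis("substitution").rename("proportion").to_csv(
        os.path.join(outdir, "mismatch_spectrum.tsv"), sep="\t")
    results["ppm"].rename_axis("base").to_csv(os.path.join(outdir, "context_ppm.tsv"),
                                              sep="\t")
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(results["manifest"], fh, indent=2, default=str)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report(results), fh, indent=2, default=str)


def plot_profiles(results: dict, path: str) -> None:
    """RCM coverage and editing-density profile figure over the BSJ window."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cov = results["coverage_profile"]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(cov.index, cov.values, "k.", ms=2, label="RCM coverage")
    ax.set_xlabel("distance from BSJ (nt)")
    ax.set_ylabel("top RCM coverage")
    dens = results.get("density_profile")
    if dens is not None:
        ax2 = ax.twinx()
        centers = (dens["bin_start"] + dens["bin_end"]) / 2
        ax2.plot(centers, dens["density"], "r-", lw=1, label="editing density")
        ax2.set_ylabel("editing-site density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
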