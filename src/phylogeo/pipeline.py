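"""End-to-end hypothesis comparison.

Given a molecular supermatrix, a morphology matrix, locality records and an
ecoregion map, the pipeline builds four topological hypotheses — the
molecular consensus itself (MOT, the baseline), the morphology-tree
consensus (MRT), the ecoregion distance tree (EDT) and an optional prior
classification supplied as a constraint file (SW86-style) — scores each by
constrained stepping-stone marginal likelihood on the molecular data, and
reports Bayes factors against the MOT baseline, a per-character homoplasy
report, and a range-area/endemism table.

The MOT baseline is the marginal likelihood of the run constrained to the
molecular consensus (not the unconstrained run): the fully resolved consensus
enters as an 'n-2 constraints' set just like the alternatives, which keeps
the comparison symmetric.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

from .charmap import homoplasy_summary, map_characters, region_homoplasy
from .core import CharacterMatrix, ConstraintSet, PartitionScheme, Tree
from .engine import McmcConfig, bayes_factor, consensus, run_mcmc, sdsf, \
    stepping_stone
from .geo import RegionMap, ecoregion_distance_tree, endemism_table
from .models import MkModel

__all__ = ["RunManifest", "run_comparison", "morphology_model_choice"]

log = logging.getLogger("phylogeo.pipeline")


@dataclass
class RunManifest:
    seed: int
    inputs: dict = field(default_factory=dict)      # name -> fingerprint
    config: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)      # name -> status/time
    outputs: dict = field(default_factory=dict)

    def fingerprint(self, name, obj):
        h = hashlib.sha256(repr(obj).encode()).hexdigest()[:16]
        self.inputs[name] = h
        return h

    def stage(self, name):
        manifest = self

        class _Stage:
            def __enter__(self):
                self.t0 = time.time()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                status = "ok" if exc is None else f"failed: {exc}"
                manifest.stages[name] = {
                    "status": status, "seconds": round(time.time() - self.t0, 2)}
                log.info("stage %s: %s", name, status)
                return False

        return _Stage()

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "inputs": self.inputs,
                       "config": self.config, "stages": self.stages,
                       "outputs": self.outputs}, fh, indent=1)


def morphology_model_choice(morphology: CharacterMatrix,
                            cfg: McmcConfig | None = None) -> dict:
    """Bayes-factor choice between Mk and Mk+Γ for a morphology matrix.

    Returns the stepping-stone marginal likelihoods, the 2*delta-ln score of
    Mk+Γ over Mk, and the winner: Mk+Γ only if the evidence is very strong
    (score > 10), otherwise the simpler Mk is retained.
    """
    cfg = cfg or McmcConfig()
    r = len(morphology.states)
    ml_mk = stepping_stone(morphology, models=MkModel(r=r), cfg=cfg,
                           data_id="morphology")
    ml_mkg = stepping_stone(morphology, models=MkModel(r=r, ncat=4), cfg=cfg,
                            data_id="morphology")
    bf = bayes_factor(ml_mkg, ml_mk)
    winner = "Mk+G" if bf.two_delta_ln > 10 else "Mk"
    return {"log_ml_mk": ml_mk.log_ml, "log_ml_mkg": ml_mkg.log_ml,
            "two_delta_ln": bf.two_delta_ln, "category": bf.category,
            "winner": winner}


def run_comparison(molecular: CharacterMatrix,
                   scheme: PartitionScheme | None,
                   morphology: CharacterMatrix | None,
                   localities, regions: RegionMap | None,
                   prior_constraints: ConstraintSet | None = None,
                   cfg: McmcConfig | None = None,
                   mcmc_cfg: McmcConfig | None = None,
                   map_draws: int = 50) -> dict:
    """Full comparison of topology hypotheses against the molecular data."""
    cfg = cfg or McmcConfig()
    mcmc_cfg = mcmc_cfg or cfg
    manifest = RunManifest(seed=cfg.seed)
    manifest.fingerprint("molecular", molecular.cells)
    report: dict = {"hypotheses": {}, "manifest": manifest}

    with manifest.stage("molecular_mcmc"):
        post = run_mcmc(molecular, scheme, None, mcmc_cfg)
        mot_tree = consensus(post)
        report["molecular_sdsf"] = sdsf(post) if len(post.runs) > 1 else None
        report["molecular_consensus"] = mot_tree

    hypotheses: dict = {"MOT": ConstraintSet.from_tree(mot_tree, "MOT")}

    if morphology is not None:
        try:
            with manifest.stage("morphology_mcmc"):
                mpost = run_mcmc(morphology, None, None, mcmc_cfg)
                mrt_tree = consensus(mpost)
                report["morphology_consensus"] = mrt_tree
                hypotheses["MRT"] = ConstraintSet.from_tree(mrt_tree, "MRT")
        except Exception as exc:
            report["hypotheses"]["MRT"] = {"error": str(exc)}

    if localities is not None and regions is not None:
        try:
            with manifest.stage("geographic_tree"):
                edt_tree, edt_constraints, members = \
                    ecoregion_distance_tree(localities, regions)
                report["edt_tree"] = edt_tree
                report["edt_regions"] = {k: sorted(v)
                                         for k, v in members.items()}
                hypotheses["EDT"] = edt_constraints
        except Exception as exc:
            report["hypotheses"]["EDT"] = {"error": str(exc)}

    if prior_constraints is not None:
        hypotheses[prior_constraints.name] = prior_constraints

    mls: dict = {}
    for name, cset in hypotheses.items():
        try:
            with manifest.stage(f"stepping_stone_{name}"):
                mls[name] = stepping_stone(
                    molecular, scheme, cset, cfg=cfg,
                    data_id=manifest.inputs["molecular"])
                report["hypotheses"][name] = {
                    "n_constraints": len(cset),
                    "log_ml": mls[name].log_ml,
                    "se": mls[name].se}
        except Exception as exc:
            report["hypotheses"][name] = {"error": str(exc)}

    if "MOT" in mls:
        for name, ml in mls.items():
            bf = bayes_factor(mls["MOT"], ml)
            report["hypotheses"][name].update(
                two_delta_ln_vs_MOT=bf.two_delta_ln, category=bf.category)
        ranked = sorted((r["two_delta_ln_vs_MOT"], n)
                        for n, r in report["hypotheses"].items()
                        if "two_delta_ln_vs_MOT" in r)
        report["ranking"] = [n for _score, n in ranked]

    if morphology is not None:
        try:
            with manifest.stage("homoplasy"):
                hrep = map_characters(mot_tree, morphology, n_draws=map_draws,
                                      seed=cfg.seed)
                report["homoplasy"] = hrep
                report["region_shares"] = region_homoplasy(hrep)
                report["fraction_hi_above_0.5"] = homoplasy_summary(hrep, 0.5)
        except Exception as exc:
            report["homoplasy_error"] = str(exc)

    if localities is not None:
        with manifest.stage("endemism"):
            report["endemism"] = endemism_table(localities)

    return report


def report_to_text(report: dict) -> str:
    """Human-readable summary table of a comparison report."""
    lines = ["hypothesis  n_constraints  log_ml        2dln_vs_MOT  category"]
    for name, rec in report["hypotheses"].items():
        if "error" in rec:
            lines.append(f"{name:<11} FAILED: {rec['error']}")
            continue
        lines.append(
            f"{name:<11} {rec['n_constraints']:>13}  {rec['log_ml']:>12.2f}  "
            f"{rec.get('two_delta_ln_vs_MOT', float('nan')):>11.2f}  "
            f"{rec.get('category', '-')}")
    if "region_shares" in report:
        shares = ", ".join(f"{k}: {100 * v:.0f}%"
                           for k, v in report["region_shares"].items())
        lines.append(f"gonopodal homoplasy shares: {shares}")
    if "endemism" in report:
        df = report["endemism"]
        n = len(df)
        lines.append(
            f"endemism: {int(df['sre_qualifying'].sum())}/{n} SRE-qualifying, "
            f"{int((df['class'] == 'MRE').sum())}/{n} MRE")
    return "\n".join(lines)
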