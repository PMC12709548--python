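"""End-to-end orchestration: simulate -> mouse-tracking -> behavior ->
diffusion-model fits -> posterior predictive checks -> mediation ->
neural similarity -> connectivity, from a single validated config.

Every stage reads its inputs from, and writes its outputs to, the run
directory as delimited text or JSON, so stages are individually skippable
and resumable.  All randomness flows from the config seed through named
substreams, and a manifest records the config hash and stage list; a
rerun with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__, io
from ._utils import substream
from .behavior import (cr_features, fit_psychometric, fit_random_intercept,
                       subject_summaries)
from .connectivity import (betweenness, fc_behavior_correlation, fc_matrix,
                           global_efficiency, run_trend)
from .ddm import HierarchicalDDM
from .mediation import mediation_fit
from .mouse import TrajectoryNormalizer
from .neural import (ISRSA, TemplateMap, model_rdm, neural_rdm,
                     similarity_trend, template_similarity)
from .synth import (GroupParams, generate_design, simulate_dataset,
                    simulate_roi_timeseries, simulate_roi_patterns,
                    simulate_trajectory)

log = logging.getLogger("moraltrace")

STAGES = ["simulate", "mt", "behavior", "fit-ddm", "ppc", "mediate",
          "isrsa", "connect", "report"]


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_subjects: int = Field(10, ge=3)
    n_questions: int = Field(20, ge=2)
    n_runs: int = Field(9, ge=2)
    frac_incorrect_higher: float = Field(0.8, ge=0.0, le=1.0)
    reward_low: int = Field(1, ge=0)
    reward_high: int = Field(9, ge=0)
    group_model: str = "M5"
    trajectory_samples: int = Field(60, ge=2)
    trajectory_noise: float = Field(0.03, ge=0.0)
    n_voxels: int = Field(120, ge=2)
    signal: float = Field(0.8, ge=0.0, le=1.0)
    n_rois: int = Field(9, ge=2)
    n_timepoints: int = Field(150, ge=20)
    coupling_trend: float = 0.02


class DDMConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    models: list[str] = ["M1", "M4", "M5"]
    chains: int = Field(3, ge=2)
    iterations: int = Field(1200, ge=100)
    burn_in: int = Field(400, ge=10)
    thin: int = Field(1, ge=1)
    normalization: str = "design"
    session_coding: str = "run"


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mediation: bool = True
    isrsa: bool = True
    connectivity: bool = True
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    fdr_q: float = Field(0.05, gt=0.0, lt=1.0)
    n_permutations: int = Field(1000, ge=100)
    n_resamples: int = Field(2000, ge=1000)
    ppc_draws: int = Field(80, ge=10)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "runs/demo"
    simulation: SimulationConfig = SimulationConfig()
    ddm: DDMConfig = DDMConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""
        payload = self.model_dump()
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML config; aggregate all errors.

    An empty file yields the full default config.  Unknown keys and
    out-of-range values are reported together, by name.
    """
    raw = yaml.safe_load(Path(path).read_text()) if Path(path).exists() else None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        msgs = [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                for e in exc.errors()]
        raise ValueError("invalid config:\n  " + "\n  ".join(msgs)) from exc


def _dump_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return round(float(o), 10)
        if isinstance(o, np.ndarray):
            return [default(x) for x in o]
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=default) + "\n")


def _stat_to_dict(res) -> dict:
    return {"params": {k: round(float(v), 10) for k, v in res.params.items()},
            "se": {k: round(float(v), 10) for k, v in res.se.items()},
            "pvalues": {k: round(float(v), 10) for k, v in res.pvalues.items()},
            "statistic": None if res.statistic is None else round(float(res.statistic), 10),
            "statistic_name": res.statistic_name,
            "effect_size": None if res.effect_size is None else round(float(res.effect_size), 10)}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None,
                 resume: bool = False) -> Path:
    """Execute the requested stages; returns the run directory."""
    stages = STAGES if stages is None else stages
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    def done(*names):
        return all((out / n).exists() for n in names)

    current = "setup"
    try:
        current = "simulate"
        if "simulate" in stages and not (resume and done("trials.csv", "trajectories.csv")):
            log.info("stage simulate: %d subjects x %d runs x %d questions",
                     sim.n_subjects, sim.n_runs, sim.n_questions)
            design = generate_design(sim.n_subjects, sim.n_questions,
                                     sim.n_runs, sim.frac_incorrect_higher,
                                     sim.reward_low, sim.reward_high,
                                     seed=config.seed)
            gp = GroupParams(model_id=sim.group_model)
            trials, true_params = simulate_dataset(gp, design,
                                                   seed=config.seed,
                                                   return_params=True)
            io.write_trials(trials, out / "trials.csv")
            pd.DataFrame({s: p for s, p in true_params.items()}).T.to_csv(
                out / "true_params.csv", float_format="%.10g")
            # trajectories: conflict is high when reward and consistency
            # cues pull in opposite or weak directions (fixture plumbing)
            traj_rng = substream(config.seed, "pipeline-traj")
            trajs = []
            feat = cr_features(trials)
            rel_r = (feat["reward_incorrect"] - feat["reward_correct"]).to_numpy(float)
            rel_r = rel_r / max(np.abs(rel_r).max(), 1.0)
            rel_c = feat["relative_cr"].to_numpy(float)
            rel_c = rel_c / max(np.abs(rel_c).max(), 1.0)
            conflict = 1.0 / (1.0 + 2.0 * np.abs(rel_r + rel_c))
            for i, row in enumerate(feat.itertuples()):
                if row.timeout:
                    continue
                uid = f"{row.subject}_r{row.run}_q{row.question}"
                trajs.append(simulate_trajectory(
                    "upper" if row.islie else "lower", row.rt,
                    float(conflict[i]), n_samples=sim.trajectory_samples,
                    noise=sim.trajectory_noise,
                    seed=int(traj_rng.integers(0, 2**31 - 1)),
                    trial_uid=uid))
            io.write_trajectories(trajs, out / "trajectories.csv")

        current = "mt"
        if "mt" in stages and not (resume and done("trials_mt.csv")):
            log.info("stage mt: trajectory metrics")
            trials = io.read_trials(out / "trials.csv")
            trajs = io.read_trajectories(out / "trajectories.csv")
            norm = TrajectoryNormalizer()
            metrics = norm.metrics(trajs)
            trials["trial_uid"] = (trials["subject"].astype(str) + "_r"
                                   + trials["run"].astype(str) + "_q"
                                   + trials["question"].astype(str))
            merged = trials.merge(metrics, on="trial_uid", how="left")
            merged.drop(columns="trial_uid").to_csv(
                out / "trials_mt.csv", index=False, float_format="%.10g")

        current = "behavior"
        if "behavior" in stages and not (resume and done("subject_summary.csv")):
            log.info("stage behavior: summaries and regressions")
            trials = pd.read_csv(out / "trials_mt.csv")
            trials["timeout"] = trials["timeout"].astype(bool)
            summ = subject_summaries(trials)
            summ["mean_auc"] = trials.groupby("subject")["auc"].mean()
            summ.to_csv(out / "subject_summary.csv", float_format="%.10g")
            stats = {}
            per_run = trials.groupby(["subject", "run"]).agg(
                auc=("auc", "mean")).reset_index()
            per_run = per_run.merge(summ[["lie_rate", "entropy"]],
                                    on="subject")
            stats["auc_mixed_model"] = _stat_to_dict(fit_random_intercept(
                per_run, "auc", ["lie_rate", "entropy"]))
            feat = cr_features(trials)
            feat["relative_reward"] = feat["reward_incorrect"] - feat["reward_correct"]
            for stratum in ("-", "0", "+"):
                try:
                    res = fit_psychometric(feat, stratum)
                    stats[f"psychometric_{stratum}"] = _stat_to_dict(res)
                except Exception as exc:  # degenerate stratum at small n
                    stats[f"psychometric_{stratum}"] = {"error": str(exc)}
            _dump_json(stats, out / "behavior_stats.json")

        current = "fit-ddm"
        if "fit-ddm" in stages and not (resume and done("model_comparison.csv")):
            comparison = []
            best = None
            for m in config.ddm.models:
                log.info("stage fit-ddm: model %s", m)
                trials = io.read_trials(out / "trials.csv")
                est = HierarchicalDDM(
                    model=m, chains=config.ddm.chains,
                    iterations=config.ddm.iterations,
                    burn_in=config.ddm.burn_in, thin=config.ddm.thin,
                    normalization=config.ddm.normalization,
                    session_coding=config.ddm.session_coding,
                    seed=config.seed)
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    est.fit(trials)
                post = est.posterior_
                comparison.append({"model": m, "dic": post.dic,
                                   "pd": post.pd_eff,
                                   "max_rhat": max(post.rhat.values()),
                                   "converged": post.converged})
                gsum = []
                for name in post.param_names:
                    d = post.group_mean_draws(name)
                    gsum.append({"parameter": name, "mean": d.mean(),
                                 "sd": d.std(),
                                 "q2.5": np.percentile(d, 2.5),
                                 "q97.5": np.percentile(d, 97.5),
                                 "rhat": post.rhat[f"mu_{name}"]})
                pd.DataFrame(gsum).to_csv(out / f"group_posterior_{m}.csv",
                                          index=False, float_format="%.10g")
                post.subject_posterior_means().to_csv(
                    out / f"subject_means_{m}.csv", float_format="%.10g")
                if best is None or post.dic < best[1].dic:
                    best = (est, post)
            comp = pd.DataFrame(comparison)
            comp["delta_dic"] = comp["dic"] - comp["dic"].min()
            comp.to_csv(out / "model_comparison.csv", index=False,
                        float_format="%.10g")
            run_pipeline._best = best  # cached for the ppc stage in-process

        current = "ppc"
        if "ppc" in stages and not (resume and done("ppc.csv")):
            log.info("stage ppc: posterior predictive checks")
            best = getattr(run_pipeline, "_best", None)
            if best is None:
                raise RuntimeError("ppc requires fit-ddm in the same invocation")
            est, post = best
            ppc = est.posterior_predictive(n_draws=config.analysis.ppc_draws,
                                           seed=config.seed)
            ppc.to_csv(out / "ppc.csv", index=False, float_format="%.10g")

        current = "mediate"
        if "mediate" in stages and config.analysis.mediation and \
                not (resume and done("mediation.json")):
            log.info("stage mediate: AUC -> reward weight -> entropy")
            summ = pd.read_csv(out / "subject_summary.csv", index_col=0)
            comp = pd.read_csv(out / "model_comparison.csv")
            best_model = comp.loc[comp["dic"].idxmin(), "model"]
            sm = pd.read_csv(out / f"subject_means_{best_model}.csv",
                             index_col=0)
            res = mediation_fit(summ["mean_auc"].to_numpy(),
                                sm["w_r"].to_numpy(),
                                summ["entropy"].to_numpy(),
                                n_resamples=config.analysis.n_resamples,
                                method="bootstrap", seed=config.seed)
            _dump_json({"a": res.a, "b": res.b, "c": res.c,
                        "c_prime": res.c_prime, "indirect": res.indirect,
                        "ci": {k: list(v) for k, v in res.ci.items()},
                        "n": res.n}, out / "mediation.json")

        current = "isrsa"
        if "isrsa" in stages and config.analysis.isrsa and \
                not (resume and done("isrsa.json")):
            log.info("stage isrsa: inter-subject RSA on planted patterns")
            comp = pd.read_csv(out / "model_comparison.csv")
            best_model = comp.loc[comp["dic"].idxmin(), "model"]
            sm = pd.read_csv(out / f"subject_means_{best_model}.csv",
                             index_col=0)
            params = sm[["w_c", "w_r"]].to_numpy()
            patterns = simulate_roi_patterns(params, n_voxels=sim.n_voxels,
                                             signal=sim.signal,
                                             seed=config.seed)
            io.write_matrix(patterns, out / "roi_patterns.csv",
                            labels=list(sm.index))
            nr = neural_rdm(patterns)
            mr = model_rdm(params)
            io.write_matrix(nr, out / "neural_rdm.csv", labels=list(sm.index))
            io.write_matrix(mr, out / "model_rdm.csv", labels=list(sm.index))
            est = ISRSA(n_perm=config.analysis.n_permutations,
                        seed=config.seed).fit(nr, mr)

            # template-similarity tracking: per-run patterns whose
            # resemblance to a reference map fades across runs (synthetic
            # stand-in for run-wise multi-voxel activation patterns)
            trng = substream(config.seed, "pipeline-template")
            template = TemplateMap(values=trng.normal(3.5, 0.3, sim.n_voxels))
            sims = np.empty((len(sm), sim.n_runs))
            for j in range(len(sm)):
                for r in range(sim.n_runs):
                    w = 1.0 - 0.08 * r
                    pat = w * template.values \
                        + (1 - w) * trng.standard_normal(sim.n_voxels) * 3.0
                    sims[j, r] = template_similarity(pat, template)
            trend = similarity_trend(sims)
            pd.DataFrame(sims, index=list(sm.index),
                         columns=[f"run{r + 1}" for r in range(sim.n_runs)]) \
                .to_csv(out / "template_similarity.csv",
                        float_format="%.10g")
            _dump_json({"rho": est.rho_, "p": est.p_,
                        "p_add_one": est.p_add_one_,
                        "n_perm": config.analysis.n_permutations,
                        "template_trend": _stat_to_dict(trend)},
                       out / "isrsa.json")

        current = "connect"
        if "connect" in stages and config.analysis.connectivity and \
                not (resume and done("connectivity.json")):
            log.info("stage connect: FC graphs and run trends")
            summ = pd.read_csv(out / "subject_summary.csv", index_col=0)
            subjects = list(summ.index)
            rng = substream(config.seed, "pipeline-connect")
            eff = np.empty((len(subjects), sim.n_runs))
            btw_node0 = np.empty((len(subjects), sim.n_runs))
            edge01 = np.empty(len(subjects))
            for si, sid in enumerate(subjects):
                ts = simulate_roi_timeseries(
                    n_rois=sim.n_rois, n_timepoints=sim.n_timepoints,
                    n_runs=sim.n_runs,
                    coupling_trend={(0, 1): sim.coupling_trend},
                    seed=int(rng.integers(0, 2**31 - 1)))
                zs = []
                for r in range(sim.n_runs):
                    z = fc_matrix(ts[r])
                    zs.append(z)
                    eff[si, r] = global_efficiency(z)
                    btw_node0[si, r] = betweenness(z)[0]
                edge01[si] = np.mean([z[0, 1] for z in zs])
            res_eff = run_trend(eff)
            res_btw = run_trend(btw_node0)
            fc_beh = fc_behavior_correlation(edge01,
                                             summ["entropy"].to_numpy())
            _dump_json({
                "global_efficiency_trend": _stat_to_dict(res_eff),
                "betweenness_node0_trend": _stat_to_dict(res_btw),
                "edge01_entropy_correlation": fc_beh,
            }, out / "connectivity.json")

        current = "report"
        if "report" in stages:
            log.info("stage report: manifest and summary")
            manifest = {"version": __version__, "seed": config.seed,
                        "config_hash": config.config_hash(),
                        "config": config.model_dump(),
                        "stages": stages}
            _dump_json(manifest, out / "manifest.json")
            lines = [f"moraltrace {__version__} run report",
                     f"config hash: {config.config_hash()}",
                     f"seed: {config.seed}", ""]
            for f in sorted(out.glob("*.json")):
                if f.name == "manifest.json":
                    continue
                lines.append(f"== {f.name} ==")
                lines.append(f.read_text().strip())
                lines.append("")
            (out / "report.txt").write_text("\n".join(lines))
    except Exception as exc:
        _dump_json({"stage": current, "error": str(exc),
                    "type": type(exc).__name__}, out / "error.json")
        log.error("stage %s failed: %s", current, exc)
        raise
    return out
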