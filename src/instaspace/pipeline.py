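"""End-to-end analysis pipeline.

Runs the full chain on one session — simulate or load, preprocess,
classify units, instantaneous subspaces and principal-angle time courses,
trajectory separation, decoding sweep, CCA alignment and group
comparisons — with every stochastic stage seeded independently from the
master seed, so outputs are a pure function of (input data, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeding import stage_rng, stage_seed
from .align import (BootstrapCCADistribution, CCASource, GroupComparisonReport,
                    bootstrap_cca, compare_alignment_groups, within_group_cca)
from .decode import AccuracySeries, DecoderSpec, accuracy_timecourse, \
    chance_accuracy_band
from .preprocess import RateTensor, align_and_concatenate, classify_units
from .session import SessionDataset, read_session
from .subspace import (ANCHORS, PrincipalAngleSeries, SubspaceSeries,
                       angle_timecourse, instantaneous_subspace_series,
                       random_angle_baseline)
from .synth import SynthConfig, generate_session
from .trajectory import EVENTS, clip_segments, separation_matrix

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Wraps an error with the name of the pipeline stage that raised it."""


@dataclass
class AnalysisConfig:
    """Declarative configuration of one pipeline run.

    Either ``session_path`` (with ``session_format``) or ``synth`` must be
    given.  Scale knobs default to a desk-scale run; the decoding sweep
    uses the logistic baseline by default (switch ``decoder_classifier`` to
    ``"bilstm"`` for the reference recurrent decoder).
    """

    session_path: str | None = None
    session_format: str = "hdf5"
    synth: dict = field(default_factory=dict)
    contexts: list[str] = field(default_factory=lambda: ["execution", "observation"])
    population: str = "MN"          # unit class for the main analyses
    reference_population: str = "AE"
    use_ground_truth_classes: bool = False
    # angle stage
    angle_step_ms: int = 10
    angle_folds: int = 10
    angle_trials_per_object: int = 20
    baseline_draws: int = 5000
    # decode stage
    decoder_classifier: str = "logistic"
    decoder_repeats: int = 10
    decoder_epochs: int = 150
    decode_step_ms: int = 50
    chance_draws: int = 50
    decode_events: list[str] = field(default_factory=lambda: list(EVENTS))
    # cca stage
    cca_event: str = "H"
    cca_iterations: int = 500
    cca_trials_per_object: int = 20
    cca_min_trials: int = 10

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
            else json.loads(text)
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResults:
    session: SessionDataset
    classification: pd.DataFrame
    tensors: dict[tuple[str, str], RateTensor]       # (population, context)
    subspace_series: dict[tuple[str, str], SubspaceSeries]
    angles: dict[tuple[str, str], dict[str, PrincipalAngleSeries]]
    baseline: dict
    separation: dict[tuple[str, str], np.ndarray]
    accuracy: dict[tuple[str, str, str], AccuracySeries]  # (pop, context, event)
    cca: dict[str, BootstrapCCADistribution]
    comparison: GroupComparisonReport | None
    provenance: dict


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - annotate and re-raise
                raise StageError(f"stage {name!r} failed: {err}") from err
        return inner
    return wrap


def run_full_pipeline(config: AnalysisConfig, seed: int,
                      out_dir: str | Path | None = None) -> PipelineResults:
    """Run every analysis stage and optionally write the result tables."""
    cfg = config

    # -- input ----------------------------------------------------------
    ground_truth = None
    if cfg.session_path is not None:
        session = _stage("read_session")(read_session)(cfg.session_path,
                                                       cfg.session_format)
    else:
        synth_cfg = SynthConfig(**{**cfg.synth,
                                   "seed": stage_seed(seed, "simulate")})
        session, ground_truth = _stage("simulate")(generate_session)(synth_cfg)

    # -- unit classes ---------------------------------------------------
    if cfg.use_ground_truth_classes and ground_truth is not None:
        classes = dict(ground_truth.unit_classes)
        classification = pd.DataFrame(
            {"unit_id": list(classes), "unit_class": list(classes.values())})
    else:
        uc = _stage("classify_units")(classify_units)(session)
        classes = uc.classes
        classification = uc.frame()

    populations = {}
    for pop in {cfg.population, cfg.reference_population}:
        ids = [u for u, c in classes.items() if c == pop]
        if len(ids) >= 4:
            populations[pop] = ids
        else:
            logger.warning("population %s has only %d units; skipped", pop, len(ids))

    # -- per-population, per-context stages -----------------------------
    tensors, series_map, angles, separation, accuracy = {}, {}, {}, {}, {}
    smallest_n = None
    for pop, ids in populations.items():
        sub = session.subset_units(ids)
        for context in cfg.contexts:
            key = (pop, context)
            tensor = _stage("preprocess")(align_and_concatenate)(sub, context)
            tensors[key] = tensor
            n = tensor.n_units
            smallest_n = n if smallest_n is None else min(smallest_n, n)
            grid = np.arange(0, tensor.n_timepoints, cfg.angle_step_ms)
            series = _stage("subspaces")(instantaneous_subspace_series)(
                tensor, times=grid)
            series_map[key] = series
            angles[key] = _stage("angles")(angle_timecourse)(
                tensor, ANCHORS, cfg.angle_trials_per_object, cfg.angle_folds,
                stage_rng(seed, f"angles/{pop}/{context}"), times=grid)
            anchor_series = _stage("subspaces")(instantaneous_subspace_series)(
                tensor, times=np.asarray(sorted(tensor.event_index.values())))
            separation[key] = _stage("separation")(separation_matrix)(
                tensor, anchor_series)
            spec = DecoderSpec(classifier=cfg.decoder_classifier,
                               n_repeats=cfg.decoder_repeats,
                               epochs=cfg.decoder_epochs)
            for event in cfg.decode_events:
                segs = clip_segments(tensor, event, "single_trial")
                acc = _stage("decode")(accuracy_timecourse)(
                    segs, series, cfg.decode_step_ms, spec,
                    stage_rng(seed, f"decode/{pop}/{context}/{event}"))
                if cfg.chance_draws > 0:
                    cm, csd = _stage("decode")(chance_accuracy_band)(
                        segs, cfg.chance_draws, spec,
                        stage_rng(seed, f"chance/{pop}/{context}/{event}"))
                    acc.chance_mean, acc.chance_sd = cm, csd
                accuracy[(pop, context, event)] = acc

    baseline = {}
    if smallest_n is not None and smallest_n >= 3:
        b = _stage("angles")(random_angle_baseline)(
            smallest_n, cfg.baseline_draws, stage_rng(seed, "baseline"))
        baseline = {"n_ambient": b.n_ambient, "mean": b.mean, "sd": b.sd,
                    "mean_minus_3sd": b.mean_minus_3sd}
        for key in angles:
            for s in angles[key].values():
                s.chance_mean = baseline["mean"]
                s.chance_minus_3sd = baseline["mean_minus_3sd"]

    # -- CCA ------------------------------------------------------------
    cca: dict[str, BootstrapCCADistribution] = {}
    comparison = None
    pop, ref = cfg.population, cfg.reference_population
    both_contexts = {"execution", "observation"} <= set(cfg.contexts)
    if not both_contexts:
        logger.info("only contexts %s configured; execution-vs-observation "
                    "CCA stage skipped", cfg.contexts)
    if pop in populations:
        def source(p, context, label):
            return CCASource(tensors[(p, context)], cfg.cca_event, label=label,
                             min_trials_per_object=cfg.cca_min_trials)
        try:
            groups = []
            if both_contexts:
                cca["MN:E/O"] = _stage("cca")(bootstrap_cca)(
                    source(pop, "execution", f"{pop}:E"),
                    source(pop, "observation", f"{pop}:O"),
                    cfg.cca_iterations, cfg.cca_trials_per_object,
                    stage_rng(seed, "cca/EO"))
            if ref in populations and "execution" in cfg.contexts:
                cca["MN/AE"] = _stage("cca")(bootstrap_cca)(
                    source(pop, "execution", pop),
                    source(ref, "execution", ref),
                    cfg.cca_iterations, cfg.cca_trials_per_object,
                    stage_rng(seed, "cca/MNAE"))
            for p, context, name in ((pop, "execution", "MN:E/E"),
                                     (pop, "observation", "MN:O/O"),
                                     (ref, "execution", "AE:E/E")):
                if p in populations and context in cfg.contexts:
                    cca[name] = _stage("cca")(within_group_cca)(
                        source(p, context, name.split(":")[0] + ":" + context[0].upper()),
                        cfg.cca_iterations, cfg.cca_trials_per_object,
                        stage_rng(seed, f"cca/{name}"))
            groups = [d for d in cca.values()]
            if len(groups) >= 2:
                comparison = _stage("compare")(compare_alignment_groups)(groups, 1)
        except StageError:
            raise
    provenance = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": int(seed),
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "n_units": session.n_units,
        "n_trials": len(session.trials),
    }
    results = PipelineResults(session=session, classification=classification,
                              tensors=tensors, subspace_series=series_map,
                              angles=angles, baseline=baseline,
                              separation=separation, accuracy=accuracy,
                              cca=cca, comparison=comparison,
                              provenance=provenance)
    if out_dir is not None:
        write_results(results, out_dir)
    return results


def write_results(results: PipelineResults, out_dir: str | Path) -> Path:
    """Write every stage output as CSV/JSON tables (deterministic layout)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.classification.to_csv(out / "unit_classification.csv", index=False)

    angle_rows = []
    for (pop, context), per_anchor in results.angles.items():
        for anchor, s in per_anchor.items():
            mean, sd = s.mean, s.sd
            for i, t in enumerate(s.times):
                angle_rows.append({
                    "population": pop, "context": context, "anchor": anchor,
                    "time_ms": int(t), "theta1_mean": mean[i, 0],
                    "theta1_sd": sd[i, 0], "theta2_mean": mean[i, 1],
                    "theta3_mean": mean[i, 2],
                    "chance_mean": s.chance_mean,
                    "chance_minus_3sd": s.chance_minus_3sd})
    pd.DataFrame(angle_rows).to_csv(out / "principal_angles.csv", index=False,
                                    float_format="%.6f")

    sep_rows = []
    for (pop, context), mat in results.separation.items():
        for i, seg in enumerate(EVENTS):
            for j, sub in enumerate(EVENTS):
                sep_rows.append({"population": pop, "context": context,
                                 "segment": seg, "subspace": sub,
                                 "cumulative_separation": mat[i, j]})
    pd.DataFrame(sep_rows).to_csv(out / "separation.csv", index=False,
                                  float_format="%.6f")

    acc_rows = []
    for (pop, context, event), s in results.accuracy.items():
        mean, sd = s.mean, s.sd
        for i, t in enumerate(s.times):
            acc_rows.append({"population": pop, "context": context,
                             "segment": event, "subspace_time_ms": int(t),
                             "accuracy_mean": mean[i], "accuracy_sd": sd[i],
                             "chance_mean": s.chance_mean,
                             "chance_sd": s.chance_sd})
    pd.DataFrame(acc_rows).to_csv(out / "decoding_accuracy.csv", index=False,
                                  float_format="%.6f")

    if results.cca:
        pd.concat([d.frame() for d in results.cca.values()],
                  ignore_index=True).to_csv(out / "cca_distributions.csv",
                                            index=False, float_format="%.6f")
    if results.comparison is not None:
        (out / "group_comparison.txt").write_text(results.comparison.summary() + "\n")
        payload = {"coefficient": results.comparison.coefficient,
                   "groups": results.comparison.groups,
                   "kruskal_p": results.comparison.kruskal_p,
                   "degenerate": results.comparison.degenerate,
                   "pairwise": results.comparison.pairwise.to_dict("records")}
        (out / "group_comparison.json").write_text(json.dumps(payload, indent=2))
    (out / "baseline.json").write_text(json.dumps(results.baseline, indent=2))
    (out / "provenance.json").write_text(
        json.dumps(results.provenance, indent=2, default=str))
    return out
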