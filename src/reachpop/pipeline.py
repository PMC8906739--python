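"""Config-driven orchestration of a full session analysis.

``run`` takes a :class:`PipelineConfig`, generates (or loads) a session,
and executes every stage: reach kinematics, baseline-normalized PETHs,
the consensus position decoder with per-class partial contributions,
AMP/DIR targeted dimensionality reduction with per-unit tuning, the
Poisson naive-Bayes amplitude-tertile classifier per subpopulation, PCA
trajectories, and optotag classification. The result is a JSON-able
report plus CSV tables; re-running with the same config and seed is
byte-identical.

Stage defaults are the analysis constants used throughout: 1-ms count
bins, 50-ms PETH bins, a 2500-ms pre-reach baseline, 24-ms Gaussian
smoothing for decoding, 50 batches of 50 movements with ~10% of
movements held out, quintile tuning, tertile classification with 10
folds and 1000 iterations, and tagging criteria alpha = 0.01, 60%
reduction, 0.3 z sustained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import bayes, decoder, optotag, pca, targeted
from .kinematics import JoystickTrace, detect_reaches, label_trials
from .preprocessing import align_trials, bin_spikes, smooth_rates, sqrt_stack, zscore_baseline
from .synthetic import Session, SessionConfig, generate_session

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run", "decoder_features", "movement_tensor"]


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run."""

    mode: str = "synthetic"  # 'synthetic' | 'files'
    session: SessionConfig = field(default_factory=SessionConfig)
    # files mode
    trace_path: Optional[str] = None
    spikes_path: Optional[str] = None
    tag_spikes_path: Optional[str] = None
    laser_onsets_path: Optional[str] = None
    # stage toggles
    run_decoder: bool = True
    run_tdr: bool = True
    run_classifier: bool = True
    run_pca: bool = True
    run_optotag: bool = True
    # analysis constants
    bin_ms: float = 1.0
    peth_bin_ms: float = 50.0
    baseline_window: tuple[float, float] = (-2.5, 0.0)
    smooth_sigma_ms: float = 24.0
    n_batches: int = 50
    batch_size: int = 50
    heldout_frac: float = 0.10
    n_shuffles: int = 100
    movement_window: tuple[float, float] = (0.0, 0.35)
    classifier_window: tuple[float, float] = (0.0, 0.6)
    nb_n_iter: int = 1000
    nb_n_folds: int = 10
    tag_alpha: float = 0.01
    tag_reduction: float = 0.6
    tag_z: float = 0.3
    seed: int = 0

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def decoder_features(
    session: Session,
    sigma_ms: float = 24.0,
    bin_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Build the decoder's (F, K, movement windows) from a session.

    Per unit, session-long 1-ms counts are converted to rates, Gaussian-
    smoothed (sigma 24 ms) and z-scored over the session; only the
    columns inside detected reach windows are kept. ``K`` holds the
    joystick x, y at those samples; ``windows[i]`` indexes movement
    ``i``'s columns of F.
    """
    trace = session.trace
    fs = trace.fs
    bin_s = bin_ms * 1e-3
    if abs(fs * bin_s - 1.0) > 1e-9:
        raise ValueError("decoder binning must match the trace sample rate")
    n_bins = trace.n_samples
    col_chunks = []
    windows = []
    off = 0
    for ev in session.events:
        i0 = int(round(ev.start_s * fs))
        i1 = int(round(ev.stop_s * fs))
        i1 = min(i1, n_bins)
        idx = np.arange(i0, i1)
        col_chunks.append(idx)
        windows.append(np.arange(off, off + idx.size))
        off += idx.size
    cols = np.concatenate(col_chunks)
    K = np.column_stack([trace.x[cols], trace.y[cols]])

    unit_ids = session.truth.units.index.to_numpy()
    F = np.empty((unit_ids.size, cols.size))
    times = session.spikes["time_s"].to_numpy()
    units = session.spikes["unit_id"].to_numpy()
    for j, u in enumerate(unit_ids):
        st = times[units == u]
        b = np.floor(st * fs).astype(np.int64)
        b = b[(b >= 0) & (b < n_bins)]
        r = np.bincount(b, minlength=n_bins) / bin_s
        r = smooth_rates(r, sigma_ms, bin_ms)
        sd = r.std()
        z = (r - r.mean()) / (sd if sd > 0 else 1.0)
        F[j] = z[cols]
    return F, K, windows


def movement_tensor(session: Session, window: tuple[float, float], bin_ms: float):
    """Reach-start-aligned raw count tensor over the given window."""
    binned = bin_spikes(
        session.spikes,
        bin_ms=bin_ms,
        t_start=0.0,
        t_stop=session.duration_s,
        unit_ids=session.truth.units.index.to_numpy(),
    )
    starts = [ev.start_s for ev in session.events]
    return align_trials(binned, starts, window=(-window[0], window[1]),
                        alignment_event="reach_start")


def _class_subsets(session: Session) -> dict:
    subsets = {}
    for cls in ("amp_tuned", "dir_tuned", "reward_timed", "untuned"):
        ids = session.truth.class_units(cls)
        if ids.size:
            subsets[cls] = ids
    tagged = session.truth.tagged_units
    if tagged.size:
        subsets["tagged"] = tagged
        subsets["untagged"] = session.truth.units.index.difference(tagged).to_numpy()
    return subsets


def run(config: PipelineConfig, outdir: Optional[str] = None) -> dict:
    """Run every enabled stage and return (optionally write) the report.

    The global seed fans out into independent per-stage substreams, so
    toggling one stage does not shift another's randomness. Stage
    failures are caught: the report carries an ``errors`` map and the
    remaining stages still run.
    """
    report: dict = {"config": config.resolved(), "errors": {}}
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: child for name, child in zip(
        ("decoder", "tdr", "classifier", "optotag"), ss.spawn(4))}

    if config.mode == "synthetic":
        session = generate_session(config.session)
    elif config.mode == "files":
        session = _load_session_from_files(config)
    else:
        raise ValueError("mode must be 'synthetic' or 'files'")

    events = session.events
    amps = np.array([ev.amplitude for ev in events])
    dirs = np.array([ev.direction for ev in events])
    blocks = np.array([ev.block_id for ev in events])
    report["kinematics"] = {
        "n_reaches": int(len(events)),
        "amplitude_mean_mm": float(amps.mean()),
        "amplitude_sd_mm": float(amps.std()),
        "amplitude_max_mm": float(amps.max()),
        "block_mean_amplitude_mm": {
            str(b): float(amps[blocks == b].mean()) for b in np.unique(blocks)
        },
        "block_n_reaches": {
            str(b): int(np.sum(blocks == b)) for b in np.unique(blocks)
        },
        "fraction_rewarded": float(np.mean([bool(ev.rewarded) for ev in events])),
    }

    if config.run_decoder:
        try:
            rng = np.random.default_rng(seeds["decoder"])
            F, K, windows = decoder_features(session, sigma_ms=config.smooth_sigma_ms,
                                             bin_ms=config.bin_ms)
            model = decoder.fit_consensus(
                F, K, windows,
                n_batches=config.n_batches,
                batch_size=min(config.batch_size, max(1, len(windows) - 2)),
                heldout_frac=config.heldout_frac,
                rng=rng,
                n_shuffles=config.n_shuffles,
            )
            F_h, K_h, _ = decoder.heldout_arrays(F, K, windows, model.heldout_ids)
            unit_ids = session.truth.units.index.to_numpy()
            pos = {u: i for i, u in enumerate(unit_ids)}
            contributions = {}
            for name, ids in _class_subsets(session).items():
                idx = [pos[u] for u in ids]
                contributions[name] = decoder.partial_contribution(model, idx, F_h, K_h)
            report["decoder"] = {
                "r_pooled": model.performance["r_pooled"],
                "r_x": model.performance["r_x"],
                "r_y": model.performance["r_y"],
                "n_heldout_movements": int(model.heldout_ids.size),
                "shuffle": {k: v for k, v in model.shuffle_r.items() if k != "r_pooled"},
                "partial_contributions": contributions,
            }
        except Exception as exc:  # noqa: BLE001 - stage isolation
            logger.exception("decoder stage failed")
            report["errors"]["decoder"] = str(exc)

    counts_move = None
    if config.run_tdr or config.run_classifier:
        tensor_move = movement_tensor(session, config.classifier_window, config.peth_bin_ms)

    if config.run_tdr:
        try:
            rng = np.random.default_rng(seeds["tdr"])
            counts_move = targeted.movement_window_counts(
                tensor_move, window=config.movement_window)
            kept = tensor_move.trial_ids
            beta_a = targeted.consensus_regression(
                counts_move, amps[kept], n_batches=config.n_batches,
                batch_size=config.batch_size, rng=rng)
            beta_d = targeted.consensus_regression(
                counts_move, dirs[kept], n_batches=config.n_batches,
                batch_size=config.batch_size, rng=rng)
            dims = targeted.orthonormalize(beta_a, beta_d)
            tun_a = targeted.quintile_tuning(counts_move, amps[kept], dims, "AMP")
            tun_d = targeted.quintile_tuning(counts_move, dirs[kept], dims, "DIR")
            table = targeted.per_unit_tuning_slopes(counts_move, amps[kept], dirs[kept], dims)
            table["cell_class"] = session.truth.units["cell_class"].to_numpy()
            amp_ids = session.truth.class_units("amp_tuned")
            dir_ids = session.truth.class_units("dir_tuned")
            auc = math.nan
            if amp_ids.size and dir_ids.size:
                auc = targeted.rank_auc(
                    table.loc[amp_ids, "tuning_diff"].to_numpy(),
                    table.loc[dir_ids, "tuning_diff"].to_numpy(),
                )
            report["targeted_dims"] = {
                "amp_tuning_slope_z_per_mm": tun_a.slope,
                "dir_tuning_slope_z_per_rad": tun_d.slope,
                "omega_dot": float(dims.omega_a @ dims.omega_d),
                "class_separation_auc": auc,
            }
            report["_tdr_table"] = table
        except Exception as exc:  # noqa: BLE001
            logger.exception("targeted-dims stage failed")
            report["errors"]["targeted_dims"] = str(exc)

    if config.run_classifier:
        try:
            rng = np.random.default_rng(seeds["classifier"])
            kept = tensor_move.trial_ids
            labels = bayes.tertile_labels(amps[kept])
            n_folds = min(config.nb_n_folds, int(np.unique(labels, return_counts=True)[1].min()))
            pop_counts = tensor_move.counts.transpose(2, 0, 1)  # (trials, units, bins)
            subsets = _class_subsets(session)
            sizes = [len(v) for v in subsets.values()] or [pop_counts.shape[1]]
            match_n = min(sizes)
            unit_ids = session.truth.units.index.to_numpy()
            pos = {u: i for i, u in enumerate(unit_ids)}
            results = {}
            rep_all = bayes.crossval(
                pop_counts, labels, n_iter=config.nb_n_iter, n_folds=n_folds,
                subsample_to=match_n, rng=rng, label="all")
            results["all"] = {"mean_accuracy_pct": rep_all.mean_accuracy,
                              "ci95": list(rep_all.ci95())}
            for name, ids in subsets.items():
                idx = [pos[u] for u in ids]
                rep = bayes.crossval(
                    pop_counts[:, idx, :], labels, n_iter=config.nb_n_iter,
                    n_folds=n_folds,
                    subsample_to=min(match_n, len(idx)), rng=rng, label=name)
                results[name] = {"mean_accuracy_pct": rep.mean_accuracy,
                                 "ci95": list(rep.ci95())}
            report["classifier"] = {
                "n_units_matched": int(match_n),
                "chance_pct": 100.0 / 3.0,
                "populations": results,
            }
        except Exception as exc:  # noqa: BLE001
            logger.exception("classifier stage failed")
            report["errors"]["classifier"] = str(exc)

    if config.run_pca:
        try:
            binned = bin_spikes(
                session.spikes, bin_ms=config.peth_bin_ms, t_start=0.0,
                t_stop=session.duration_s,
                unit_ids=session.truth.units.index.to_numpy())
            starts = [ev.start_s for ev in session.events]
            tensor = align_trials(binned, starts, window=(1.0, 1.5))
            D = sqrt_stack(tensor)
            res = pca.fit_pca(D, n_components=min(10, D.shape[0] - 1, D.shape[1]))
            n_bins = tensor.counts.shape[1]
            traj = pca.pc_trajectories(res, n_bins=n_bins, n_trials=tensor.n_trials,
                                       top_k=3)["all"]
            t_peak = tensor.bin_centers[int(np.argmax(np.abs(traj[:, 0] - traj[:, 0].mean())))]
            report["pca"] = {
                "explained_variance_ratio_top3": [float(v) for v in
                                                  res.explained_variance_ratio[:3]],
                "pc1_peak_time_s": float(t_peak),
            }
            report["_pca_loadings"] = pd.DataFrame(
                res.W[:, :3], columns=["PC1", "PC2", "PC3"],
                index=session.truth.units.index)
        except Exception as exc:  # noqa: BLE001
            logger.exception("pca stage failed")
            report["errors"]["pca"] = str(exc)

    if config.run_optotag:
        try:
            criteria = optotag.TagCriteria(
                alpha=config.tag_alpha, reduction_thresh=config.tag_reduction,
                z_thresh=config.tag_z)
            tag_times = session.tag_spikes
            results = []
            for u in session.truth.units.index:
                st = tag_times.loc[tag_times["unit_id"] == u, "time_s"].to_numpy()
                results.append(optotag.test_tagged(
                    st, session.laser_onsets, pulse_s=1.0, criteria=criteria, unit_id=int(u)))
            truth_tag = session.truth.units["tagged"].to_numpy()
            called = np.array([r.tagged_stringent for r in results])
            sens = float(called[truth_tag].mean()) if truth_tag.any() else math.nan
            fpr = float(called[~truth_tag].mean()) if (~truth_tag).any() else math.nan
            lat = [r.latency_half_max_ms for r in results
                   if r.tagged_stringent and not math.isnan(r.latency_half_max_ms)]
            dur = [r.duration_below_half_max_ms for r in results
                   if r.tagged_stringent and not math.isnan(r.duration_below_half_max_ms)]
            report["optotag"] = {
                "n_tagged_stringent": int(called.sum()),
                "n_tagged_lenient": int(sum(r.tagged_lenient for r in results)),
                "sensitivity_vs_truth": sens,
                "false_positive_rate_vs_truth": fpr,
                "mean_latency_half_max_ms": float(np.mean(lat)) if lat else math.nan,
                "mean_duration_below_half_max_ms": float(np.mean(dur)) if dur else math.nan,
            }
            report["_tag_table"] = pd.DataFrame([dataclasses.asdict(r) for r in results])
        except Exception as exc:  # noqa: BLE001
            logger.exception("optotag stage failed")
            report["errors"]["optotag"] = str(exc)

    if outdir is not None:
        _write_report(report, Path(outdir))
    return report


def _load_session_from_files(config: PipelineConfig) -> Session:
    from . import io as rio

    for name in ("trace_path", "spikes_path"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"files mode requires {name}; missing: {p!r}")
    trace = rio.read_trace(config.trace_path)
    spikes = rio.read_spikes(config.spikes_path)
    cfg = config.session
    events = detect_reaches(trace, speed_on=cfg.speed_on, speed_off=cfg.speed_off)
    events, reward_times = label_trials(
        events, cfg.block_thresholds, trials_per_block=cfg.trials_per_block,
        reward_delay_s=cfg.reward_delay_s, iti_s=cfg.iti_s, trace=trace)
    unit_ids = np.unique(spikes["unit_id"].to_numpy())
    units = pd.DataFrame(
        {
            "cell_class": "unknown",
            "baseline_hz": np.nan,
            "amp_gain": 0.0,
            "dir_gain": 0.0,
            "pref_dir": 0.0,
            "reward_mod": 0.0,
            "tagged": False,
            "inhib_frac": 0.0,
            "inhib_latency_ms": 0.0,
        },
        index=pd.Index(unit_ids, name="unit_id"),
    )
    from .synthetic import GroundTruth

    tag_spikes = pd.DataFrame({"unit_id": [], "time_s": []})
    onsets = np.empty(0)
    if config.tag_spikes_path and config.laser_onsets_path:
        tag_spikes = rio.read_spikes(config.tag_spikes_path)
        onsets = np.loadtxt(config.laser_onsets_path, ndmin=1)
    planted = pd.DataFrame()
    return Session(
        config=cfg, trace=trace, events=events, planted=planted,
        reward_times=reward_times, truth=GroundTruth(units=units), spikes=spikes,
        tag_spikes=tag_spikes, laser_onsets=onsets)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_json_safe(v) for v in obj.tolist()]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def _write_report(report: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {k: v for k, v in report.items() if k.startswith("_")}
    payload = {k: v for k, v in report.items() if not k.startswith("_")}
    (outdir / "report.json").write_text(
        json.dumps(_json_safe(payload), indent=1, sort_keys=True))
    if "_tdr_table" in tables:
        tables["_tdr_table"].to_csv(outdir / "per_unit_tuning.csv")
    if "_tag_table" in tables:
        tables["_tag_table"].to_csv(outdir / "tag_table.csv", index=False)
    if "_pca_loadings" in tables:
        tables["_pca_loadings"].to_csv(outdir / "pc_loadings.csv")
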