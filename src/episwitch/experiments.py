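"""Seeded end-to-end experiment runners tying simulation, estimation, FISH
synthesis and spot calling into reproducible tables."""

from __future__ import annotations

import itertools
import logging
import time

import numpy as np
import pandas as pd

from . import fish_synth, sector_stats, spot_caller
from .config import RunConfig, config_hash
from .errors import ConfigError

__all__ = ["run_sector_experiment", "run_fish_experiment"]

logger = logging.getLogger(__name__)


def run_sector_experiment(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every configured strain and estimate its switching rate.

    Returns a per-strain rates table and a pairwise comparisons table (fold
    of the larger over the smaller mean, delta-method SE, Student's t).
    """
    blk = config.switch
    if not blk.get("strains"):
        raise ConfigError("switch.strains: at least one strain is required")
    n_colonies = int(blk.get("n_colonies", 100_000))
    n_replicates = int(blk.get("n_replicates", 3))
    method = blk.get("method", "thinned")
    bootstrap = int(blk.get("bootstrap", 0))

    t0 = time.perf_counter()
    logger.info(
        "sector experiment %s: seed=%s hash=%s strains=%d",
        config.experiment, config.seed, config_hash(config), len(blk["strains"]),
    )
    names = sorted(blk["strains"])
    seeds = np.random.SeedSequence(config.seed).spawn(len(names))
    estimates: dict[str, sector_stats.RateEstimate] = {}
    rows = []
    for name, ss in zip(names, seeds):
        params = config.switch_params(name)
        est = sector_stats.recover_rate(
            params, n_colonies, n_replicates, np.random.default_rng(ss),
            method=method, ci=bootstrap > 0, n_boot=bootstrap or 2000,
        )
        estimates[name] = est
        ci = est.ci or (np.nan, np.nan, np.nan)
        rows.append((name, params.p_div, est.mean, est.sd, est.n_replicates, ci[1], ci[2]))
        logger.info("  %s: rate=%.4g (p_div=%.4g) [%.1fs]", name, est.mean, params.p_div, time.perf_counter() - t0)
    rates = pd.DataFrame(rows, columns=["strain", "p_div", "mean", "sd", "n_replicates", "ci_lower", "ci_upper"])

    comp_rows = []
    for a, b in itertools.combinations(names, 2):
        hi, lo = (a, b) if estimates[a].mean >= estimates[b].mean else (b, a)
        if estimates[lo].mean > 0:
            fc = sector_stats.fold_change(estimates[hi], estimates[lo])
            fold, fold_se = fc.ratio, fc.se
        else:
            fold, fold_se = np.nan, None
        tt = sector_stats.two_sample_t(estimates[hi].replicate_estimates, estimates[lo].replicate_estimates)
        comp_rows.append((f"{hi}/{lo}", hi, lo, fold, fold_se, tt.statistic, tt.pvalue))
    comparisons = pd.DataFrame(
        comp_rows, columns=["pair", "numerator", "denominator", "fold", "fold_se", "t", "p"]
    )
    logger.info("sector experiment done in %.1fs", time.perf_counter() - t0)
    return rates, comparisons


def run_fish_experiment(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate synthetic two-channel FISH stacks per strain, call spots with
    one stored threshold per channel, and emit count summaries plus
    detection scores against the generative ground truth."""
    blk = config.fish
    if not blk.get("strains"):
        raise ConfigError("fish.strains: at least one strain is required")
    spec = fish_synth.StackSpec(**blk.get("stack", {}))
    if spec.n_cells < 1:
        raise ConfigError("fish.stack.n_cells: must be >= 1")
    n_stacks = int(blk.get("n_stacks", 1))
    caller = config.caller
    sigma_xy = float(caller.get("sigma_xy", spec.sigma_xy))
    sigma_z = float(caller.get("sigma_z", spec.sigma_z))
    size_range = (int(caller.get("min_size", 4)), int(caller.get("max_size", 200)))
    k_mad = float(caller.get("k_mad", 8.0))
    match_radius = float(caller.get("match_radius", 3.0))
    # one stored threshold per channel, shared across every sample of the run
    thresholds: dict[str, float | None] = {
        "channel_a": caller.get("threshold_a"),
        "channel_b": caller.get("threshold_b"),
    }

    t0 = time.perf_counter()
    logger.info(
        "fish experiment %s: seed=%s hash=%s", config.experiment, config.seed, config_hash(config)
    )
    names = sorted(blk["strains"])
    seeds = np.random.SeedSequence(config.seed).spawn(len(names))
    per_cell: dict[tuple[str, str], list[np.ndarray]] = {}
    matched: dict[tuple[str, str], list[spot_caller.DetectionScore]] = {}
    for name, ss in zip(names, seeds):
        models = blk["strains"][name]
        model_a = fish_synth.CountModel.from_dict(models["channel_a"])
        model_b = fish_synth.CountModel.from_dict(models["channel_b"])
        for rng in (np.random.default_rng(s) for s in ss.spawn(n_stacks)):
            fx = fish_synth.make_two_channel_fixture(model_a, model_b, spec, rng)
            for channel, stack, truth in (
                ("channel_a", fx.stack_a, fx.truth_a),
                ("channel_b", fx.stack_b, fx.truth_b),
            ):
                filtered = spot_caller.log_filter_3d(stack, sigma_xy, sigma_z)
                if thresholds[channel] is None:
                    thresholds[channel] = spot_caller.suggest_threshold(filtered, k=k_mad)
                    logger.info("  stored %s threshold: %.3g", channel, thresholds[channel])
                spots = spot_caller.detect_spots(filtered, thresholds[channel], size_range=size_range)
                spots, counts = spot_caller.assign_spots_to_cells(spots, fx.mask)
                key = (name, channel)
                per_cell.setdefault(key, []).append(counts.to_numpy())
                matched.setdefault(key, []).append(
                    spot_caller.score_detection(spots, truth.spots, match_radius=match_radius)
                )
        logger.info("  %s done [%.1fs]", name, time.perf_counter() - t0)

    srows, drows = [], []
    for (name, channel), counts_list in per_cell.items():
        counts = np.concatenate(counts_list)
        s = spot_caller.summarize_counts(counts)
        srows.append(
            (name, channel, s.mean_spots_per_cell, s.variance, s.pct_cells_gt0,
             s.pct_cells_gt1, s.n_cells, s.dispersion_index)
        )
        scores = matched[(name, channel)]
        n_match = sum(sc.n_matched for sc in scores)
        n_calls = sum(sc.n_calls for sc in scores)
        n_truth = sum(sc.n_truth for sc in scores)
        precision = n_match / n_calls if n_calls else np.nan
        recall = n_match / n_truth if n_truth else np.nan
        drows.append((name, channel, precision, recall, n_calls, n_truth, thresholds[channel]))
    summary = pd.DataFrame(
        srows,
        columns=["strain", "channel", "mean_spots_per_cell", "variance",
                 "pct_cells_gt0", "pct_cells_gt1", "n_cells", "dispersion_index"],
    )
    detection = pd.DataFrame(
        drows, columns=["strain", "channel", "precision", "recall", "n_calls", "n_truth", "threshold"]
    )
    logger.info("fish experiment done in %.1fs", time.perf_counter() - t0)
    return summary, detection
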