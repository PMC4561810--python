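"""End-to-end analysis pipeline on a set of game records.

Stages, in order: derive or load classification thresholds; classify every
dyad by its two-trial pattern counts; fit the requested utility models to
each dyad; build BIC comparison tables against the chance baseline; run the
sliding-window non-stationary analysis per dyad.  Outputs are CSV/JSON files
plus a run manifest recording the master seed and a hash of the configuration
so a rerun reproduces the numbers exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from .game import (
    DEFAULT_PAYOFFS,
    GameRecord,
    PayoffMatrix,
    REFERENCE_THRESHOLDS,
    Thresholds,
    classify,
    count_patterns,
)
from .fitting import FitResult, OptimizerConfig, compare_models, fit_pair
from .io import read_records
from .simulate import derive_thresholds
from .windows import diff_fit_correlation, diff_series, halves_ttest, sliding_fit

logger = logging.getLogger("hawkdove")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Settings for one pipeline run."""

    input_csv: str
    out_dir: str
    models: Sequence[str] = ("fs", "cox", "sc")
    matrix: PayoffMatrix = field(default_factory=lambda: DEFAULT_PAYOFFS)
    thresholds: Optional[Thresholds] = None  # None -> derive
    threshold_sims: int = 100_000
    window_size: int = 20
    window_models: Sequence[str] = ("sc",)
    n_starts: int = 20
    window_starts: int = 5
    seed: int = 0
    run_windows: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["matrix"] = self.matrix.to_dict()
        d["thresholds"] = None if self.thresholds is None else self.thresholds.as_dict()
        d["models"] = list(self.models)
        d["window_models"] = list(self.window_models)
        return d

    def config_hash(self) -> str:
        # out_dir does not affect any computed number; exclude it so reruns
        # into a different directory produce byte-identical outputs
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _stamp(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.config_hash()
    df["seed"] = config.seed
    return df


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run the full analysis; returns the in-memory report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = read_records(config.input_csv, matrix=config.matrix)
    if not records:
        raise ValueError(f"no game records found in {config.input_csv}")
    logger.info("loaded %d dyads", len(records))

    # 1. thresholds
    if config.thresholds is not None:
        thresholds = config.thresholds
        source = "fixed"
    else:
        logger.info("deriving thresholds from %d simulations", config.threshold_sims)
        thresholds = derive_thresholds(
            config.threshold_sims, matrix=config.matrix, seed=config.seed
        )
        source = f"derived (n_sims={config.threshold_sims})"
    (out / "thresholds.json").write_text(
        json.dumps(
            {
                "thresholds": thresholds.as_dict(),
                "source": source,
                "seed": config.seed,
                "config_hash": config.config_hash(),
            },
            indent=2,
        )
        + "\n"
    )

    # 2. classification
    labels: Dict[str, str] = {}
    class_rows = []
    for rec in records:
        counts = count_patterns(rec)
        label = classify(counts, thresholds)
        labels[rec.pair_id] = label
        class_rows.append({"pair_id": rec.pair_id, "label": label, **counts.as_dict()})
    class_df = pd.DataFrame(class_rows)
    _stamp(class_df, config).to_csv(out / "classification.csv", index=False)
    logger.info("classified: %s", class_df["label"].value_counts().to_dict())

    # 3. model fits
    fits: Dict[str, Dict[str, FitResult]] = {}
    opt_cfg = OptimizerConfig(n_starts=config.n_starts, seed=config.seed)
    for rec in records:
        fits[rec.pair_id] = {}
        for model in config.models:
            fits[rec.pair_id][model] = fit_pair(model, rec, config.matrix, opt_cfg)
        logger.info("fitted pair %s", rec.pair_id)
    fits_json = {
        pid: {m: fr.to_dict() for m, fr in per.items()} for pid, per in fits.items()
    }
    (out / "fits.json").write_text(
        json.dumps(
            {"config_hash": config.config_hash(), "seed": config.seed, "fits": fits_json},
            indent=2,
        )
        + "\n"
    )

    # 4. comparison tables
    comparison = compare_models(fits, labels)
    _stamp(comparison.summary, config).to_csv(out / "comparison.csv", index=False)
    _stamp(comparison.pairwise, config).to_csv(out / "comparison_pairwise.csv", index=False)

    # 5. sliding windows
    window_frames: List[pd.DataFrame] = []
    window_tests = []
    if config.run_windows:
        win_cfg = OptimizerConfig(n_starts=config.window_starts, seed=config.seed)
        for rec in records:
            if rec.n_trials < config.window_size:
                logger.warning("pair %s shorter than window; skipped", rec.pair_id)
                continue
            for model in config.window_models:
                series = sliding_fit(model, rec, config.window_size, config.matrix, win_cfg)
                window_frames.append(series.param_frame().assign(model=model))
                ds = diff_series(series)
                tt = halves_ttest(ds).add_prefix("halves_")
                cc = diff_fit_correlation(ds).add_prefix("corr_")
                merged = tt.join(cc).reset_index()
                merged.insert(0, "model", model)
                merged.insert(0, "pair_id", rec.pair_id)
                window_tests.append(merged)
            logger.info("windowed pair %s", rec.pair_id)
        if window_frames:
            _stamp(pd.concat(window_frames, ignore_index=True), config).to_csv(
                out / "windows.csv", index=False
            )
            _stamp(pd.concat(window_tests, ignore_index=True), config).to_csv(
                out / "window_tests.csv", index=False
            )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_pairs": len(records),
        "thresholds": thresholds.as_dict(),
        "note": "window-level p-values are descriptive; overlapping windows are autocorrelated",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return {
        "thresholds": thresholds,
        "labels": labels,
        "classification": class_df,
        "fits": fits,
        "comparison": comparison,
        "window_tests": pd.concat(window_tests, ignore_index=True) if window_tests else None,
    }
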