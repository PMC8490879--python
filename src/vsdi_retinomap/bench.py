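"""Simulation benchmark: SNR x method repetition sweeps with summaries.

Each repetition simulates one experiment (a fresh seed per repetition)
and feeds the same movie to every requested method, so methods are
compared on common data.  The long-format results table carries the six
image statistics and the four cluster indices per (snr, method, rep).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .extract import METHODS
from .simulate import SimConfig, simulate_experiment

__all__ = ["run_sweep", "summarize", "ALL_METHODS"]

logger = logging.getLogger(__name__)

ALL_METHODS = tuple(METHODS)

_METRIC_COLS = [
    "mse",
    "psnr",
    "cnr",
    "mssim",
    "cc",
    "cp",
    "si_median",
    "dbi",
    "adjusted_si",
    "adjusted_dbi",
]


def run_sweep(
    snr_list,
    methods=ALL_METHODS,
    reps: int = 100,
    base_seed: int = 0,
    config: SimConfig | None = None,
    percentile: float = 90.0,
) -> pd.DataFrame:
    """Run the repetition sweep and return a long-format results table.

    Per-repetition seeds are ``base_seed + rep``; every method sees the
    same simulated movie within a repetition.  A method failing on a
    repetition yields a row of NaNs (and a logged error) rather than
    aborting the sweep.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base = config if config is not None else SimConfig()
    rows = []
    for snr_db in snr_list:
        for rep in range(reps):
            cfg = dataclasses.replace(base, snr_db=float(snr_db), seed=base_seed + rep)
            stack, truth, schedule = simulate_experiment(cfg)
            for name in methods:
                row = {
                    "snr_db": float(snr_db),
                    "method": name,
                    "rep": rep,
                    "seed": cfg.seed,
                }
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        result = METHODS[name](stack, schedule).fit()
                        row.update(result.evaluate(truth, percentile=percentile))
                except Exception as exc:
                    logger.error("method %s failed on rep %d: %s", name, rep, exc)
                    row.update({c: np.nan for c in _METRIC_COLS})
                rows.append(row)
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame, alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Per-(snr, method) mean/median/SD plus Tukey-HSD contrasts.

    Pairwise multiple-comparison marks (at the given alpha) are computed
    for each metric and SNR level across methods; the returned dict maps
    ``(snr_db, metric)`` to the fitted Tukey-HSD result.
    """
    if table["method"].nunique() < 2:
        raise ValueError("summaries need at least two methods")
    summary = (
        table.groupby(["snr_db", "method"])[_METRIC_COLS]
        .agg(["mean", "median", "std"])
        .reset_index()
    )
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tukey: dict = {}
    for snr_db, sub in table.groupby("snr_db"):
        if sub.groupby("method").size().min() < 2:
            continue
        for metric in ("si_median", "dbi", "adjusted_si", "adjusted_dbi"):
            vals = sub[metric]
            ok = vals.notna()
            if ok.sum() < 4 or sub.loc[ok, "method"].nunique() < 2:
                continue
            if vals[ok].std() == 0:
                continue  # identical columns: nothing to contrast
            tukey[(float(snr_db), metric)] = pairwise_tukeyhsd(
                vals[ok].to_numpy(), sub.loc[ok, "method"].to_numpy(), alpha=alpha
            )
    return summary, tukey
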