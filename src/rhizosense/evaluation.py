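"""End-to-end validation studies: detector scoring and effect recovery.

These routines run the full chain — simulate raw voltages, estimate R-C,
mask, detect, normalize by uptime, aggregate — on the reference scenarios
of :mod:`rhizosense.scenarios` and measure how well the pipeline recovers
what the simulator programmed: truth-log precision/recall, programmed
rate reductions, and programmed depth shifts.  They are used by the test
suite and the reproduction script; all randomness flows from the ``seed``
argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import scenarios
from .detect import run_trial, score_detections
from .simulate import TrialConfig
from .stats import (
    compare_groups,
    daily_rates,
    deeper_half_indices,
    exclude_sparse,
    interaction_anova,
    time_averaged_rate,
)

__all__ = [
    "score_scenario",
    "drought_effect_recovery",
    "depth_shift_recovery",
    "anova_type1_rate",
]


def score_scenario(config: TrialConfig) -> dict[str, float]:
    """Run the detector on a scenario and score it against the truth log."""
    result = run_trial(config)
    return score_detections(result.detections, result.truth, config.geometry)


def _group_window_rates(
    config: TrialConfig,
    window: tuple[int, int],
    depth_indices: list[int] | None = None,
) -> dict[str, np.ndarray]:
    """Per-treatment arrays of device time-averaged rates over a window."""
    result = run_trial(config)
    table = daily_rates(result.detections, result.uptime, config.geometry)
    a, b = window
    averaged = time_averaged_rate(table, a, b, depth_index=depth_indices)
    averaged = exclude_sparse(averaged, table, a, b)
    col = "R" if depth_indices is None else "Rd"
    merged = averaged.merge(result.devices, on="device_id")
    return {
        trt: grp[col].dropna().to_numpy()
        for trt, grp in merged.groupby("treatment")
    }


def drought_effect_recovery(seed: int = 1, n_per_group: int = 300) -> dict:
    """Recover the programmed drought rate reduction through the pipeline.

    Simulates the two-treatment drought scenario (x0.64 arrival-rate
    multiplier during the drought window), runs detection and rate
    statistics, and contrasts the groups' time-averaged rates over the
    window with a one-sided Welch test.
    """
    config = scenarios.drought_recovery(seed=seed, n_per_group=n_per_group)
    groups = _group_window_rates(config, scenarios.DROUGHT_WINDOW)
    ww, dr = groups["well_watered"], groups["drought"]
    cmp = compare_groups(ww, dr, direction="greater")
    reduction_pct = 100.0 * (1.0 - dr.mean() / ww.mean())
    return {
        "reduction_pct": reduction_pct,
        "programmed_pct": 36.0,
        "p": cmp.p,
        "t": cmp.t,
        "cohens_d": cmp.d,
        "n_well_watered": len(ww),
        "n_drought": len(dr),
        "mean_well_watered": ww.mean(),
        "mean_drought": dr.mean(),
    }


def depth_shift_recovery(seed: int = 1, n_per_group: int = 150) -> dict:
    """Recover the programmed deep-growth shift through the pipeline.

    The primed treatment concentrates post-drought arrivals in the deeper
    half of electrode depths; the contrast is on per-device mean
    deeper-half depth rates over the drought window.
    """
    config = scenarios.depth_shift(seed=seed, n_per_group=n_per_group)
    deep = deeper_half_indices(config.geometry)
    groups = _group_window_rates(
        config, scenarios.DROUGHT_WINDOW, depth_indices=deep
    )
    primed, ww = groups["primed"], groups["well_watered"]
    cmp = compare_groups(primed, ww, direction="greater")
    return {
        "p": cmp.p,
        "t": cmp.t,
        "cohens_d": cmp.d,
        "mean_deep_primed": primed.mean(),
        "mean_deep_well_watered": ww.mean(),
        "n_primed": len(primed),
        "n_well_watered": len(ww),
    }


def anova_type1_rate(
    seed: int = 1,
    n_sims: int = 1000,
    n_per_cell: int = 10,
    alpha: float = 0.05,
) -> float:
    """Empirical type-I error of the interaction test under the null.

    Simulates balanced 2x2 treatment-by-genotype tables with strictly
    additive cell means (no interaction) and returns the fraction of
    simulations whose interaction p-value falls below ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        rows = []
        for i, trt in enumerate(("WW", "DR")):
            for j, gen in enumerate(("G1", "G2")):
                mean = 1.0 + 0.8 * i + 0.5 * j  # additive: no interaction
                for v in rng.normal(mean, 1.0, n_per_cell):
                    rows.append({"R": v, "treatment": trt, "genotype": gen})
        out = interaction_anova(pd.DataFrame(rows))
        rejections += out["p"] < alpha
    return rejections / n_sims
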