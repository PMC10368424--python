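"""Grid calibration of the adhesion sensitivity coefficient alpha.

alpha is the only manually optimised parameter of the model: it maps the
ternary-bond count formed during a brief contact to an adhesion
probability, ``P_a = 1 - exp(-alpha N)``.  Every other parameter comes from
the literature or from direct measurement, so alpha is fitted once, by grid
search, against observed in vitro engagement fractions pooled over
co-incubation conditions, and then frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .engine import run_base


@dataclass(frozen=True)
class CalibrationCondition:
    """One observed condition: a base-model scenario and its measured
    engagement fraction (% of effector cells in synapses)."""

    config: RunConfig
    observed_engagement_pct: float


#: The four printed engagement fractions used for the default calibration:
#: 1 vs 8 x10^6 total cells/mL at E:T ~1, CD3(L)/CD19(M), 60 min.
PRINTED_ENGAGEMENT_CONDITIONS: tuple[tuple[float, float, float], ...] = (
    # (total cells/mL, BiTE ng/mL, observed % effectors engaged)
    (1e6, 20.0, 3.1),
    (8e6, 20.0, 15.3),
    (1e6, 100.0, 3.9),
    (8e6, 100.0, 27.8),
)


def printed_conditions(replicates: int = 10, seed: int = 0,
                       scaled_volume_ul: float = 0.1) -> list[CalibrationCondition]:
    out = []
    for density, conc, observed in PRINTED_ENGAGEMENT_CONDITIONS:
        cfg = RunConfig(model="base", total_density_per_ml=density, et_ratio=1.0,
                        cd3_level="L", cd19_level="M", bite_ng_per_ml=conc,
                        duration_min=60.0, replicates=replicates, seed=seed,
                        scaled_volume_ul=scaled_volume_ul)
        out.append(CalibrationCondition(cfg, observed))
    return out


def _with_alpha(cfg: RunConfig, alpha: float) -> RunConfig:
    params = cfg.params.model_copy(
        update={"adhesion": cfg.params.adhesion.model_copy(update={"alpha": alpha})})
    return cfg.model_copy(update={"params": params})


def calibration_loss(predicted_pct, observed_pct) -> float:
    """Mean squared log-accuracy ratio; scale-free so low- and
    high-engagement conditions weigh comparably."""
    pred = np.maximum(np.asarray(predicted_pct, dtype=float), 1e-3)
    obs = np.maximum(np.asarray(observed_pct, dtype=float), 1e-3)
    return float(np.mean(np.log(pred / obs) ** 2))


def calibrate_alpha(conditions: list[CalibrationCondition],
                    alpha_grid) -> pd.DataFrame:
    """Evaluate the pooled calibration loss over an alpha grid.

    Returns one row per grid point (alpha, loss, per-condition predictions)
    sorted by the grid; the best alpha is the row with minimal loss.
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if np.any(alpha_grid <= 0):
        raise ValueError("alpha grid must be positive")
    rows = []
    for alpha in alpha_grid:
        preds = []
        for cond in conditions:
            res = run_base(_with_alpha(cond.config, float(alpha)))
            preds.append(res.final_engagement_pct)
        rows.append({"alpha": float(alpha),
                     "loss": calibration_loss(preds, [c.observed_engagement_pct
                                                      for c in conditions]),
                     "predicted_pct": preds})
    return pd.DataFrame(rows)


def best_alpha(table: pd.DataFrame) -> float:
    return float(table.loc[table["loss"].idxmin(), "alpha"])
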