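"""Recovery benchmarks: can the pipeline recover a known virtual species?

Runs the full occurrence + abundance + adjustment pipeline on the demo
scenario (100×100 landscape, strong plateau signal) across seeds and
measures how well the fitted surfaces recover the known truth:

* out-of-bag ROC AUC of the occurrence model;
* whether the dominant occurrence driver ranks first in importance;
* Spearman rank correlation of the RIO surface with true p (at the
  training points) and of the adjusted RA surface with true λ (over all
  valid pixels);
* closed-form OLS recovery of a known linear calibration (A, B).

The per-seed pipeline uses 500 trees: at ~1,200 occurrence training
points the OOB estimates are already stable, and the benchmark stays
inexpensive. Sub-seeds are derived from the replicate seed by a fixed
affine scheme so every stage has its own stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import abundance as ab
from . import occurrence as occ
from .landsim import generate_landscape, simulate_observations, true_surfaces
from .layers import PREDICTOR_NAMES, build_stack, extract_at_points
from .scenarios import OCCURRENCE_DRIVER, demo_landscape_config, demo_response

#: pipeline settings of the benchmark (documented package choices)
N_TREES = 500
N_PSEUDO_ABSENCES = 1000


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 16 + k) % (2**31 - 1)


@dataclass
class RecoveryResult:
    """One seeded replicate of the recovery benchmark."""

    seed: int
    oob_roc: float
    top_importance: str
    rio_truth_spearman: float
    ra_truth_spearman: float
    abundance_oob_rmse: float
    adjustment_A: float
    adjustment_B: float
    adjustment_r_squared: float


def run_recovery(seed: int, rows: int = 100, cols: int = 100) -> RecoveryResult:
    """Run the full pipeline once on the demo scenario and score recovery."""
    config = demo_landscape_config(rows, cols, seed=_sub_seed(seed, 0))
    response = demo_response()
    landscape = generate_landscape(config)
    stack = build_stack(landscape)
    p_grid, lam_grid = true_surfaces(landscape, response, stack=stack)

    observations = simulate_observations(landscape, response,
                                         seed=_sub_seed(seed, 1), stack=stack)
    absences = occ.sample_pseudo_absences(landscape.study_mask,
                                          N_PSEUDO_ABSENCES, seed=_sub_seed(seed, 2))
    pres_samples = extract_at_points(stack, observations)
    abs_samples = extract_at_points(stack, absences)
    occ_samples = pd.concat([pres_samples, abs_samples], ignore_index=True)

    model = occ.fit_occurrence(occ_samples, n_trees=N_TREES, seed=_sub_seed(seed, 3))
    rio = occ.predict_rio(model, stack)

    # RIO vs true p at the training points
    row, col = rio.index_of(occ_samples["x"].to_numpy(), occ_samples["y"].to_numpy())
    rio_at = rio.values[row, col]
    p_at = p_grid.values[row, col]
    rio_rho = float(spearmanr(rio_at, p_at).statistic)

    # abundance on the presence samples, all candidates
    ab_model = ab.fit_abundance(pres_samples, list(PREDICTOR_NAMES),
                                n_trees=N_TREES, seed=_sub_seed(seed, 4))
    adj = ab.fit_adjustment(pres_samples["count"].to_numpy(),
                            ab_model.oob_predictions_)
    ra = ab.predict_abundance(ab_model, stack)
    ra_adj = ab.apply_adjustment(adj, ra)

    valid = ra_adj.valid & lam_grid.valid
    ra_rho = float(spearmanr(ra_adj.values[valid], lam_grid.values[valid]).statistic)

    return RecoveryResult(
        seed=seed,
        oob_roc=model.oob_roc_auc_,
        top_importance=model.importances_[0][0],
        rio_truth_spearman=rio_rho,
        ra_truth_spearman=ra_rho,
        abundance_oob_rmse=ab_model.oob_rmse_,
        adjustment_A=adj.A,
        adjustment_B=adj.B,
        adjustment_r_squared=adj.r_squared,
    )


def run_recovery_study(n_seeds: int = 20, base_seed: int = 0,
                       rows: int = 100, cols: int = 100) -> pd.DataFrame:
    """Recovery benchmark over ``n_seeds`` replicates; one row per seed."""
    results = [
        run_recovery(_sub_seed(base_seed, 7) + i, rows=rows, cols=cols)
        for i in range(n_seeds)
    ]
    return pd.DataFrame([r.__dict__ for r in results])


def summarize_recovery(study: pd.DataFrame) -> dict[str, float]:
    """Headline numbers of a recovery study."""
    return {
        "mean_oob_roc": float(study["oob_roc"].mean()),
        "top_driver_rate": float((study["top_importance"] == OCCURRENCE_DRIVER).mean()),
        "mean_rio_truth_spearman": float(study["rio_truth_spearman"].mean()),
        "mean_ra_truth_spearman": float(study["ra_truth_spearman"].mean()),
        "mean_adjustment_r_squared": float(study["adjustment_r_squared"].mean()),
    }


def adjustment_recovery(seed: int, A: float = 2.0, B: float = 3.0,
                        n: int = 1000, noise_sd: float = 0.5) -> dict[str, float]:
    """Recover a known linear calibration from noisy pairs.

    Generates predictions uniform on [0, 30], observations
    ``A·pred + B + N(0, noise_sd)``, refits by OLS and reports the
    relative recovery errors of A and B.
    """
    rng = np.random.default_rng(seed)
    pred = rng.uniform(0.0, 30.0, size=n)
    obs = A * pred + B + rng.normal(0.0, noise_sd, size=n)
    fit = ab.fit_adjustment(obs, pred)
    return {
        "A_true": A,
        "B_true": B,
        "A_hat": fit.A,
        "B_hat": fit.B,
        "A_rel_err": abs(fit.A - A) / abs(A),
        "B_rel_err": abs(fit.B - B) / abs(B),
        "r_squared": fit.r_squared,
    }
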