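"""Self-validation utilities: parameter-recovery grids and test calibration.

These routines measure how well the pipeline recovers known ground truth
from the synthetic generators, and the finite-sample calibration of the
statistical tests.  They are used by the test suite and the reproduction
script; problem sizes default to the scales of a typical recording session
(about 30 s of trace per fly, cohorts of tens of flies).
"""

from __future__ import annotations

import numpy as np

from .beatmetrics import TooFewBeatsError, compute_metrics, detect_beats
from .cohortstats import compare_slopes, fit_age_trend
from .synth import AgingModel, BeatTrainParams, GeometryParams, render_cardiogram, simulate_beat_train, simulate_cohort

__all__ = ["recovery_grid", "recovery_summary", "zar_type1_rate"]

#: Default recovery grid: mean heart periods (ms), interval CVs,
#: trace signal-to-noise ratios and frame rates.
GRID_HP_MS = (120.0, 150.0, 400.0)
GRID_CV = (0.0, 0.1, 0.3)
GRID_SNR = (5.0, 10.0)
GRID_FPS = (32.0, 200.0)

#: Simulated recording length (ms) per replicate, matching a full movie.
RECORD_MS = 30_000.0

EDD_UM = 70.0
ESD_UM = 45.0


def _one_recovery(hp_ms, cv, snr, fps, seed):
    n_beats = max(3, int(round(RECORD_MS / hp_ms)))
    params = BeatTrainParams(mean_period_ms=hp_ms, cv_period=cv, n_beats=n_beats)
    truth = simulate_beat_train(params, seed)
    noise_um = (EDD_UM - ESD_UM) / snr if snr and np.isfinite(snr) else 0.0
    geom = GeometryParams(
        edd_um=EDD_UM, esd_um=ESD_UM, frame_rate_hz=fps, trace_noise_um=noise_um
    )
    cardiogram, truth = render_cardiogram(truth, geom, seed)
    try:
        metrics = compute_metrics(detect_beats(cardiogram))
    except TooFewBeatsError:
        return dict(hp_err_rel=np.nan, ai_err_abs=np.nan, detected=False)
    return dict(
        hp_true_ms=truth.hp_true_ms,
        hp_est_ms=metrics.hp_ms,
        ai_true=truth.ai_true,
        ai_est=metrics.ai,
        hp_err_rel=abs(metrics.hp_ms - truth.hp_true_ms) / truth.hp_true_ms,
        ai_err_abs=abs(metrics.ai - truth.ai_true),
        detected=True,
    )


def recovery_grid(
    seed: int = 0,
    n_rep: int = 50,
    hp_grid=GRID_HP_MS,
    cv_grid=GRID_CV,
    snr_grid=GRID_SNR,
    fps_grid=GRID_FPS,
):
    """Parameter-recovery errors over the simulation grid.

    For every (HP, CV, SNR, fps) cell, ``n_rep`` independent beat trains
    are simulated, rendered as noisy diameter traces (SNR = stroke
    amplitude / trace noise SD), run through beat detection and metric
    computation, and compared with the realized ground truth.  Returns a
    DataFrame with one row per replicate.
    """
    import pandas as pd

    ss = np.random.SeedSequence(seed)
    rows = []
    for hp in hp_grid:
        for cv in cv_grid:
            for snr in snr_grid:
                for fps in fps_grid:
                    for rep, child in enumerate(ss.spawn(n_rep)):
                        rep_seed = int(child.generate_state(1)[0] % (2**31))
                        row = _one_recovery(hp, cv, snr, fps, rep_seed)
                        row.update(hp_ms=hp, cv=cv, snr=snr, fps=fps, rep=rep)
                        rows.append(row)
    return pd.DataFrame(rows)


def recovery_summary(grid) -> dict:
    """Headline recovery figures from a :func:`recovery_grid` table."""
    at200 = grid[grid["fps"] == 200.0]
    return {
        "median_hp_rel_err_200fps": float(at200["hp_err_rel"].median()),
        "ai_mae_200fps": float(at200["ai_err_abs"].mean()),
        "median_hp_rel_err_32fps": float(grid[grid["fps"] == 32.0]["hp_err_rel"].median()),
        "detection_rate": float(grid["detected"].mean()),
    }


def zar_type1_rate(
    seed: int = 0,
    n_rep: int = 1000,
    alpha: float = 0.05,
    n_per_group: int = 10,
    ages=(10, 30, 45, 60),
    metric: str = "hp_ms",
) -> float:
    """Empirical type-I error of the two-slope test under equal planted slopes.

    Simulates ``n_rep`` cohorts of two conditions with identical linear age
    trends plus Gaussian between-fly noise, fits both trends and counts
    rejections at ``alpha``.  A calibrated test rejects at about the nominal
    rate.
    """
    model = AgingModel(
        conditions=(
            ("a", (("hp_ms", (130.0, 2.4)),)),
            ("b", (("hp_ms", (130.0, 2.4)),)),
        ),
        noise_sd=(("hp_ms", 20.0),),
    )
    ss = np.random.SeedSequence(seed)
    rejections = 0
    for child in ss.spawn(n_rep):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        df = simulate_cohort(model, n_per_group, ages, rep_seed)
        fit_a = fit_age_trend(df, metric, condition="a")
        fit_b = fit_age_trend(df, metric, condition="b")
        if compare_slopes(fit_a, fit_b).p_value < alpha:
            rejections += 1
    return rejections / n_rep
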