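"""Shared simulation helpers for the test suite."""

import numpy as np

from bbbmap import (
    AIFParams,
    B1Map,
    DynamicSeries,
    KineticsConfig,
    T1M0Maps,
    VIFCurve,
    build_regressors,
    fit_volume,
    population_aif,
    signal_to_concentration,
    spgr_signal,
)

# study-like acquisition: 160 dynamics at 7.6 s, bolus on the 8th dynamic
N_DYN, DT_S, BOLUS = 160, 7.6, 8
TR_MS, FLIP_DEG = 5.0, 18.0
T1_S, M0 = 1.0, 1000.0


def patlak_noise_errors(
    snr: float,
    n_voxels: int = 1000,
    ktrans: float = 3e-3,
    vp: float = 0.02,
    seed: int = 0,
    noise_model: str = "rician",
) -> dict[str, float]:
    """Median |relative error| of Patlak estimates under magnitude noise.

    Synthesises ``n_voxels`` identical tissue curves through the SPGR forward
    model, adds Rician (or Gaussian) noise with sigma = baseline signal / SNR,
    runs the conversion with the true T1/M0, and fits the uptake model with
    the noiseless plasma curve as regressors.
    """
    rng = np.random.default_rng(seed)
    times_s = np.arange(N_DYN) * DT_S
    t_min = times_s / 60.0
    cfg = KineticsConfig()
    aif = AIFParams(onset_time=float(t_min[BOLUS - 1]))
    cp = population_aif(t_min, aif) / (1.0 - cfg.hematocrit)
    vif = VIFCurve(cp=cp, times=t_min, bolus_time=float(t_min[BOLUS - 1]),
                   bolus_dynamic=BOLUS, n_roi_voxels=50,
                   hematocrit_used=cfg.hematocrit)
    reg = build_regressors(vif)
    ct = vp * reg.cp + ktrans * reg.cp_integral

    r1t = 1.0 / T1_S + cfg.r1 * ct
    clean = spgr_signal(M0, 1.0 / r1t, TR_MS, FLIP_DEG)
    sigma = clean[0] / snr
    shape = (n_voxels, 1, 1, N_DYN)
    sig = np.broadcast_to(clean, shape)
    if noise_model == "rician":
        noisy = np.hypot(sig + rng.normal(0, sigma, shape), rng.normal(0, sigma, shape))
    else:
        noisy = sig + rng.normal(0, sigma, shape)

    series = DynamicSeries(noisy, times_s, BOLUS, FLIP_DEG, TR_MS)
    grid = (n_voxels, 1, 1)
    t1m0 = T1M0Maps(t1=np.full(grid, T1_S), m0=np.full(grid, M0),
                    valid=np.ones(grid, bool))
    conc = signal_to_concentration(series, t1m0, B1Map(np.ones(grid)), cfg)
    maps = fit_volume(conc, vif, np.ones(grid, bool))
    kt_err = np.abs(maps.ktrans.ravel() - ktrans) / ktrans
    vp_err = np.abs(maps.vp.ravel() - vp) / vp
    return {
        "ktrans": float(np.nanmedian(kt_err)),
        "vp": float(np.nanmedian(vp_err)),
        "n": n_voxels,
    }
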