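"""MEG/EEG source-spectra comparison: log transform, per-frequency scaling
regression, and the max-statistic permutation test.

The two modalities are related by the multiplicative model
MEG_sfc = exp(a_f) * EEG_sfc^(b_f) * exp(E_sfc): after a log transform the
per-frequency regression MEG = a_f + b_f * EEG + E pools sources and cases,
a_f capturing the acquisition-dependent power scale and b_f the spatial-decay
contraction of the EEG spectra.  Differences surviving the regression are
tested with a two-sample permutation test whose family-wise threshold comes
from the permutation null of the maximum absolute statistic over every
(source, frequency) cell; per-band maps union the significant cells across
the in-band frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RegressionResult:
    a: np.ndarray  # (F,) intercepts
    b: np.ndarray  # (F,) slopes
    r2: np.ndarray  # (F,)
    residuals: np.ndarray  # (S, F, C)


@dataclass
class PermutationTestResult:
    significant: np.ndarray  # (S, F) booleans
    statistic: np.ndarray  # (S, F)
    null_max: np.ndarray  # (n_perm,)
    threshold: float
    alpha: float
    n_permutations: int


def log_transform(spectra: np.ndarray) -> np.ndarray:
    """Elementwise natural log of strictly positive spectra."""
    spectra = np.asarray(spectra, dtype=np.float64)
    if np.any(spectra <= 0):
        idx = tuple(int(i) for i in np.unravel_index(int(np.argmax(spectra <= 0)), spectra.shape))
        raise ValueError(f"nonpositive spectrum value at index {idx}")
    return np.log(spectra)


def fit_scaling_model(meg_log: np.ndarray, eeg_log: np.ndarray) -> RegressionResult:
    """Per-frequency OLS of log MEG on log EEG, pooling sources and cases.

    Shapes are (sources, frequencies, cases) and must match.
    """
    meg_log = np.asarray(meg_log, dtype=np.float64)
    eeg_log = np.asarray(eeg_log, dtype=np.float64)
    if meg_log.shape != eeg_log.shape:
        raise ValueError("tensor shapes differ")
    S, F, C = meg_log.shape
    a = np.zeros(F)
    b = np.zeros(F)
    r2 = np.zeros(F)
    resid = np.zeros_like(meg_log)
    for f in range(F):
        x = eeg_log[:, f, :].ravel()
        y = meg_log[:, f, :].ravel()
        xc = x - x.mean()
        den = float(xc @ xc)
        if den == 0:
            raise ValueError(f"zero-variance regressor at frequency index {f}")
        b[f] = float(xc @ (y - y.mean())) / den
        a[f] = float(y.mean() - b[f] * x.mean())
        e = y - (a[f] + b[f] * x)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2[f] = 1.0 if ss_tot == 0 else 1.0 - float(e @ e) / ss_tot
        resid[:, f, :] = e.reshape(S, C)
    return RegressionResult(a, b, r2, resid)


def _cell_statistic(x: np.ndarray, y: np.ndarray, kind: str) -> np.ndarray:
    """Two-sample statistic per (s, f) cell; x, y are (S, F, C) tensors."""
    mx, my = x.mean(axis=2), y.mean(axis=2)
    nx, ny = x.shape[2], y.shape[2]
    vx = x.var(axis=2, ddof=1)
    vy = y.var(axis=2, ddof=1)
    se = np.sqrt(vx / nx + vy / ny)
    se = np.maximum(se, 1e-300)
    stat = (mx - my) / se
    if kind not in ("mean_diff", "t_like"):
        raise ValueError(f"unknown statistic {kind!r}")
    return stat


def permutation_max_test(
    meg_corrected: np.ndarray,
    eeg_corrected: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    statistic: str = "mean_diff",
) -> PermutationTestResult:
    """Two-sample max-statistic permutation test with family-wise control.

    Cases (subjects) are the permutation unit: modality labels are shuffled
    across the pooled 2C cases; the family-wise threshold is the (1 - alpha)
    quantile of the permutation distribution of max |statistic| over every
    (source, frequency) cell.
    """
    x = np.asarray(meg_corrected, dtype=np.float64)
    y = np.asarray(eeg_corrected, dtype=np.float64)
    if x.shape[:2] != y.shape[:2]:
        raise ValueError("source/frequency grids differ")
    if n_perm < int(np.ceil(1.0 / alpha)):
        raise ValueError(
            f"n_perm={n_perm} cannot resolve alpha={alpha}; need at least {int(np.ceil(1/alpha))}"
        )
    nx, ny = x.shape[2], y.shape[2]
    stat = _cell_statistic(x, y, statistic)
    pooled = np.concatenate([x, y], axis=2)  # (S, F, nx+ny)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(nx + ny)
        xs = pooled[:, :, perm[:nx]]
        ys = pooled[:, :, perm[nx:]]
        null_max[p] = np.max(np.abs(_cell_statistic(xs, ys, statistic)))
    threshold = float(np.quantile(null_max, 1.0 - alpha))
    sig = np.abs(stat) > threshold
    return PermutationTestResult(
        significant=sig, statistic=stat, null_max=null_max,
        threshold=threshold, alpha=alpha, n_permutations=n_perm,
    )


def band_indicator_map(
    significant: np.ndarray, frequencies: np.ndarray, bands: dict
) -> dict:
    """Per-band source masks: OR of the significant cells over in-band
    frequencies (band edges inclusive on the left, exclusive on the right)."""
    significant = np.asarray(significant, dtype=bool)
    frequencies = np.asarray(frequencies, dtype=np.float64)
    if significant.shape[1] != len(frequencies):
        raise ValueError("significance grid and frequency axis differ")
    out = {}
    for name, (lo, hi) in bands.items():
        in_band = (frequencies >= lo) & (frequencies < hi)
        if not np.any(in_band):
            raise ValueError(f"band {name!r} ({lo}-{hi} Hz) outside the frequency grid")
        out[name] = significant[:, in_band].any(axis=1)
    return out


def compare_source_spectra(
    meg_spectra: np.ndarray,
    eeg_spectra: np.ndarray,
    frequencies: np.ndarray,
    bands: dict,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    statistic: str = "mean_diff",
):
    """End-to-end comparison: log, regression correction, permutation test,
    band maps.  MEG residuals are tested against zero-centered EEG residuals
    (the regression removes the global scale/contraction differences)."""
    meg_log = log_transform(meg_spectra)
    eeg_log = log_transform(eeg_spectra)
    reg = fit_scaling_model(meg_log, eeg_log)
    # per-case centered EEG residuals on the same scale as the MEG residuals
    eeg_resid = (eeg_log - eeg_log.mean(axis=2, keepdims=True)) * reg.b[None, :, None]
    test = permutation_max_test(
        reg.residuals, eeg_resid, n_perm=n_perm, alpha=alpha, seed=seed, statistic=statistic
    )
    maps = band_indicator_map(test.significant, frequencies, bands)
    return reg, test, maps
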