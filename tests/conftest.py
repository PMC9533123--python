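"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from eegmse.io import EEGRecording
from eegmse.montage import MONTAGE_1020
from eegmse.pipeline import PipelineConfig, _iter_input, analyze_cohort


def sampen_bruteforce(y: np.ndarray, m: int, r: float) -> float:
    """Quadratic-time reference SampEn, independent of the package kernel.

    Counts template pairs i < j over the N−m templates admitting an
    (m+1)-point extension, with strict max-norm tolerance.
    """
    y = np.asarray(y, dtype=np.float64)
    nt = y.size - m
    tm = np.lib.stride_tricks.sliding_window_view(y, m + 1)[:nt]
    a = b = 0
    for i in range(nt - 1):
        d = np.abs(tm[i + 1:] - tm[i])
        b += int(np.sum(np.max(d[:, :m], axis=1) < r))
        a += int(np.sum(np.max(d, axis=1) < r))
    if a == 0 or b == 0:
        return np.nan
    return -np.log(a / b)


def bh_bruteforce(pvals, q):
    """Literal step-up rule by enumeration over all candidate ranks."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    ranked = np.sort(p)
    k_star = 0
    for k in range(1, m + 1):
        if ranked[k - 1] <= k * q / m:
            k_star = k
    if k_star == 0:
        return np.zeros(m, dtype=bool), 0.0
    crit = ranked[k_star - 1]
    return p <= crit, float(crit)


def make_recording(
    n_samples: int = 2000,
    fs: float = 200.0,
    seed: int = 0,
    n_channels: int = 19,
) -> EEGRecording:
    """White-noise recording on the canonical montage (or a prefix of it)."""
    rng = np.random.default_rng(seed)
    data = 10.0 * rng.standard_normal((n_channels, n_samples))
    return EEGRecording(
        data, fs, list(MONTAGE_1020[:n_channels]), subject_id=f"s{seed}"
    )


def reduced_null_config(seed: int) -> PipelineConfig:
    """Small fast cohort for null-calibration replicates.

    43 subjects, 19 electrodes, 8 scales in 8 one-scale bins, 2-3 epochs
    of 4 s at 128 Hz — preserves the 19 × 8 analysis grid while keeping a
    full pipeline replicate under a second.
    """
    return PipelineConfig(
        mode="synthetic",
        seed=seed,
        fs=128.0,
        duration=8.0,
        effect_size=0.0,
        epoch_len_gen=4.0,
        n_epochs_range=(2, 3),
        epoch_len=4.0,
        target_fs=128.0,
        n_scales=8,
        bin_width=1,
        compute_psd=False,
        make_figures=False,
    )


def reduced_effect_config(seed: int, effect_size: float = 0.10) -> PipelineConfig:
    """Moderate cohort for effect-recovery replicates.

    Full 40-scale / 8-bin grid and PSD control at 200 Hz with 2-3 epochs
    of 8 s per subject.
    """
    return PipelineConfig(
        mode="synthetic",
        seed=seed,
        fs=200.0,
        duration=16.0,
        effect_size=effect_size,
        epoch_len_gen=8.0,
        n_epochs_range=(2, 3),
        epoch_len=8.0,
        target_fs=200.0,
        make_figures=False,
    )


def run_reduced(cfg: PipelineConfig):
    """Run the full analysis chain quietly on a reduced config."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_cohort(_iter_input(cfg), cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
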