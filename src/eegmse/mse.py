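"""Multiscale entropy: coarse-graining, sample entropy, scale binning.

The scale-τ series is obtained by averaging non-overlapping windows of τ
consecutive samples,

    y_j = (1/τ) Σ_{i=(j−1)τ+1}^{jτ} x_i ,   1 ≤ j ≤ floor(N/τ),

and sample entropy is

    SampEn(m, r) = −ln [ U^{m+1}(r) / U^m(r) ],

where U^m(r) is the fraction of template-vector pairs (i ≠ j) whose
Chebyshev (max-coordinate) distance is below r.  Self-matches are excluded
and the pair-count normalisation cancels in the ratio.  Both counts are
taken over the N−m templates that admit an (m+1)-point extension (the
Richman–Moorman convention), so the brute-force definition can be matched
bit for bit.

By default each coarse-grained series is z-scored (population SD) before
matching, so r = 0.2 is in SD units of that scale's series.  Under this
per-scale normalisation the MSE curve of white noise is flat at the
analytic value −ln(erf(r/2)) for i.i.d. Gaussian data (≈ 2.185 at
r = 0.2), which makes deviations from flatness a pure signature of
temporal structure.  ``r_mode="global"`` instead fixes r in
SD units of the scale-1 series (the original Costa convention, under which
white-noise MSE decays with scale).

Sample entropy is computed by an O(n²) pair scan accelerated by sorting on
the first template coordinate, so only pairs already within r on that
coordinate are examined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .preprocess import EpochSet

__all__ = [
    "MSEConfig",
    "MSEProfile",
    "ScaleBinProfile",
    "coarse_grain",
    "zscore",
    "sample_entropy",
    "mse_curve",
    "epoch_mse",
    "concat_profiles",
    "bin_scales",
]


@dataclass(frozen=True)
class MSEConfig:
    """Parameters of the multiscale entropy estimate.

    m : embedding dimension (template length); default 2.
    r : tolerance in SD units of the (normalised) series; default 0.2.
    scales : coarse-graining factors τ; default 1..40.
    bin_width : scales averaged per reported bin; default 5 (→ 8 bins).
    r_mode : "per_scale" (z-score each coarse series; default) or
        "global" (r fixed in scale-1 SD units).
    """

    m: int = 2
    r: float = 0.2
    scales: tuple[int, ...] = tuple(range(1, 41))
    bin_width: int = 5
    r_mode: str = "per_scale"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if not self.r > 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if len(self.scales) == 0 or min(self.scales) < 1:
            raise ValueError("scales must be positive integers")
        if self.r_mode not in ("per_scale", "global"):
            raise ValueError(f"unknown r_mode {self.r_mode!r}")

    @property
    def n_bins(self) -> int:
        if len(self.scales) % self.bin_width:
            raise ValueError(
                f"{len(self.scales)} scales not divisible by bin width {self.bin_width}"
            )
        return len(self.scales) // self.bin_width


@dataclass
class MSEProfile:
    """SampEn indexed subject × electrode × scale (nats).

    ``values`` entries are NaN where SampEn was undefined (no template
    matches) in every contributing epoch; ``n_contrib`` counts the epochs
    that contributed to each cell.
    """

    values: np.ndarray  # (n_subjects, n_electrodes, n_scales)
    subjects: list[str]
    labels: list[str]
    scales: tuple[int, ...]
    fs: float
    n_epochs: np.ndarray  # kept epochs per subject
    n_contrib: np.ndarray  # (n_subjects, n_electrodes, n_scales)

    @property
    def dt_ms(self) -> float:
        """Base sampling interval in milliseconds (5 ms at 200 Hz)."""
        return 1000.0 / self.fs

    def to_frame(self):
        """Tidy table (subject, electrode, scale, sampen, n_epochs)."""
        import pandas as pd

        ns, ne, nt = self.values.shape
        subj = np.repeat(self.subjects, ne * nt)
        elec = np.tile(np.repeat(self.labels, nt), ns)
        scl = np.tile(self.scales, ns * ne)
        return pd.DataFrame(
            {
                "subject": subj,
                "electrode": elec,
                "scale": scl,
                "sampen": self.values.ravel(),
                "n_epochs": np.repeat(self.n_epochs, ne * nt),
            }
        )


@dataclass
class ScaleBinProfile:
    """SampEn averaged within consecutive scale bins (subject × electrode × bin)."""

    values: np.ndarray  # (n_subjects, n_electrodes, n_bins)
    subjects: list[str]
    labels: list[str]
    bin_scale_ranges: list[tuple[int, int]]  # inclusive τ ranges
    bin_ms_ranges: list[tuple[float, float]]  # τ·Δt ranges, ms

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    def to_frame(self):
        import pandas as pd

        ns, ne, nb = self.values.shape
        return pd.DataFrame(
            {
                "subject": np.repeat(self.subjects, ne * nb),
                "electrode": np.tile(np.repeat(self.labels, nb), ns),
                "scale_bin": np.tile(np.arange(1, nb + 1), ns * ne),
                "sampen": self.values.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Average non-overlapping windows of τ samples; remainder dropped."""
    x = np.asarray(x, dtype=np.float64)
    if tau < 1 or tau > x.size:
        raise ValueError(f"scale factor {tau} outside [1, {x.size}]")
    n = x.size // tau
    return x[: n * tau].reshape(n, tau).mean(axis=1)


def zscore(y: np.ndarray) -> np.ndarray:
    """Center and scale to unit population SD.

    A constant series has no scale; the result is all-NaN (an undefined
    sentinel that propagates as a masked SampEn), not an exception.
    """
    y = np.asarray(y, dtype=np.float64)
    sd = y.std()
    if sd == 0 or not np.isfinite(sd):
        return np.full_like(y, np.nan)
    return (y - y.mean()) / sd


@njit(cache=True)
def _sampen_counts(y, m, r):  # pragma: no cover - exercised via wrappers
    """Return (A, B): matched pairs at length m+1 and m, strict < r, i < j."""
    nt = y.size - m  # templates admitting an (m+1)-point extension
    if nt < 2:
        return 0, 0
    first = y[:nt].copy()
    order = np.argsort(first)
    a_count = 0
    b_count = 0
    for a in range(nt - 1):
        i = order[a]
        va = first[i]
        for b in range(a + 1, nt):
            j = order[b]
            if first[j] - va >= r:
                break
            ok = True
            for k in range(1, m):
                d = y[i + k] - y[j + k]
                if d >= r or d <= -r:
                    ok = False
                    break
            if ok:
                b_count += 1
                d = y[i + m] - y[j + m]
                if -r < d < r:
                    a_count += 1
    return a_count, b_count


def sample_entropy(y: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """SampEn of a 1-D series; NaN when no template pair matches.

    ``r`` is in the units of ``y`` — z-score first (or use
    :func:`mse_curve`) for the conventional SD-relative tolerance.
    """
    y = np.ascontiguousarray(y, dtype=np.float64)
    if y.size < m + 2:
        raise ValueError(f"series of length {y.size} too short for m={m}")
    if np.any(np.isnan(y)):
        return np.nan
    a, b = _sampen_counts(y, m, r)
    if a == 0 or b == 0:
        return np.nan
    return -np.log(a / b)


@njit(cache=True)
def _mse_curve_kernel(x, scales, m, r, per_scale):  # pragma: no cover
    out = np.full(scales.size, np.nan)
    if per_scale == 0:
        mu = x.mean()
        sd = np.sqrt(((x - mu) ** 2).mean())
        if sd <= 0:
            return out
        x = (x - mu) / sd
    for si in range(scales.size):
        tau = scales[si]
        nc = x.size // tau
        if nc < m + 2:
            continue
        y = np.empty(nc)
        for jj in range(nc):
            s = 0.0
            for ii in range(jj * tau, (jj + 1) * tau):
                s += x[ii]
            y[jj] = s / tau
        if per_scale == 1:
            mu = y.mean()
            sd = np.sqrt(((y - mu) ** 2).mean())
            if sd <= 0:
                continue
            y = (y - mu) / sd
        a, b = _sampen_counts(y, m, r)
        if a > 0 and b > 0:
            out[si] = -np.log(a / b)
    return out


def mse_curve(x: np.ndarray, cfg: MSEConfig = MSEConfig()) -> np.ndarray:
    """SampEn over ``cfg.scales`` for one series (coarse-grain → normalise →
    match); NaN at scales where SampEn is undefined."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    scales = np.asarray(cfg.scales, dtype=np.int64)
    if x.size // int(scales.max()) < cfg.m + 2:
        raise ValueError(
            f"series of {x.size} samples too short for scale {scales.max()}"
        )
    return _mse_curve_kernel(
        x, scales, cfg.m, cfg.r, 1 if cfg.r_mode == "per_scale" else 0
    )


# ---------------------------------------------------------------------------
# epoch-level profiles
# ---------------------------------------------------------------------------

def epoch_mse(es: EpochSet, cfg: MSEConfig = MSEConfig()) -> MSEProfile:
    """Epoch-averaged MSE profile for one subject.

    Each kept epoch yields a per-channel curve over scales; undefined
    (NaN) entries are excluded from the average.  Cells undefined in every
    epoch stay NaN and are reported with a warning.
    """
    if not es.usable:
        raise ValueError(f"subject {es.subject_id!r} has no kept epochs")
    n_ep, n_ch, _ = es.epochs.shape
    scales = np.asarray(cfg.scales, dtype=np.int64)
    per_scale = 1 if cfg.r_mode == "per_scale" else 0
    curves = np.full((n_ep, n_ch, scales.size), np.nan)
    for e in range(n_ep):
        for c in range(n_ch):
            curves[e, c] = _mse_curve_kernel(
                np.ascontiguousarray(es.epochs[e, c]), scales, cfg.m, cfg.r, per_scale
            )
    defined = np.isfinite(curves)
    n_contrib = defined.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(curves, axis=0)
    n_missing = int((n_contrib == 0).sum())
    if n_missing:
        warnings.warn(
            f"subject {es.subject_id!r}: {n_missing} (electrode, scale) cells "
            "undefined in every epoch"
        )
    return MSEProfile(
        values=mean[None],
        subjects=[es.subject_id],
        labels=list(es.labels),
        scales=tuple(int(t) for t in scales),
        fs=es.fs,
        n_epochs=np.array([n_ep]),
        n_contrib=n_contrib[None],
    )


def concat_profiles(profiles: list[MSEProfile]) -> MSEProfile:
    """Stack single-subject profiles into one cohort profile."""
    if not profiles:
        raise ValueError("no profiles to concatenate")
    p0 = profiles[0]
    for p in profiles[1:]:
        if p.labels != p0.labels or p.scales != p0.scales or p.fs != p0.fs:
            raise ValueError("profiles have incompatible axes")
    return MSEProfile(
        values=np.concatenate([p.values for p in profiles]),
        subjects=sum((p.subjects for p in profiles), []),
        labels=list(p0.labels),
        scales=p0.scales,
        fs=p0.fs,
        n_epochs=np.concatenate([p.n_epochs for p in profiles]),
        n_contrib=np.concatenate([p.n_contrib for p in profiles]),
    )


def bin_scales(profile: MSEProfile, bin_width: int | None = None) -> ScaleBinProfile:
    """Average consecutive scales into equal-width bins.

    With the default 40 scales and width 5, bin k spans τ = 5k−4 .. 5k,
    i.e. (5k−4)·Δt .. 5k·Δt in time (25 ms steps at 200 Hz, ending at
    180–200 ms for bin 8).  NaN scale entries are excluded from the bin
    mean; a bin is NaN only when all of its scales are undefined.
    """
    bw = bin_width if bin_width is not None else 5
    n_scales = len(profile.scales)
    if n_scales % bw:
        raise ValueError(f"{n_scales} scales not divisible by bin width {bw}")
    nb = n_scales // bw
    v = profile.values.reshape(*profile.values.shape[:2], nb, bw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        binned = np.nanmean(v, axis=3)
    scale_ranges = []
    ms_ranges = []
    for k in range(nb):
        lo_tau = profile.scales[k * bw]
        hi_tau = profile.scales[(k + 1) * bw - 1]
        scale_ranges.append((lo_tau, hi_tau))
        ms_ranges.append((lo_tau * profile.dt_ms, hi_tau * profile.dt_ms))
    return ScaleBinProfile(
        values=binned,
        subjects=list(profile.subjects),
        labels=list(profile.labels),
        bin_scale_ranges=scale_ranges,
        bin_ms_ranges=ms_ranges,
    )
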