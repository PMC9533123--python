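"""End-to-end orchestration: cohort → preprocess → MSE + PSD → statistics.

`run_pipeline` is the one-command entry point used by the CLI: it loads
or simulates a cohort, runs the per-subject analysis chain (band-pass,
resample, epoch, reject, multiscale entropy, Welch PSD), fits the
mixed-design ANCOVA, computes both post-hoc FDR grids and writes tidy
CSVs plus a machine-readable JSON summary and a provenance log.

`analyze_cohort` is the library-level core: it takes an iterable of
recordings plus the subject table and returns the result bundle without
touching the file system.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_delimited_matrix, read_edf
from .mse import MSEConfig, bin_scales, concat_profiles, epoch_mse
from .preprocess import bandpass, reject_epochs, resample, segment
from .simulate import CohortConfig, iter_cohort
from .spectral import concat_psd, welch_psd
from .stats import fit_rm_ancova, long_table, posthoc_ttests, psd_pointwise_tests

__all__ = ["PipelineConfig", "run_pipeline", "analyze_cohort", "render_heatmap"]


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    mode: str = "synthetic"  # synthetic | edf_dir | matrix_dir
    seed: int = 0
    out_dir: str = "eegmse_results"
    input_dir: str | None = None
    subject_table: str | None = None  # CSV with subject,group,age,sex[,score]
    # cohort (synthetic mode)
    n_high: int = 22
    n_low: int = 21
    fs: float = 500.0
    duration: float = 180.0
    effect_size: float = 0.1
    epoch_len_gen: float = 20.0
    n_epochs_range: tuple[int, int] = (9, 15)
    # preprocessing
    band: tuple[float, float] = (1.0, 60.0)
    target_fs: float = 200.0
    epoch_len: float = 20.0
    amp_thresh: float = 100.0
    # MSE
    m: int = 2
    r: float = 0.2
    n_scales: int = 40
    bin_width: int = 5
    r_mode: str = "per_scale"
    # Welch
    welch_window_sec: float = 2.0
    welch_overlap: float = 0.5
    # statistics
    covariates: tuple[str, ...] = ("age", "sex")
    fdr_q: float = 0.05
    equal_var: bool = True
    compute_psd: bool = True
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "edf_dir", "matrix_dir"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode != "synthetic" and not self.input_dir:
            raise ValueError(f"mode {self.mode!r} requires input_dir")
        for name in ("fs", "target_fs", "epoch_len", "amp_thresh", "r", "fdr_q"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_scales % self.bin_width:
            raise ValueError(
                f"{self.n_scales} scales not divisible by bin width {self.bin_width}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("band", "n_epochs_range", "covariates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def mse_config(self) -> MSEConfig:
        return MSEConfig(
            m=self.m,
            r=self.r,
            scales=tuple(range(1, self.n_scales + 1)),
            bin_width=self.bin_width,
            r_mode=self.r_mode,
        )


def _iter_input(cfg: PipelineConfig):
    """Yield (subject_row_dict, EEGRecording) for the configured source."""
    if cfg.mode == "synthetic":
        ccfg = CohortConfig(
            n_high=cfg.n_high,
            n_low=cfg.n_low,
            fs=cfg.fs,
            duration=cfg.duration,
            seed=cfg.seed,
            effect_size=cfg.effect_size,
            epoch_len=cfg.epoch_len_gen,
            n_epochs_range=cfg.n_epochs_range,
        )
        for spec, rec in iter_cohort(ccfg):
            yield (
                {
                    "subject": spec.subject_id,
                    "group": spec.group,
                    "age": spec.age,
                    "sex": spec.sex,
                    "score": spec.score,
                },
                rec,
            )
        return
    table = pd.read_csv(cfg.subject_table)
    reader = read_edf if cfg.mode == "edf_dir" else read_delimited_matrix
    ext = ".edf" if cfg.mode == "edf_dir" else ".csv"
    for _, row in table.iterrows():
        path = Path(cfg.input_dir) / f"{row['subject']}{ext}"
        rec = reader(path)
        rec.subject_id = str(row["subject"])
        yield row.to_dict(), rec


def analyze_cohort(
    records,
    cfg: PipelineConfig | None = None,
):
    """Run the analysis chain over (subject_info, EEGRecording) pairs.

    Returns a dict with the cohort MSE profile, binned profile, PSD
    matrix (or None), ANCOVA table, both post-hoc grids and the subject
    table restricted to usable subjects.
    """
    cfg = cfg or PipelineConfig()
    mse_cfg = cfg.mse_config()
    rows, profiles, psds, rejections = [], [], [], {}
    for info, rec in records:
        rec = bandpass(rec, cfg.band[0], cfg.band[1])
        rec = resample(rec, cfg.target_fs)
        es = segment(rec, cfg.epoch_len, max_scale=cfg.n_scales)
        es = reject_epochs(es, cfg.amp_thresh)
        rejections[rec.subject_id] = len(es.rejected)
        if not es.usable:
            warnings.warn(f"skipping unusable subject {rec.subject_id!r}")
            continue
        profiles.append(epoch_mse(es, mse_cfg))
        if cfg.compute_psd:
            psds.append(
                welch_psd(es, cfg.welch_window_sec, cfg.welch_overlap)
            )
        rows.append(info)
    if not profiles:
        raise RuntimeError("no usable subjects")
    table = pd.DataFrame(rows)
    profile = concat_profiles(profiles)
    binned = bin_scales(profile, cfg.bin_width)
    tbl = long_table(binned, table)
    ancova = fit_rm_ancova(tbl, covariates=cfg.covariates)
    post_mse = posthoc_ttests(binned, table, q=cfg.fdr_q, equal_var=cfg.equal_var)
    psd = post_psd = None
    if cfg.compute_psd:
        psd = concat_psd(psds)
        post_psd = psd_pointwise_tests(psd, table, q=cfg.fdr_q, equal_var=cfg.equal_var)
    return {
        "subject_table": table,
        "mse_profile": profile,
        "binned_profile": binned,
        "psd": psd,
        "ancova": ancova,
        "posthoc_mse": post_mse,
        "posthoc_psd": post_psd,
        "rejections": rejections,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline and write all outputs under cfg.out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = analyze_cohort(_iter_input(cfg), cfg)

    res["subject_table"].to_csv(out / "subject_table.csv", index=False)
    res["mse_profile"].to_frame().to_csv(out / "mse_profile.csv", index=False)
    res["binned_profile"].to_frame().to_csv(out / "binned_profile.csv", index=False)
    res["ancova"].to_csv(out / "ancova_table.csv", index=False)
    res["posthoc_mse"].to_frame().to_csv(out / "posthoc_mse.csv", index=False)
    if res["psd"] is not None:
        res["psd"].to_frame().to_csv(out / "psd.csv", index=False)
        res["posthoc_psd"].to_frame().to_csv(out / "posthoc_psd.csv", index=False)
    if cfg.make_figures:
        render_heatmap(res["posthoc_mse"], out / "posthoc_mse_heatmap.png")
        if res["posthoc_psd"] is not None:
            render_heatmap(res["posthoc_psd"], out / "posthoc_psd_heatmap.png")

    anc = res["ancova"]
    summary = {
        "n_subjects": int(len(res["subject_table"])),
        "n_mse_tests": int(res["posthoc_mse"].n_tests),
        "n_mse_discoveries": int(res["posthoc_mse"].q_mask.sum()),
        "group_F": float(anc.loc[anc["effect"] == "Group", "F"].iloc[0]),
        "group_p_gg": float(anc.loc[anc["effect"] == "Group", "p_gg"].iloc[0]),
        "group_partial_eta2": float(
            anc.loc[anc["effect"] == "Group", "partial_eta2"].iloc[0]
        ),
    }
    if res["posthoc_psd"] is not None:
        summary["n_psd_tests"] = int(res["posthoc_psd"].n_tests)
        summary["n_psd_discoveries"] = int(res["posthoc_psd"].q_mask.sum())
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    log = {
        "eegmse_version": __version__,
        "python": platform.python_version(),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "epochs_rejected": res["rejections"],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    res["summary"] = summary
    return res


def render_heatmap(grid, path) -> None:
    """Electrode × column heatmap of t values (diverging palette) with an
    FDR-masked right panel; warm colours mean higher values in the
    high-cognition group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = max(np.abs(grid.t).max(), 1e-9)
    masked = np.where(grid.q_mask, grid.t, np.nan)
    fig, axes = plt.subplots(
        1, 2, figsize=(11, 5), sharey=True, constrained_layout=True
    )
    for ax, data, title in (
        (axes[0], grid.t, "t (high − low)"),
        (axes[1], masked, "t, FDR q < 0.05"),
    ):
        im = ax.imshow(
            data, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
            interpolation="nearest",
        )
        ax.set_title(title)
        ax.set_xlabel(grid.column_name)
        if len(grid.columns) <= 10:
            ax.set_xticks(range(len(grid.columns)))
            ax.set_xticklabels(grid.columns)
    axes[0].set_yticks(range(len(grid.labels)))
    axes[0].set_yticklabels(grid.labels, fontsize=7)
    fig.colorbar(im, ax=axes, shrink=0.8, label="t")
    fig.savefig(path, dpi=120)
    plt.close(fig)
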