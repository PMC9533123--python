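"""Group statistics: mixed-design repeated-measures ANCOVA, post-hoc grids.

The omnibus model is the univariate mixed-design GLM: one between-subject
factor (group: high vs low cognitive function), two within-subject factors
(electrode: 19 levels in montage order; scale bin: 8 levels) and the
continuous covariates age (grand-mean centred) and sex (centred binary).

For each group-involving effect the subject-by-cell matrix is projected
onto orthonormal within-subject contrasts (the subject mean for the
between-subject Group effect; Kronecker products of electrode and bin
contrasts for the interactions), a multivariate regression on the
between-subject design is fitted, and the averaged univariate F is formed
from the traces of the hypothesis and error SSCP matrices:

    F = [tr(H)/d] / [tr(E)/(d·dfe)],  partial η² = tr(H)/(tr(H)+tr(E)),

with dfe = n − rank(X) (n − 4 with both covariates).  Sums of squares are
Type III with sum-to-zero group coding; with a single between factor and
no between-factor interactions this coincides with Type II.  Sphericity
violations are handled by the Greenhouse–Geisser adjustment: Box's
epsilon estimated from the error covariance of the contrast scores
shrinks both F degrees of freedom.

Post-hoc comparisons are plain two-sample t-tests per (electrode, bin)
cell — or per (electrode, frequency) for the PSD control analysis —
without covariate adjustment by default, corrected with the
Benjamini–Hochberg step-up procedure at q < 0.05 over the whole grid
(152 tests for MSE, 1121 for PSD).  Positive t means the high group's
mean is larger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AncovaTable",
    "PosthocGrid",
    "long_table",
    "fit_rm_ancova",
    "greenhouse_geisser_epsilon",
    "bh_fdr",
    "posthoc_ttests",
    "psd_pointwise_tests",
]

EFFECT_NAMES = ("Group", "Group x scale", "Group x node", "Node x scale x group")


@dataclass
class PosthocGrid:
    """Cell-wise t statistics with BH-FDR significance mask.

    ``t``, ``p``, ``q_mask`` are electrode × column grids (columns are
    scale bins or frequency points); ``critical_p`` is the largest raw p
    rejected by the step-up rule (0 when nothing is rejected).
    """

    t: np.ndarray
    p: np.ndarray
    q_mask: np.ndarray
    critical_p: float
    labels: list[str]
    columns: list
    column_name: str = "scale_bin"

    @property
    def n_tests(self) -> int:
        return self.p.size

    def to_frame(self) -> pd.DataFrame:
        ne, nc = self.t.shape
        return pd.DataFrame(
            {
                "electrode": np.repeat(self.labels, nc),
                self.column_name: np.tile(self.columns, ne),
                "t": self.t.ravel(),
                "p": self.p.ravel(),
                "significant": self.q_mask.ravel(),
            }
        )


class AncovaTable(pd.DataFrame):
    """Effect table (F, df, p, GG-adjusted p, partial η²) as a DataFrame."""

    @property
    def _constructor(self):
        return AncovaTable


def long_table(binned, subject_table: pd.DataFrame) -> pd.DataFrame:
    """Merge a ScaleBinProfile with subject covariates into tidy long form.

    Rows: (subject, group, age, sex, electrode, scale_bin, value); a
    complete case contributes one row per electrode × bin cell.
    """
    df = binned.to_frame().rename(columns={"sampen": "value"})
    cov = subject_table[["subject", "group", "age", "sex"]]
    out = df.merge(cov, on="subject", how="left")
    if out["group"].isna().any():
        miss = sorted(out.loc[out["group"].isna(), "subject"].unique())
        raise ValueError(f"subjects missing from subject table: {miss}")
    return out


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k × (k−1) orthonormal basis of the subspace orthogonal to the mean."""
    # QR of centred identity; any orthonormal completion works since the
    # trace statistics are invariant to rotation within the subspace
    a = np.eye(k) - np.full((k, k), 1.0 / k)
    q, _ = np.linalg.qr(a)
    return q[:, : k - 1]


def greenhouse_geisser_epsilon(within_cov: np.ndarray) -> float:
    """Box's epsilon-hat for a k × k within-cell covariance matrix.

    1 under compound symmetry (sphericity); bounded below by 1/(k−1).
    """
    W = np.asarray(within_cov, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("within_cov must be square")
    k = W.shape[0]
    if k < 2:
        raise ValueError("need at least 2 within-cells")
    if not np.allclose(W, W.T, atol=1e-8):
        raise ValueError("within_cov must be symmetric")
    Q = _orthonormal_contrasts(k)
    M = Q.T @ W @ Q
    tr = np.trace(M)
    denom = (k - 1) * np.sum(M * M)
    if denom <= 0:
        return 1.0
    return float(np.clip(tr * tr / denom, 1.0 / (k - 1), 1.0))


def _epsilon_from_error(E: np.ndarray, d: int) -> float:
    """GG epsilon from the error SSCP of orthonormal contrast scores."""
    tr = np.trace(E)
    denom = d * np.sum(E * E)
    if denom <= 0:
        return 1.0
    return float(np.clip(tr * tr / denom, 1.0 / d, 1.0))


def fit_rm_ancova(
    tbl: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> AncovaTable:
    """Mixed-design repeated-measures ANCOVA on a long table.

    ``tbl`` must carry columns subject, group, electrode, scale_bin,
    value, plus the covariates.  Subjects with any missing cell are
    dropped listwise (with a logged count).  Returns one row per
    group-involving effect: Group, Group × scale, Group × node,
    Node × scale × group — with F, df, uncorrected p, GG epsilon,
    GG-adjusted p and partial η².
    """
    electrodes = list(pd.unique(tbl["electrode"]))
    bins = sorted(pd.unique(tbl["scale_bin"]))
    ne, nb = len(electrodes), len(bins)

    wide = tbl.pivot_table(
        index="subject", columns=["electrode", "scale_bin"], values="value",
        sort=False,
    )
    # canonical cell order: electrode-major, bin-minor
    wide = wide.reindex(columns=pd.MultiIndex.from_product([electrodes, bins]))
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        warnings.warn(
            f"listwise deletion dropped {n_dropped} subject(s) with missing cells"
        )
    meta = tbl.drop_duplicates("subject").set_index("subject")
    meta = meta.loc[complete.index]
    n = len(complete)
    if n < 4:
        raise ValueError(f"only {n} complete subjects; cannot fit the model")
    groups = meta["group"].astype(str)
    if groups.nunique() != 2:
        raise ValueError(f"need exactly 2 groups, got {sorted(groups.unique())}")
    if (groups.value_counts() < 2).any():
        raise ValueError("need at least 2 complete subjects per group")

    # between-subject design: intercept, sum-coded group, centred covariates
    g = np.where(groups == "high", 1.0, -1.0)
    cols = [np.ones(n), g]
    for cv in covariates:
        v = meta[cv]
        if v.dtype == object or str(v.dtype) == "category":
            levels = sorted(v.astype(str).unique())
            if len(levels) == 1:
                raise ValueError(
                    f"covariate {cv!r} is constant; design would be singular"
                )
            if len(levels) != 2:
                raise ValueError(f"covariate {cv!r} must be binary or numeric")
            v = (v.astype(str) == levels[1]).astype(float)
        v = np.asarray(v, dtype=np.float64)
        cols.append(v - v.mean())
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "singular between-subject design (collinear group/covariates)"
        )
    dfe = n - X.shape[1]
    if dfe < 1:
        raise ValueError(f"no error degrees of freedom (n={n}, p={X.shape[1]})")

    Y = complete.to_numpy()  # n × (ne*nb), electrode-major
    Qe = _orthonormal_contrasts(ne)
    Qb = _orthonormal_contrasts(nb)
    ue = np.full((ne, 1), 1.0 / np.sqrt(ne))
    ub = np.full((nb, 1), 1.0 / np.sqrt(nb))
    contrasts = {
        "Group": np.kron(ue, ub),
        "Group x scale": np.kron(ue, Qb),
        "Group x node": np.kron(Qe, ub),
        "Node x scale x group": np.kron(Qe, Qb),
    }

    XtX_inv = np.linalg.inv(X.T @ X)
    P = X @ XtX_inv @ X.T
    R = np.eye(n) - P
    L = np.zeros((1, X.shape[1]))
    L[0, 1] = 1.0  # the group coefficient
    LXXL_inv = np.linalg.inv(L @ XtX_inv @ L.T)

    rows = []
    for name in EFFECT_NAMES:
        C = contrasts[name]
        d = C.shape[1]
        Yc = Y @ C
        B = XtX_inv @ X.T @ Yc
        LB = L @ B
        H = LB.T @ LXXL_inv @ LB
        E = Yc.T @ R @ Yc
        trH, trE = np.trace(H), np.trace(E)
        df1, df2 = d, d * dfe
        F = (trH / df1) / (trE / df2) if trE > 0 else np.inf
        p = float(sps.f.sf(F, df1, df2))
        eps = 1.0 if d == 1 else _epsilon_from_error(E, d)
        p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps))
        peta = trH / (trH + trE) if (trH + trE) > 0 else np.nan
        rows.append(
            {
                "effect": name,
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
                "gg_epsilon": eps,
                "p_gg": p_gg,
                "partial_eta2": peta,
                "n_subjects": n,
            }
        )
    return AncovaTable(rows)


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up: (rejection mask, critical p).

    Rejects the hypotheses with p ≤ p_(k) where k is the largest rank with
    p_(k) ≤ k·q/M; critical_p = p_(k), or 0 when nothing is rejected.
    """
    p = np.asarray(pvals, dtype=np.float64).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * q / m)
    if not below.any():
        return np.zeros(m, dtype=bool), 0.0
    k = int(np.max(np.nonzero(below)[0]))
    critical = float(ranked[k])
    return p <= critical, critical


def _t_grid(
    values: np.ndarray,
    is_high: np.ndarray,
    equal_var: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample t per trailing cell; positive t = high mean larger."""
    hi = values[is_high]
    lo = values[~is_high]
    res = sps.ttest_ind(hi, lo, axis=0, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=np.float64)
    p = np.asarray(res.pvalue, dtype=np.float64)
    # identical samples give 0/0; define t=0, p=1
    bad = ~np.isfinite(t)
    t[bad] = 0.0
    p[bad] = 1.0
    return t, p


def posthoc_ttests(
    binned,
    groups: pd.DataFrame,
    q: float = 0.05,
    equal_var: bool = True,
) -> PosthocGrid:
    """Electrode × scale-bin two-sample t grid with BH-FDR at level q.

    ``groups`` maps subject → group ('high'/'low'); Student's pooled
    two-sample t by default (Welch via ``equal_var=False``).
    """
    gmap = groups.set_index("subject")["group"] if isinstance(groups, pd.DataFrame) else groups
    is_high = np.array([gmap[s] == "high" for s in binned.subjects])
    if is_high.sum() < 2 or (~is_high).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    t, p = _t_grid(binned.values, is_high, equal_var)
    mask, crit = bh_fdr(p, q)
    return PosthocGrid(
        t=t,
        p=p,
        q_mask=mask.reshape(p.shape),
        critical_p=crit,
        labels=list(binned.labels),
        columns=list(range(1, binned.values.shape[2] + 1)),
        column_name="scale_bin",
    )


def psd_pointwise_tests(
    psd,
    groups: pd.DataFrame,
    q: float = 0.05,
    equal_var: bool = True,
) -> PosthocGrid:
    """Electrode × frequency-point t grid with BH-FDR over all cells."""
    gmap = groups.set_index("subject")["group"] if isinstance(groups, pd.DataFrame) else groups
    is_high = np.array([gmap[s] == "high" for s in psd.subjects])
    if is_high.sum() < 2 or (~is_high).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    t, p = _t_grid(psd.values, is_high, equal_var)
    mask, crit = bh_fdr(p, q)
    return PosthocGrid(
        t=t,
        p=p,
        q_mask=mask.reshape(p.shape),
        critical_p=crit,
        labels=list(psd.labels),
        columns=[float(f) for f in psd.freqs],
        column_name="freq_hz",
    )
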