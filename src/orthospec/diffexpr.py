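"""Per-protein quasi-Poisson differential abundance with BH FDR control.

For every joint ortholog row the 2 x species x treatment spectral counts are
modelled with a Poisson log-link regression

    log E[y] = beta0 + beta_species * I[sorghum] + beta_treatment * I[WD]

fitted by iteratively reweighted least squares.  Overdispersion is absorbed
through the quasi-likelihood dispersion phi = Pearson X^2 / (n - p), which
scales the Wald standard errors by sqrt(phi); two-sided p-values use the t
reference with n - p degrees of freedom (the conventional quasi-likelihood
choice).  Species and treatment p-values are each adjusted across proteins
with the Benjamini-Hochberg step-up rule, and a protein is called
significant on a term when its q-value is strictly below alpha (default
0.05).  Per-species log2 fold changes are computed descriptively from the
replicate means with a pseudocount, since the additive model carries a
single treatment coefficient but the report carries one fold change per
species.

Rows are first filtered on a minimum information criterion of 10 total
spectra (boundary inclusive, summed over both species and all samples).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .countmerge import JointCountMatrix, JointRow

__all__ = [
    "QPFit",
    "DEFAULT_ALPHA",
    "DEFAULT_MIN_SPECTRA",
    "DEFAULT_PSEUDOCOUNT",
    "filter_min_spectra",
    "build_design",
    "quasipoisson_fit",
    "bh_adjust",
    "log2_fold_changes",
    "fit_all",
    "classify",
]

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_SPECTRA = 10
DEFAULT_PSEUDOCOUNT = 0.5

_ETA_CLIP = 30.0
_PHI_SE_FLOOR = 1e-12


@dataclass
class QPFit:
    """Quasi-Poisson fit summary for one protein."""

    beta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    dispersion: float
    converged: bool
    iterations: int
    df_resid: int
    separation: bool
    columns: tuple[str, ...] = ("intercept", "species", "treatment")


def filter_min_spectra(
    matrix: JointCountMatrix, min_total: int = DEFAULT_MIN_SPECTRA
) -> JointCountMatrix:
    """Keep rows whose grand spectral total (both species) is >= min_total."""
    kept = [r for r in matrix.rows if r.total >= min_total]
    return JointCountMatrix(
        rows=kept,
        maize_samples=matrix.maize_samples,
        sorghum_samples=matrix.sorghum_samples,
        stats=matrix.stats,
    )


def build_design(
    design: pd.DataFrame,
    maize_samples: list[str],
    sorghum_samples: list[str],
    interaction: bool = False,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Design matrix for the concatenated (maize then sorghum) count vector.

    Columns: intercept, I[sorghum], I[water deficit], and optionally the
    species x treatment interaction.
    """
    meta = design.set_index("sample_id")
    ordered = list(maize_samples) + list(sorghum_samples)
    missing = [s for s in ordered if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    species = np.array(
        [1.0 if meta.loc[s, "species"] == "sorghum" else 0.0 for s in ordered]
    )
    treatment = np.array(
        [1.0 if meta.loc[s, "treatment"] == "WD" else 0.0 for s in ordered]
    )
    cols = [np.ones(len(ordered)), species, treatment]
    names = ["intercept", "species", "treatment"]
    if interaction:
        cols.append(species * treatment)
        names.append("species:treatment")
    return np.column_stack(cols), tuple(names)


def quasipoisson_fit(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> QPFit:
    """Poisson log-link IRLS with quasi-likelihood dispersion.

    Coefficients are the Poisson maximum-likelihood estimates (tolerance
    ``tol`` on the coefficient change, at most ``max_iter`` iterations);
    the dispersion is the Pearson statistic over the residual degrees of
    freedom, and standard errors scale with sqrt(dispersion).  A complete
    separation (an all-zero design cell) is not patched with ad-hoc
    constants; the fit is flagged instead.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("y must be a vector with one row of X per element")
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    n, p = X.shape
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    mu = np.clip((y + y.mean()) / 2.0, 1e-4, None)
    eta = np.log(mu)
    beta = np.zeros(p)
    converged = False
    iterations = 0
    A = np.eye(p)
    for iterations in range(1, max_iter + 1):
        W = mu
        z = (eta - off) + (y - mu) / mu
        XtW = X.T * W
        A = XtW @ X
        b = XtW @ z
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta_new, *_ = np.linalg.lstsq(A, b, rcond=None)
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        eta = np.clip(X @ beta + off, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        if delta < tol:
            converged = True
            break

    df_resid = n - p
    pearson = float(np.sum((y - mu) ** 2 / np.clip(mu, 1e-10, None)))
    phi = pearson / df_resid if df_resid > 0 else math.nan

    try:
        cov_unscaled = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        cov_unscaled = np.linalg.pinv(A)
    diag = np.clip(np.diag(cov_unscaled), 0.0, None)
    se = np.sqrt(max(phi, _PHI_SE_FLOOR) * diag) if df_resid > 0 else np.full(p, np.nan)

    separation = bool(np.any(np.abs(beta) >= _ETA_CLIP - 1e-6) or np.any(se > 1e3))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    if df_resid > 0:
        pvalues = 2.0 * sps.t.sf(np.abs(tvals), df=df_resid)
        pvalues = np.where(np.isnan(tvals), np.nan, pvalues)
    else:
        pvalues = np.full(p, np.nan)

    return QPFit(
        beta=beta,
        se=se,
        pvalues=pvalues,
        dispersion=phi,
        converged=converged,
        iterations=iterations,
        df_resid=df_resid,
        separation=separation,
        columns=tuple(f"b{i}" for i in range(p)),
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q(i) = min over j >= i of m * p(j) / j on the sorted scale, mapped back
    to the input order and clipped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be a vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def log2_fold_changes(
    row: JointRow,
    design: pd.DataFrame,
    maize_samples: list[str],
    sorghum_samples: list[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[float, float]:
    """Descriptive per-species log2 fold changes WD vs WW.

    Per species: log2((mean_WD + pseudocount) / (mean_WW + pseudocount)) over
    that species' replicate counts.  A species with no identified counts is
    reported as NaN (undefined), not zero.
    """
    meta = design.set_index("sample_id")

    def one(samples: list[str], counts: np.ndarray, present: bool) -> float:
        if not present:
            return math.nan
        wd = np.array([meta.loc[s, "treatment"] == "WD" for s in samples])
        mean_wd = counts[wd].mean() if wd.any() else math.nan
        mean_ww = counts[~wd].mean() if (~wd).any() else math.nan
        num = mean_wd + pseudocount
        den = mean_ww + pseudocount
        if den <= 0 or num <= 0:
            return math.nan
        return float(np.log2(num / den))

    return (
        one(maize_samples, row.maize_counts, row.has_maize),
        one(sorghum_samples, row.sorghum_counts, row.has_sorghum),
    )


def fit_all(
    matrix: JointCountMatrix,
    design: pd.DataFrame,
    offset: str = "none",
    interaction: bool = False,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Fit the quasi-Poisson model to every row of the joint matrix.

    ``offset='total'`` adds a log library-size offset (per-sample column
    totals of the matrix); the default applies no normalisation.  Returns one
    row per protein with coefficients, dispersion, per-term p-values and the
    descriptive per-species fold changes.
    """
    if offset not in ("none", "total"):
        raise ValueError("offset must be 'none' or 'total'")
    X, names = build_design(
        design, matrix.maize_samples, matrix.sorghum_samples, interaction
    )
    off = None
    if offset == "total":
        m_tot, s_tot = matrix.totals()
        lib = np.concatenate([m_tot, s_tot]).astype(float)
        off = np.log(np.clip(lib, 1.0, None))

    i_species = names.index("species")
    i_treat = names.index("treatment")
    meta = design.set_index("sample_id")
    wd_m = np.array(
        [meta.loc[s, "treatment"] == "WD" for s in matrix.maize_samples]
    )
    wd_s = np.array(
        [meta.loc[s, "treatment"] == "WD" for s in matrix.sorghum_samples]
    )

    records = []
    for row in matrix.rows:
        y = np.concatenate([row.maize_counts, row.sorghum_counts]).astype(float)
        fit = quasipoisson_fit(y, X, offset=off)

        def lfc(counts: np.ndarray, wd: np.ndarray, present: bool) -> float:
            if not present:
                return math.nan
            num = counts[wd].mean() + pseudocount
            den = counts[~wd].mean() + pseudocount
            return float(np.log2(num / den)) if num > 0 and den > 0 else math.nan

        m_acc, s_acc = row.key()
        records.append(
            {
                "maize_accession": m_acc,
                "sorghum_accession": s_acc,
                "description": "",
                "log2fc_maize": lfc(row.maize_counts, wd_m, row.has_maize),
                "log2fc_sorghum": lfc(row.sorghum_counts, wd_s, row.has_sorghum),
                "beta_intercept": fit.beta[0],
                "beta_species": fit.beta[i_species],
                "beta_treatment": fit.beta[i_treat],
                "se_species": fit.se[i_species],
                "se_treatment": fit.se[i_treat],
                "p_species": fit.pvalues[i_species],
                "p_treatment": fit.pvalues[i_treat],
                "dispersion": fit.dispersion,
                "converged": fit.converged,
                "separation": fit.separation,
                "one_sided": row.one_sided,
                "total_spectra": row.total,
            }
        )
    return pd.DataFrame(records)


def classify(fits: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """BH-adjust each term across proteins and flag significance.

    q-values are computed separately for the species and treatment columns;
    a term is significant when q < alpha (strict).  Proteins whose p-value is
    undefined (degenerate fit) are excluded from the adjustment and never
    called significant.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    out = fits.copy()
    for term in ("species", "treatment"):
        pcol, qcol = f"p_{term}", f"q_{term}"
        p = out[pcol].to_numpy(dtype=float)
        q = np.full_like(p, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            q[ok] = bh_adjust(p[ok])
        out[qcol] = q
        out[f"significant_{term}"] = (q < alpha) & ok
    out["significant_both"] = out["significant_species"] & out["significant_treatment"]
    return out
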