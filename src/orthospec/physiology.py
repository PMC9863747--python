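"""Drought-physiology computations: leaf hydration, proline, group letters.

Relative water content (RWC) indexes leaf hydration from fresh, dry, and
turgid weights as 100 * (FW - DW) / (TW - DW).  Free proline is quantified
by the acid-ninhydrin assay: absorbance at 520 nm is converted to a toluene
phase concentration through an L-proline standard curve, then scaled by the
assay geometry (extract, aliquot and toluene volumes, tissue mass) to
micromoles per gram fresh weight:

    content = (A520 - intercept)/slope * V_toluene * (V_extract/V_aliquot) / m_tissue

Group comparisons use one-way ANOVA with Tukey-Kramer honest significant
differences (studentised range, unequal-n form); groups that are not
significantly different share a compact-display letter.
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthdata import (
    PROLINE_ALIQUOT_VOLUME,
    PROLINE_EXTRACT_VOLUME,
    PROLINE_TISSUE_MASS,
    PROLINE_TOLUENE_VOLUME,
)

__all__ = [
    "StandardCurve",
    "AnovaTukeyResult",
    "rwc",
    "fit_standard_curve",
    "proline_content",
    "anova_tukey",
    "compute_physiology",
    "summarize_groups",
]


def rwc(FW: float, DW: float, TW: float) -> float:
    """Relative water content (%) = 100 * (FW - DW) / (TW - DW).

    Requires TW > DW; an FW outside [DW, TW] is physically implausible and
    triggers a warning, but the value is still returned.
    """
    if TW <= DW:
        raise ValueError(f"turgid weight must exceed dry weight (TW={TW}, DW={DW})")
    if FW < DW or FW > TW:
        warnings.warn(
            f"fresh weight {FW} outside [DW={DW}, TW={TW}]; RWC outside [0, 100]",
            stacklevel=2,
        )
    return 100.0 * (FW - DW) / (TW - DW)


@dataclass(frozen=True)
class StandardCurve:
    """OLS line absorbance = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    conc_min: float
    conc_max: float
    n_standards: int


def fit_standard_curve(
    standards: pd.DataFrame | Sequence[tuple[float, float]],
) -> StandardCurve:
    """Fit the L-proline standard curve by ordinary least squares.

    ``standards`` is a (concentration, absorbance) table; at least three
    distinct concentrations are required.  A coefficient of determination
    below 0.98 triggers a warning (a poor standard curve).
    """
    if isinstance(standards, pd.DataFrame):
        conc = standards["concentration"].to_numpy(dtype=float)
        ab = standards["absorbance"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(standards), dtype=float)
        if arr.size == 0:
            raise ValueError("no standards provided")
        conc, ab = arr[:, 0], arr[:, 1]
    if len(np.unique(conc)) < 3:
        raise ValueError("need at least 3 distinct standard concentrations")
    res = sps.linregress(conc, ab)
    r2 = float(res.rvalue**2)
    if r2 < 0.98:
        warnings.warn(
            f"standard curve r^2 = {r2:.4f} < 0.98; check the standards",
            stacklevel=2,
        )
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        conc_min=float(conc.min()),
        conc_max=float(conc.max()),
        n_standards=len(conc),
    )


def proline_content(
    A520: float,
    curve: StandardCurve,
    extract_volume: float = PROLINE_EXTRACT_VOLUME,
    aliquot_volume: float = PROLINE_ALIQUOT_VOLUME,
    toluene_volume: float = PROLINE_TOLUENE_VOLUME,
    tissue_mass: float = PROLINE_TISSUE_MASS,
) -> float:
    """Proline (umol per g fresh weight) from a 520 nm absorbance.

    The toluene-phase concentration (A520 - intercept)/slope is scaled by the
    toluene volume, the extract-to-aliquot dilution, and the tissue mass.
    An absorbance below the curve intercept is clipped to zero content with a
    warning.
    """
    if curve.slope == 0:
        raise ValueError("standard curve slope is zero")
    if tissue_mass <= 0 or aliquot_volume <= 0:
        raise ValueError("tissue_mass and aliquot_volume must be positive")
    conc = (A520 - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(
            f"A520={A520} below the curve intercept; clipping proline to 0",
            stacklevel=2,
        )
        conc = 0.0
    return conc * toluene_volume * (extract_volume / aliquot_volume) / tissue_mass


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    letters: dict[str, str]
    pairwise: pd.DataFrame
    degenerate: bool = False


def _letter_labels(n: int) -> list[str]:
    letters = list(string.ascii_lowercase)
    if n <= len(letters):
        return letters[:n]
    return letters + [a + b for a in letters for b in letters][: n - len(letters)]


def _assign_letters(
    labels: list[str],
    means: dict[str, float],
    nonsig_pairs: set[tuple[str, str]],
) -> dict[str, str]:
    """Compact letter display: one letter per maximal clique of the
    non-significance graph, cliques ordered by descending group mean."""
    G = nx.Graph()
    G.add_nodes_from(sorted(labels, key=lambda l: (-means[l], l)))
    for a, b in nonsig_pairs:
        G.add_edge(a, b)
    cliques = [sorted(c) for c in nx.find_cliques(G)]
    cliques.sort(key=lambda c: (-max(means[l] for l in c), tuple(c)))
    assigned: dict[str, list[str]] = {l: [] for l in labels}
    for letter, clique in zip(_letter_labels(len(cliques)), cliques):
        for l in clique:
            assigned[l].append(letter)
    return {l: "".join(sorted(v)) for l, v in assigned.items()}


def anova_tukey(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaTukeyResult:
    """One-way ANOVA plus Tukey-Kramer pairwise comparisons with letters.

    Groups sharing no significant pairwise difference share a letter.  With
    zero within-group variance everywhere the studentised-range test is
    undefined; the result is flagged degenerate and letters fall back to
    grouping by exact mean equality.
    """
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    data = {l: np.asarray(groups[l], dtype=float) for l in labels}
    if any(len(v) < 2 for v in data.values()):
        raise ValueError("each group needs at least 2 values")
    means = {l: float(v.mean()) for l, v in data.items()}

    if all(float(v.var(ddof=1)) == 0.0 for v in data.values()):
        # No residual variance: every pairwise test is degenerate.
        nonsig = {
            (a, b)
            for i, a in enumerate(labels)
            for b in labels[i + 1 :]
            if means[a] == means[b]
        }
        letters = _assign_letters(labels, means, nonsig)
        pairwise = pd.DataFrame(
            [
                {"group_a": a, "group_b": b, "p_value": math.nan,
                 "significant": means[a] != means[b]}
                for i, a in enumerate(labels)
                for b in labels[i + 1 :]
            ]
        )
        return AnovaTukeyResult(
            f_statistic=math.nan,
            p_value=math.nan,
            letters=letters,
            pairwise=pairwise,
            degenerate=True,
        )

    f_stat, p_val = sps.f_oneway(*(data[l] for l in labels))
    tk = sps.tukey_hsd(*(data[l] for l in labels))
    nonsig: set[tuple[str, str]] = set()
    rows = []
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            p = float(tk.pvalue[i, j])
            sig = p < alpha
            if not sig:
                nonsig.add((a, b))
            rows.append(
                {"group_a": a, "group_b": b, "p_value": p, "significant": sig}
            )
    letters = _assign_letters(labels, means, nonsig)
    return AnovaTukeyResult(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        letters=letters,
        pairwise=pd.DataFrame(rows),
        degenerate=False,
    )


def compute_physiology(
    records: pd.DataFrame,
    standards: pd.DataFrame,
) -> tuple[pd.DataFrame, StandardCurve]:
    """Per-sample RWC and proline from a physiology table plus standards.

    ``records`` needs sample_id, species, treatment, FW, DW, TW, A520 and
    optionally tissue_mass (default assay geometry otherwise).
    """
    curve = fit_standard_curve(standards)
    out = records.copy()
    out["rwc"] = [
        rwc(r.FW, r.DW, r.TW) for r in records.itertuples()
    ]
    masses = (
        records["tissue_mass"]
        if "tissue_mass" in records
        else pd.Series(PROLINE_TISSUE_MASS, index=records.index)
    )
    out["proline"] = [
        proline_content(a, curve, tissue_mass=m)
        for a, m in zip(records["A520"], masses)
    ]
    return out, curve


def summarize_groups(
    per_sample: pd.DataFrame,
    metrics: Sequence[str] = ("rwc", "proline"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Species-by-treatment group means, SEs and Tukey-Kramer letters."""
    per_sample = per_sample.copy()
    per_sample["group"] = per_sample["species"] + "_" + per_sample["treatment"]
    rows = []
    for metric in metrics:
        groups = {
            g: v[metric].to_numpy(dtype=float)
            for g, v in per_sample.groupby("group")
        }
        res = anova_tukey(groups, alpha=alpha)
        for g in sorted(groups):
            vals = groups[g]
            rows.append(
                {
                    "metric": metric,
                    "group": g,
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "se": float(vals.std(ddof=1) / math.sqrt(len(vals))),
                    "letter": res.letters[g],
                    "anova_F": res.f_statistic,
                    "anova_p": res.p_value,
                }
            )
    return pd.DataFrame(rows)
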