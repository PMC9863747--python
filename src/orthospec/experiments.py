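"""Repeatable simulation studies of the differential-abundance pipeline.

These harnesses generate synthetic two-species experiments with known truth,
push them through the full ortholog-mapping -> row-alignment -> filtering ->
quasi-Poisson -> BH chain, and score the calls against the planted effects.
They back both the test suite's operating-characteristic checks and the
result-reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .countmerge import align_rows, merge_split_rows
from .diffexpr import classify, filter_min_spectra, fit_all
from .orthomap import best_hits, combine_directions, hits_from_frame, split_directions
from .synthdata import (
    SimConfig,
    generate_alignment_table,
    generate_count_tables,
    generate_protein_dbs,
)

__all__ = [
    "run_synthetic_de",
    "treatment_fdr_experiment",
    "beta_recovery_experiment",
]


def run_synthetic_de(
    cfg: SimConfig, alpha: float = 0.05, min_spectra: int = 10
) -> pd.DataFrame:
    """One synthetic experiment end to end; returns classified results with
    the planted truth joined on (``true_de``, ``true_beta_treatment``)."""
    maize_db, sorghum_db, truth = generate_protein_dbs(cfg)
    align = generate_alignment_table(truth, cfg)
    fwd, rev = split_directions(
        hits_from_frame(align), set(maize_db), set(sorghum_db)
    )
    omap = combine_directions(best_hits(rev), best_hits(fwd))
    counts_m, counts_s, design = generate_count_tables(truth, cfg)
    matrix, _ = align_rows(counts_m, counts_s, omap)
    matrix = merge_split_rows(matrix, omap)
    matrix = filter_min_spectra(matrix, min_spectra)
    res = classify(fit_all(matrix, design), alpha=alpha)

    de_by_maize = {m: bool(f) for (m, _s), f in zip(truth.ortholog_pairs, truth.de_flags)}
    bt_by_maize = {
        m: float(b) for (m, _s), b in zip(truth.ortholog_pairs, truth.true_betas[:, 2])
    }
    res["true_de"] = res["maize_accession"].map(de_by_maize)
    res["true_beta_treatment"] = res["maize_accession"].map(bt_by_maize)
    return res


@dataclass
class FdrExperimentResult:
    fdp_per_rep: np.ndarray  # false-discovery proportion, one per repetition
    n_discoveries: np.ndarray
    n_false: np.ndarray

    @property
    def mean_fdp(self) -> float:
        return float(self.fdp_per_rep.mean())

    @property
    def mc_se(self) -> float:
        n = len(self.fdp_per_rep)
        return float(self.fdp_per_rep.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0


def treatment_fdr_experiment(
    seed: int,
    n_reps: int = 20,
    n_proteins: int = 2000,
    frac_de: float = 0.1,
    log2fc: float = 2.0,
    dispersion: float = 2.0,
    n_replicates: int = 5,
    alpha: float = 0.05,
) -> FdrExperimentResult:
    """Empirical FDR of the treatment-term calls over seeded repetitions.

    Each repetition simulates ``n_proteins`` ortholog pairs (a ``frac_de``
    fraction carrying a treatment log2 fold change of ``log2fc``, the rest
    null) with quasi-Poisson dispersion ``dispersion`` and ``n_replicates``
    samples per species-by-treatment cell, then scores the fraction of true
    nulls among BH q < alpha treatment discoveries.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    fdps, n_disc, n_false = [], [], []
    for s in rep_seeds:
        cfg = SimConfig(
            n_ortholog_pairs=n_proteins,
            n_paralog_split_pairs=0,
            n_orphans_per_species=0,
            n_replicates=n_replicates,
            frac_treatment_de=frac_de,
            treatment_log2fc=log2fc,
            dispersion=dispersion,
            seed=int(s),
        )
        res = run_synthetic_de(cfg, alpha=alpha)
        disc = res[res["significant_treatment"]]
        false = int((~disc["true_de"].astype(bool)).sum())
        d = len(disc)
        fdps.append(false / d if d > 0 else 0.0)
        n_disc.append(d)
        n_false.append(false)
    return FdrExperimentResult(
        fdp_per_rep=np.array(fdps),
        n_discoveries=np.array(n_disc),
        n_false=np.array(n_false),
    )


def beta_recovery_experiment(
    seed: int,
    n_proteins: int = 500,
    frac_de: float = 0.5,
    log2fc: float = 2.0,
    dispersion: float = 2.0,
    n_replicates: int = 5,
) -> pd.DataFrame:
    """Treatment-coefficient recovery on one simulated experiment.

    Returns the classified results restricted to the planted differentially
    abundant pairs, whose true treatment coefficient is log(2) * log2fc on
    the natural-log scale.
    """
    cfg = SimConfig(
        n_ortholog_pairs=n_proteins,
        n_paralog_split_pairs=0,
        n_orphans_per_species=0,
        n_replicates=n_replicates,
        frac_treatment_de=frac_de,
        treatment_log2fc=log2fc,
        dispersion=dispersion,
        seed=seed,
    )
    res = run_synthetic_de(cfg)
    return res[res["true_de"].astype(bool)].reset_index(drop=True)
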