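"""Synthetic two-species spectral-count experiment generator.

Emulates the study design that the downstream pipeline expects: two grass
species (maize and sorghum) sampled under well-watered (WW) and water-deficit
(WD) treatments with five biological replicates per species-by-treatment cell.
The generator emits every input the pipeline consumes -- paired protein FASTA
databases, a cross-species alignment table in the 12-column tabular
convention, per-species spectral-count tables with a sample-metadata table,
and leaf physiology tables -- together with the ground truth used to plant
them, so every downstream stage can be tested without external data.

Spectral counts are drawn from a negative binomial parameterised to have the
quasi-Poisson variance ``phi * mu``; the log-scale mean model is

    log mu = beta0 + beta_species * I[sorghum] + beta_treatment * I[WD]

with ``beta_treatment = log(2) * treatment_log2fc`` for the planted
differentially abundant pairs and 0 otherwise.

Paralog-split pairs emulate the situation where one species' spectra and the
other species' spectra for an orthologous pair land in different rows of the
aligned matrix (e.g. a paralog family collapsed differently by the protein
assembler in each species): each split pair carries an extra maize paralog
accession, the maize->sorghum best hit departs from the count-bearing maize
accession while the sorghum->maize best hit points at the paralog, so row
alignment produces two one-sided rows that only merging rejoins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PhysioSim",
    "generate_protein_dbs",
    "generate_alignment_table",
    "generate_count_tables",
    "generate_physio_data",
    "write_fasta",
    "write_alignment_table",
    "write_count_table",
]

LN2 = math.log(2.0)

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")

# Sub-stream identifiers so each generator function is reproducible from the
# single cfg.seed regardless of call order.
_STREAM_DBS = 11
_STREAM_ALIGN = 23
_STREAM_COUNTS = 37
_STREAM_PHYSIO = 53

SPECIES_MAIZE = "maize"
SPECIES_SORGHUM = "sorghum"
TREATMENTS = ("WW", "WD")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated two-species experiment.

    Defaults mirror the study design: 5 replicates per species-by-treatment
    cell, overdispersed counts (phi = 2), a modest fraction of pairs with a
    treatment effect of 2 on the log2 scale, and true-ortholog bit scores
    comfortably above the mapping floor of 50.
    """

    n_ortholog_pairs: int = 500
    n_paralog_split_pairs: int = 0
    n_orphans_per_species: int = 50
    n_replicates: int = 5
    frac_treatment_de: float = 0.1
    treatment_log2fc: float = 2.0
    species_log2fc_sd: float = 0.5
    baseline_mean: float = 8.0
    dispersion: float = 2.0
    bitscore_true_range: tuple[float, float] = (80.0, 300.0)
    bitscore_orphan_max: float = 45.0
    seed: int = 0

    @property
    def n_pairs_total(self) -> int:
        return self.n_ortholog_pairs + self.n_paralog_split_pairs

    def validate(self) -> None:
        if self.n_ortholog_pairs < 0 or self.n_paralog_split_pairs < 0:
            raise ValueError("pair counts must be non-negative")
        if self.n_orphans_per_species < 0:
            raise ValueError("n_orphans_per_species must be non-negative")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be at least 2")
        if not 0.0 <= self.frac_treatment_de <= 1.0:
            raise ValueError("frac_treatment_de must lie in [0, 1]")
        if self.species_log2fc_sd < 0:
            raise ValueError("species_log2fc_sd must be non-negative")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion < 1:
            raise ValueError("dispersion (variance inflation) must be >= 1")
        lo, hi = self.bitscore_true_range
        if not (lo <= hi):
            raise ValueError("bitscore_true_range must be (lo, hi) with lo <= hi")
        if not (self.bitscore_orphan_max < 50.0 <= lo):
            raise ValueError(
                "require bitscore_orphan_max < 50 <= bitscore_true_range lo"
            )


@dataclass
class GroundTruth:
    """What was planted: ortholog pairs, their effects, and the decoys.

    ``ortholog_pairs`` lists (maize_accession, sorghum_accession) using the
    count-bearing accessions; for paralog-split pairs the extra maize paralog
    accession (present in the FASTA and alignment table but carrying no
    counts) is recorded in ``split_paralogs``.
    """

    ortholog_pairs: list[tuple[str, str]]
    de_flags: np.ndarray
    true_betas: np.ndarray  # (n_pairs, 3): beta0, beta_species, beta_treatment
    split_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    split_paralogs: dict[str, str] = field(default_factory=dict)  # maize acc -> paralog acc
    maize_orphans: list[str] = field(default_factory=list)
    sorghum_orphans: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.ortholog_pairs)

    def de_lookup(self) -> dict[tuple[str, str], bool]:
        return {
            pair: bool(flag)
            for pair, flag in zip(self.ortholog_pairs, self.de_flags)
        }


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _AA[rng.integers(0, len(_AA), size=length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    n_mut = max(1, int(round(rate * len(arr))))
    pos = rng.choice(len(arr), size=min(n_mut, len(arr)), replace=False)
    arr[pos] = _AA[rng.integers(0, len(_AA), size=len(pos))]
    return arr.tobytes().decode("ascii")


def _maize_accessions(rng: np.random.Generator, n: int) -> list[str]:
    nums = rng.choice(900_000, size=n, replace=False) + 100_000
    return [f"GRMZM2G{int(v):06d}_P01" for v in nums]


def _sorghum_accessions(rng: np.random.Generator, n: int) -> list[str]:
    loci = rng.choice(900_000, size=n, replace=False) + 100_000
    chroms = rng.integers(1, 11, size=n)
    return [f"Sobic.{int(c):03d}G{int(v):06d}.1.p" for c, v in zip(chroms, loci)]


def generate_protein_dbs(
    cfg: SimConfig,
) -> tuple[dict[str, str], dict[str, str], GroundTruth]:
    """Generate the paired protein databases and the planted ground truth.

    Returns (maize_db, sorghum_db, truth) where each database is an ordered
    mapping accession -> amino-acid sequence.  Ortholog partners share
    recognisably similar but non-identical sequences; orphans appear in one
    species only; each paralog-split pair adds one extra maize paralog.
    """
    cfg.validate()
    rng = _rng(cfg.seed, _STREAM_DBS)

    n_pairs = cfg.n_pairs_total
    n_orph = cfg.n_orphans_per_species
    maize_accs = _maize_accessions(rng, n_pairs + cfg.n_paralog_split_pairs + n_orph)
    sorghum_accs = _sorghum_accessions(rng, n_pairs + n_orph)

    pair_maize = maize_accs[:n_pairs]
    paralog_accs = maize_accs[n_pairs : n_pairs + cfg.n_paralog_split_pairs]
    maize_orphans = maize_accs[n_pairs + cfg.n_paralog_split_pairs :]
    pair_sorghum = sorghum_accs[:n_pairs]
    sorghum_orphans = sorghum_accs[n_pairs:]

    # Split pairs are the last n_paralog_split_pairs of the pair list.
    split_flags = np.zeros(n_pairs, dtype=bool)
    if cfg.n_paralog_split_pairs:
        split_flags[-cfg.n_paralog_split_pairs :] = True
    split_paralogs = {
        pair_maize[i]: paralog_accs[k]
        for k, i in enumerate(np.flatnonzero(split_flags))
    }

    maize_db: dict[str, str] = {}
    sorghum_db: dict[str, str] = {}
    for i in range(n_pairs):
        length = int(rng.integers(120, 400))
        seq = _random_sequence(rng, length)
        maize_db[pair_maize[i]] = seq
        sorghum_db[pair_sorghum[i]] = _mutate(rng, seq, 0.12)
        if split_flags[i]:
            split_acc = split_paralogs[pair_maize[i]]
            maize_db[split_acc] = _mutate(rng, seq, 0.06)
    for acc in maize_orphans:
        maize_db[acc] = _random_sequence(rng, int(rng.integers(120, 400)))
    for acc in sorghum_orphans:
        sorghum_db[acc] = _random_sequence(rng, int(rng.integers(120, 400)))

    # Effects on the natural-log scale.
    beta0 = np.full(n_pairs, math.log(cfg.baseline_mean))
    beta_species = rng.normal(0.0, cfg.species_log2fc_sd * LN2, size=n_pairs)
    n_de = int(round(cfg.frac_treatment_de * n_pairs))
    de_flags = np.zeros(n_pairs, dtype=bool)
    if n_de:
        de_flags[rng.choice(n_pairs, size=n_de, replace=False)] = True
    beta_treatment = np.where(de_flags, LN2 * cfg.treatment_log2fc, 0.0)

    truth = GroundTruth(
        ortholog_pairs=list(zip(pair_maize, pair_sorghum)),
        de_flags=de_flags,
        true_betas=np.column_stack([beta0, beta_species, beta_treatment]),
        split_flags=split_flags,
        split_paralogs=split_paralogs,
        maize_orphans=list(maize_orphans),
        sorghum_orphans=list(sorghum_orphans),
    )
    return maize_db, sorghum_db, truth


_BLAST_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


def _hit_row(
    rng: np.random.Generator,
    query: str,
    subject: str,
    bitscore: float,
    pident_range: tuple[float, float] = (55.0, 95.0),
) -> dict:
    length = int(rng.integers(80, 400))
    pident = float(np.round(rng.uniform(*pident_range), 2))
    mismatch = int(round(length * (100.0 - pident) / 100.0))
    return {
        "qseqid": query,
        "sseqid": subject,
        "pident": pident,
        "length": length,
        "mismatch": mismatch,
        "gapopen": int(rng.integers(0, 6)),
        "qstart": 1,
        "qend": length,
        "sstart": 1,
        "send": length,
        "evalue": float(f"{10.0 ** (-bitscore / 10.0):.3g}"),
        "bitscore": float(np.round(bitscore, 1)),
    }


def generate_alignment_table(
    truth: GroundTruth,
    cfg: SimConfig,
    include_decoys: bool = False,
) -> pd.DataFrame:
    """Emit cross-species alignment hits (both query directions).

    Each true pair receives one maize->sorghum and one sorghum->maize hit
    with bit scores drawn from ``cfg.bitscore_true_range``; for paralog-split
    pairs the reverse hit targets the maize paralog instead of the
    count-bearing accession.  Orphans receive either no hit or a
    sub-threshold hit.  With ``include_decoys`` each direction may add a
    strictly lower-scoring second-best hit.
    """
    cfg.validate()
    rng = _rng(cfg.seed, _STREAM_ALIGN)
    lo, hi = cfg.bitscore_true_range
    rows: list[dict] = []

    sorghum_pool = [s for _, s in truth.ortholog_pairs] or ["Sobic.001G000001.1.p"]
    maize_pool = [m for m, _ in truth.ortholog_pairs] or ["GRMZM2G000001_P01"]

    for i, (m_acc, s_acc) in enumerate(truth.ortholog_pairs):
        fwd_bits = rng.uniform(lo, hi)
        rev_bits = rng.uniform(lo, hi)
        rev_subject = (
            truth.split_paralogs[m_acc] if truth.split_flags[i] else m_acc
        )
        rows.append(_hit_row(rng, m_acc, s_acc, fwd_bits))
        rows.append(_hit_row(rng, s_acc, rev_subject, rev_bits))
        if include_decoys:
            if rng.random() < 0.5 and len(sorghum_pool) > 1:
                decoy = sorghum_pool[int(rng.integers(len(sorghum_pool)))]
                if decoy != s_acc:
                    rows.append(
                        _hit_row(rng, m_acc, decoy, fwd_bits - rng.uniform(5, 25))
                    )
            if rng.random() < 0.5 and len(maize_pool) > 1:
                decoy = maize_pool[int(rng.integers(len(maize_pool)))]
                if decoy != m_acc:
                    rows.append(
                        _hit_row(rng, s_acc, decoy, rev_bits - rng.uniform(5, 25))
                    )

    for acc in truth.maize_orphans:
        if rng.random() < 0.5:
            subject = sorghum_pool[int(rng.integers(len(sorghum_pool)))]
            bits = rng.uniform(20.0, cfg.bitscore_orphan_max)
            rows.append(_hit_row(rng, acc, subject, bits, (25.0, 50.0)))
    for acc in truth.sorghum_orphans:
        if rng.random() < 0.5:
            subject = maize_pool[int(rng.integers(len(maize_pool)))]
            bits = rng.uniform(20.0, cfg.bitscore_orphan_max)
            rows.append(_hit_row(rng, acc, subject, bits, (25.0, 50.0)))

    return pd.DataFrame(rows, columns=_BLAST_COLUMNS)


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, phi: float, size: tuple
) -> np.ndarray:
    """Counts with mean mu and quasi-Poisson variance phi * mu.

    Negative binomial with size r = mu / (phi - 1) and success probability
    1/phi has mean mu and variance phi * mu; phi = 1 degenerates to Poisson.
    """
    mu = np.broadcast_to(np.asarray(mu, dtype=float), size)
    if phi <= 1.0:
        return rng.poisson(mu)
    r = mu / (phi - 1.0)
    return rng.negative_binomial(r, 1.0 / phi)


def sample_ids(n_replicates: int) -> tuple[list[str], list[str], pd.DataFrame]:
    """Sample identifiers and the metadata table for the 2x2xn design."""
    prefix = {SPECIES_MAIZE: "Zm", SPECIES_SORGHUM: "Sb"}
    meta_rows = []
    per_species: dict[str, list[str]] = {SPECIES_MAIZE: [], SPECIES_SORGHUM: []}
    for species in (SPECIES_MAIZE, SPECIES_SORGHUM):
        for trt in TREATMENTS:
            for rep in range(1, n_replicates + 1):
                sid = f"{prefix[species]}_{trt}{rep}"
                per_species[species].append(sid)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "species": species,
                        "treatment": trt,
                        "replicate": rep,
                    }
                )
    design = pd.DataFrame(meta_rows)
    return per_species[SPECIES_MAIZE], per_species[SPECIES_SORGHUM], design


def generate_count_tables(
    truth: GroundTruth, cfg: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw spectral-count tables for both species plus the sample metadata.

    Returns (counts_maize, counts_sorghum, design).  Count tables are indexed
    by accession with one integer column per sample.  Orphan proteins receive
    baseline counts with no treatment effect.
    """
    cfg.validate()
    rng = _rng(cfg.seed, _STREAM_COUNTS)
    maize_samples, sorghum_samples, design = sample_ids(cfg.n_replicates)
    n_rep = cfg.n_replicates
    P = truth.n_pairs

    b0 = truth.true_betas[:, 0] if P else np.zeros(0)
    bs = truth.true_betas[:, 1] if P else np.zeros(0)
    bt = truth.true_betas[:, 2] if P else np.zeros(0)

    def cell(mu: np.ndarray) -> np.ndarray:
        return _nb_draw(rng, mu[:, None], cfg.dispersion, (len(mu), n_rep))

    maize_ww = cell(np.exp(b0))
    maize_wd = cell(np.exp(b0 + bt))
    sorg_ww = cell(np.exp(b0 + bs))
    sorg_wd = cell(np.exp(b0 + bs + bt))

    maize_rows = {}
    sorghum_rows = {}
    for i, (m_acc, s_acc) in enumerate(truth.ortholog_pairs):
        maize_rows[m_acc] = np.concatenate([maize_ww[i], maize_wd[i]])
        sorghum_rows[s_acc] = np.concatenate([sorg_ww[i], sorg_wd[i]])

    mu0 = cfg.baseline_mean
    for acc in truth.maize_orphans:
        maize_rows[acc] = _nb_draw(
            rng, np.full(2 * n_rep, mu0), cfg.dispersion, (2 * n_rep,)
        )
    for acc in truth.sorghum_orphans:
        sorghum_rows[acc] = _nb_draw(
            rng, np.full(2 * n_rep, mu0), cfg.dispersion, (2 * n_rep,)
        )

    counts_maize = pd.DataFrame.from_dict(
        maize_rows, orient="index", columns=maize_samples, dtype=np.int64
    )
    counts_sorghum = pd.DataFrame.from_dict(
        sorghum_rows, orient="index", columns=sorghum_samples, dtype=np.int64
    )
    counts_maize.index.name = "accession"
    counts_sorghum.index.name = "accession"
    return counts_maize, counts_sorghum, design


# ---------------------------------------------------------------------------
# Physiology
# ---------------------------------------------------------------------------

# Proline assay geometry: 100 mg tissue extracted in 0.5 mL acid, 0.1 mL
# aliquot reacted, chromophore partitioned into 1 mL toluene.
PROLINE_EXTRACT_VOLUME = 0.5  # mL
PROLINE_ALIQUOT_VOLUME = 0.1  # mL
PROLINE_TOLUENE_VOLUME = 1.0  # mL
PROLINE_TISSUE_MASS = 0.1  # g

# Cell means emulating the drought phenotype: maize loses leaf hydration
# under deficit while sorghum largely maintains it; proline rises in both.
_RWC_MEANS = {
    (SPECIES_MAIZE, "WW"): 95.0,
    (SPECIES_MAIZE, "WD"): 65.0,
    (SPECIES_SORGHUM, "WW"): 94.0,
    (SPECIES_SORGHUM, "WD"): 88.0,
}
_PROLINE_MEANS = {  # umol per g fresh weight
    (SPECIES_MAIZE, "WW"): 2.0,
    (SPECIES_MAIZE, "WD"): 3.2,
    (SPECIES_SORGHUM, "WW"): 2.0,
    (SPECIES_SORGHUM, "WD"): 3.0,
}
_TRUE_SLOPE = 10.0  # absorbance per (umol/mL)
_TRUE_INTERCEPT = 0.02


@dataclass
class PhysioSim:
    """Physiology fixture: per-sample records, standards, and the truth."""

    records: pd.DataFrame
    standards: pd.DataFrame
    true_slope: float
    true_intercept: float


def generate_physio_data(
    seed: int, n_replicates: int = 5, noise: float = 1.0
) -> PhysioSim:
    """Leaf weights and ninhydrin absorbances with recorded ground truth.

    ``noise`` scales every stochastic perturbation; at 0 the recorded truth
    round-trips exactly through the physiology computations.  Fresh weight is
    derived from the planted relative water content so DW <= FW <= TW holds
    by construction.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    if noise < 0:
        raise ValueError("noise must be non-negative")
    rng = _rng(seed, _STREAM_PHYSIO)
    prefix = {SPECIES_MAIZE: "Zm", SPECIES_SORGHUM: "Sb"}
    dilution = PROLINE_EXTRACT_VOLUME / PROLINE_ALIQUOT_VOLUME

    rows = []
    for species in (SPECIES_MAIZE, SPECIES_SORGHUM):
        for trt in TREATMENTS:
            for rep in range(1, n_replicates + 1):
                true_rwc = float(
                    np.clip(
                        _RWC_MEANS[(species, trt)] + noise * rng.normal(0.0, 2.0),
                        5.0,
                        100.0,
                    )
                )
                true_pro = float(
                    max(
                        0.05,
                        _PROLINE_MEANS[(species, trt)]
                        * (1.0 + noise * rng.normal(0.0, 0.08)),
                    )
                )
                tw = 1.0 + noise * rng.normal(0.0, 0.05)
                dw = 0.15 + noise * rng.normal(0.0, 0.01)
                fw = dw + true_rwc / 100.0 * (tw - dw)
                conc = true_pro * PROLINE_TISSUE_MASS / (
                    PROLINE_TOLUENE_VOLUME * dilution
                )
                a520 = (
                    _TRUE_INTERCEPT
                    + _TRUE_SLOPE * conc
                    + noise * rng.normal(0.0, 0.005)
                )
                rows.append(
                    {
                        "sample_id": f"{prefix[species]}_{trt}{rep}",
                        "species": species,
                        "treatment": trt,
                        "replicate": rep,
                        "FW": fw,
                        "DW": dw,
                        "TW": tw,
                        "A520": max(a520, 0.0),
                        "tissue_mass": PROLINE_TISSUE_MASS,
                        "true_rwc": true_rwc,
                        "true_proline": true_pro,
                    }
                )
    records = pd.DataFrame(rows)

    concs = np.array([0.0, 0.02, 0.04, 0.06, 0.08, 0.10])
    absorb = (
        _TRUE_INTERCEPT
        + _TRUE_SLOPE * concs
        + noise * rng.normal(0.0, 0.005, size=len(concs))
    )
    standards = pd.DataFrame(
        {"concentration": concs, "absorbance": np.clip(absorb, 0.0, None)}
    )
    return PhysioSim(
        records=records,
        standards=standards,
        true_slope=_TRUE_SLOPE,
        true_intercept=_TRUE_INTERCEPT,
    )


# ---------------------------------------------------------------------------
# Writers (deterministic, text-only)
# ---------------------------------------------------------------------------

def write_fasta(db: dict[str, str], path: str | Path, width: int = 60) -> None:
    lines = []
    for acc, seq in db.items():
        lines.append(f">{acc}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_alignment_table(df: pd.DataFrame, path: str | Path) -> None:
    # Tabular alignment convention: tab-separated, no header row.
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")
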