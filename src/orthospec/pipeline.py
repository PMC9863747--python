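"""Pipeline orchestration: simulate -> orthomap -> merge -> DE -> physiology.

A single declarative config drives the run.  In fixture mode the synthetic
generator writes every input under ``<outdir>/inputs`` first, so the full
chain is exercised with no external data; in real mode the config must point
at existing FASTA/TSV inputs.  Every stage reads its inputs from files and
writes its outputs to files, so a run can be resumed from any intermediate
and all tabular outputs carry header comments recording the governing
parameters.  Identical config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import countmerge, diffexpr, orthomap, physiology, synthdata
from .synthdata import SimConfig

__all__ = [
    "PipelineConfig",
    "RunResult",
    "run_all",
    "validate_inputs",
    "stage_simulate",
    "stage_orthomap",
    "stage_merge",
    "stage_de",
    "stage_physio",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and records."""


@dataclass
class PipelineConfig:
    outdir: Path
    fixture: bool = True
    seed: int = 0
    sim: SimConfig | None = None
    # real-mode inputs (derived automatically in fixture mode)
    fasta_maize: Path | None = None
    fasta_sorghum: Path | None = None
    alignments: Path | None = None
    counts_maize: Path | None = None
    counts_sorghum: Path | None = None
    design: Path | None = None
    physio: Path | None = None
    standards: Path | None = None
    # thresholds and model options
    orthomap_mode: str = orthomap.MODE_UNION
    min_bitscore: float = orthomap.DEFAULT_MIN_BITSCORE
    min_spectra: int = diffexpr.DEFAULT_MIN_SPECTRA
    alpha: float = diffexpr.DEFAULT_ALPHA
    pseudocount: float = diffexpr.DEFAULT_PSEUDOCOUNT
    offset: str = "none"
    interaction: bool = False
    physio_noise: float = 1.0
    include_decoys: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.fixture and self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        if self.sim is not None and self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)
        if self.fixture:
            inputs = self.outdir / "inputs"
            self.fasta_maize = inputs / "maize.fasta"
            self.fasta_sorghum = inputs / "sorghum.fasta"
            self.alignments = inputs / "alignments.tsv"
            self.counts_maize = inputs / "counts_maize.tsv"
            self.counts_sorghum = inputs / "counts_sorghum.tsv"
            self.design = inputs / "design.tsv"
            self.physio = inputs / "physio.tsv"
            self.standards = inputs / "proline_standards.tsv"
        else:
            for name in ("counts_maize", "counts_sorghum", "design"):
                if getattr(self, name) is None:
                    raise ValueError(f"non-fixture mode requires {name}")
            for name in (
                "fasta_maize",
                "fasta_sorghum",
                "alignments",
                "counts_maize",
                "counts_sorghum",
                "design",
                "physio",
                "standards",
            ):
                p = getattr(self, name)
                if p is not None:
                    setattr(self, name, Path(p))
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_bitscore <= 0 or self.min_spectra <= 0:
            raise ValueError("thresholds must be positive")
        if self.orthomap_mode not in (orthomap.MODE_UNION, orthomap.MODE_RECIPROCAL):
            raise ValueError(f"unknown orthomap mode {self.orthomap_mode!r}")
        if self.offset not in ("none", "total"):
            raise ValueError("offset must be 'none' or 'total'")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
            d["sim"]["bitscore_true_range"] = list(
                d["sim"]["bitscore_true_range"]
            )
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", None)
        sim = None
        if sim_raw:
            if "bitscore_true_range" in sim_raw:
                sim_raw["bitscore_true_range"] = tuple(
                    sim_raw["bitscore_true_range"]
                )
            sim = SimConfig(**sim_raw)
        return cls(sim=sim, **raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True)
        )

    def config_hash(self) -> str:
        # Paths are excluded so runs differing only in location hash equal.
        d = {
            k: v
            for k, v in self.to_dict().items()
            if k
            not in (
                "outdir",
                "fasta_maize",
                "fasta_sorghum",
                "alignments",
                "counts_maize",
                "counts_sorghum",
                "design",
                "physio",
                "standards",
            )
        }
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    config: PipelineConfig
    paths: dict[str, Path]
    match_stats: countmerge.MatchStats
    de_results: pd.DataFrame
    physio_summary: pd.DataFrame
    report: str


def _header(cfg: PipelineConfig, stage: str, **extra) -> str:
    lines = [
        f"stage: {stage}",
        f"seed: {cfg.seed}",
        f"config_hash: {cfg.config_hash()}",
    ]
    lines += [f"{k}: {v}" for k, v in extra.items()]
    return "\n".join(lines)


def _write_tsv(
    df: pd.DataFrame, path: Path, header: str, index: bool = False
) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def _fasta_accessions(path: Path) -> set[str]:
    return {rec.id for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> dict[str, Path]:
    """Write every synthetic input (fixture mode only)."""
    if not cfg.fixture:
        raise StageError("simulate: config is not in fixture mode")
    sim = cfg.sim
    assert sim is not None
    inputs = cfg.outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)

    maize_db, sorghum_db, truth = synthdata.generate_protein_dbs(sim)
    synthdata.write_fasta(maize_db, cfg.fasta_maize)
    synthdata.write_fasta(sorghum_db, cfg.fasta_sorghum)
    align = synthdata.generate_alignment_table(
        truth, sim, include_decoys=cfg.include_decoys
    )
    synthdata.write_alignment_table(align, cfg.alignments)
    counts_m, counts_s, design = synthdata.generate_count_tables(truth, sim)
    synthdata.write_count_table(counts_m, cfg.counts_maize)
    synthdata.write_count_table(counts_s, cfg.counts_sorghum)
    design.to_csv(cfg.design, sep="\t", index=False)
    phys = synthdata.generate_physio_data(
        sim.seed, n_replicates=sim.n_replicates, noise=cfg.physio_noise
    )
    phys.records.to_csv(cfg.physio, sep="\t", index=False, float_format="%.10g")
    phys.standards.to_csv(
        cfg.standards, sep="\t", index=False, float_format="%.10g"
    )
    truth_df = pd.DataFrame(
        {
            "maize_accession": [m for m, _ in truth.ortholog_pairs],
            "sorghum_accession": [s for _, s in truth.ortholog_pairs],
            "de_flag": truth.de_flags.astype(int),
            "beta0": truth.true_betas[:, 0],
            "beta_species": truth.true_betas[:, 1],
            "beta_treatment": truth.true_betas[:, 2],
            "split": truth.split_flags.astype(int),
        }
    )
    truth_path = inputs / "ground_truth.tsv"
    _write_tsv(truth_df, truth_path, _header(cfg, "simulate"))
    return {
        "fasta_maize": cfg.fasta_maize,
        "fasta_sorghum": cfg.fasta_sorghum,
        "alignments": cfg.alignments,
        "counts_maize": cfg.counts_maize,
        "counts_sorghum": cfg.counts_sorghum,
        "design": cfg.design,
        "physio": cfg.physio,
        "standards": cfg.standards,
        "ground_truth": truth_path,
    }


def stage_orthomap(cfg: PipelineConfig) -> Path:
    """Build and write the ortholog map from the alignment table."""
    try:
        hits = orthomap.parse_alignments(cfg.alignments)
        maize_accs = _fasta_accessions(cfg.fasta_maize)
        sorghum_accs = _fasta_accessions(cfg.fasta_sorghum)
        fwd, rev = orthomap.split_directions(hits, maize_accs, sorghum_accs)
        omap = orthomap.combine_directions(
            orthomap.best_hits(rev, cfg.min_bitscore),
            orthomap.best_hits(fwd, cfg.min_bitscore),
            mode=cfg.orthomap_mode,
        )
    except (ValueError, OSError) as exc:
        raise StageError(f"orthomap: {exc}") from exc
    out = cfg.outdir / "ortholog_map.tsv"
    _write_tsv(
        omap.to_frame(),
        out,
        _header(cfg, "orthomap", min_bitscore=cfg.min_bitscore, mode=cfg.orthomap_mode),
    )
    return out


def stage_merge(cfg: PipelineConfig) -> tuple[Path, Path]:
    """Align count rows on the map, merge splits, write matrix and stats."""
    try:
        omap = orthomap.OrthologMap.read_tsv(cfg.outdir / "ortholog_map.tsv")
        counts_m = countmerge.read_count_table(cfg.counts_maize)
        counts_s = countmerge.read_count_table(cfg.counts_sorghum)
        matrix, _ = countmerge.align_rows(counts_m, counts_s, omap)
        matrix = countmerge.merge_split_rows(matrix, omap)
    except ValueError as exc:
        raise StageError(f"merge: {exc}") from exc
    matrix_path = cfg.outdir / "joint_matrix.tsv"
    matrix.write_tsv(matrix_path, _header(cfg, "merge"))
    stats_path = cfg.outdir / "match_stats.tsv"
    assert matrix.stats is not None
    _write_tsv(
        countmerge.match_statistics_report(matrix.stats),
        stats_path,
        _header(cfg, "merge"),
    )
    return matrix_path, stats_path


def stage_de(cfg: PipelineConfig) -> Path:
    """Filter, fit per-protein quasi-Poisson models, BH-adjust, classify."""
    try:
        matrix = countmerge.JointCountMatrix.read_tsv(cfg.outdir / "joint_matrix.tsv")
        design = pd.read_csv(cfg.design, sep="\t", comment="#")
        matrix = diffexpr.filter_min_spectra(matrix, cfg.min_spectra)
        fits = diffexpr.fit_all(
            matrix,
            design,
            offset=cfg.offset,
            interaction=cfg.interaction,
            pseudocount=cfg.pseudocount,
        )
        results = diffexpr.classify(fits, alpha=cfg.alpha)
    except ValueError as exc:
        raise StageError(f"de: {exc}") from exc
    out = cfg.outdir / "de_results.tsv"
    _write_tsv(
        results,
        out,
        _header(
            cfg,
            "de",
            min_spectra=cfg.min_spectra,
            alpha=cfg.alpha,
            pseudocount=cfg.pseudocount,
            offset=cfg.offset,
            interaction=cfg.interaction,
        ),
    )
    return out


def stage_physio(cfg: PipelineConfig) -> tuple[Path, Path]:
    """Per-sample RWC/proline and the Tukey-letter group summary."""
    try:
        records = pd.read_csv(cfg.physio, sep="\t", comment="#")
        standards = pd.read_csv(cfg.standards, sep="\t", comment="#")
        per_sample, curve = physiology.compute_physiology(records, standards)
        summary = physiology.summarize_groups(per_sample, alpha=cfg.alpha)
    except ValueError as exc:
        raise StageError(f"physio: {exc}") from exc
    per_path = cfg.outdir / "physio_per_sample.tsv"
    keep = [
        c
        for c in per_sample.columns
        if not c.startswith("true_")
    ]
    _write_tsv(
        per_sample[keep],
        per_path,
        _header(
            cfg,
            "physio",
            curve_slope=f"{curve.slope:.10g}",
            curve_intercept=f"{curve.intercept:.10g}",
            curve_r_squared=f"{curve.r_squared:.10g}",
            proline_formula=(
                "content = (A520-intercept)/slope * V_toluene"
                " * (V_extract/V_aliquot) / tissue_mass"
            ),
        ),
    )
    sum_path = cfg.outdir / "physio_summary.tsv"
    _write_tsv(summary, sum_path, _header(cfg, "physio", alpha=cfg.alpha))
    return per_path, sum_path


def validate_inputs(cfg: PipelineConfig) -> list[str]:
    """Collect (not fail-fast) validation findings on the configured inputs."""
    findings: list[str] = []

    def check_exists(name: str, path: Path | None) -> bool:
        if path is None:
            findings.append(f"{name}: no path configured")
            return False
        if not Path(path).exists():
            findings.append(f"{name}: file not found: {path}")
            return False
        return True

    maize_accs: set[str] = set()
    sorghum_accs: set[str] = set()
    for name, path in (
        ("fasta_maize", cfg.fasta_maize),
        ("fasta_sorghum", cfg.fasta_sorghum),
    ):
        if check_exists(name, path):
            try:
                accs = _fasta_accessions(path)
                if name == "fasta_maize":
                    maize_accs = accs
                else:
                    sorghum_accs = accs
            except Exception as exc:  # malformed FASTA
                findings.append(f"{name}: unparseable FASTA ({exc})")
    if maize_accs and sorghum_accs and (maize_accs & sorghum_accs):
        clash = sorted(maize_accs & sorghum_accs)[:3]
        findings.append(f"accession namespaces overlap: {clash}")

    if check_exists("alignments", cfg.alignments):
        try:
            orthomap.parse_alignments(cfg.alignments)
        except orthomap.AlignmentFormatError as exc:
            findings.append(f"alignments: {exc}")

    design = None
    if check_exists("design", cfg.design):
        design = pd.read_csv(cfg.design, sep="\t", comment="#")
        needed = {"sample_id", "species", "treatment", "replicate"}
        missing_cols = needed - set(design.columns)
        if missing_cols:
            findings.append(f"design: missing columns {sorted(missing_cols)}")
            design = None
    if design is not None:
        species = set(design["species"])
        treatments = set(design["treatment"])
        if species != {"maize", "sorghum"}:
            findings.append(f"design: expected two species, found {sorted(species)}")
        if treatments != {"WW", "WD"}:
            findings.append(
                f"design: expected treatments WW/WD, found {sorted(treatments)}"
            )
        cell_sizes = design.groupby(["species", "treatment"]).size()
        if len(set(cell_sizes)) > 1:
            findings.append(
                f"design: unbalanced cells: {cell_sizes.to_dict()}"
            )

    for name, path in (
        ("counts_maize", cfg.counts_maize),
        ("counts_sorghum", cfg.counts_sorghum),
    ):
        if not check_exists(name, path):
            continue
        try:
            raw = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        except Exception as exc:
            findings.append(f"{name}: unparseable TSV ({exc})")
            continue
        num = raw.apply(pd.to_numeric, errors="coerce")
        bad = num.isna()
        if bad.any().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            findings.append(
                f"{name}: non-numeric count at row {raw.index[r]!r}, "
                f"column {raw.columns[c]!r}"
            )
            continue
        neg = num < 0
        if neg.any().any():
            r, c = np.argwhere(neg.to_numpy())[0]
            findings.append(
                f"{name}: negative count at row {raw.index[r]!r}, "
                f"column {raw.columns[c]!r}"
            )
        frac = num != num.round()
        if frac.any().any():
            r, c = np.argwhere(frac.to_numpy())[0]
            findings.append(
                f"{name}: non-integer count at row {raw.index[r]!r}, "
                f"column {raw.columns[c]!r}"
            )
        if design is not None:
            known = set(design["sample_id"])
            unknown = [c for c in raw.columns if c not in known]
            if unknown:
                findings.append(
                    f"{name}: sample column(s) missing from metadata: {unknown}"
                )
    return findings


def run_all(cfg: PipelineConfig) -> RunResult:
    """Execute every stage in order and write a run report."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(cfg.outdir / "config.yaml")
    paths: dict[str, Path] = {}
    if cfg.fixture:
        paths.update(stage_simulate(cfg))

    findings = validate_inputs(cfg)
    if findings:
        raise StageError(
            "validate: input problems found:\n  " + "\n  ".join(findings)
        )

    paths["ortholog_map"] = stage_orthomap(cfg)
    paths["joint_matrix"], paths["match_stats"] = stage_merge(cfg)
    paths["de_results"] = stage_de(cfg)
    paths["physio_per_sample"], paths["physio_summary"] = stage_physio(cfg)

    matrix = countmerge.JointCountMatrix.read_tsv(paths["joint_matrix"])
    stats = matrix.stats
    results = pd.read_csv(paths["de_results"], sep="\t", comment="#")
    physio_summary = pd.read_csv(paths["physio_summary"], sep="\t", comment="#")
    stats_table = pd.read_csv(paths["match_stats"], sep="\t", comment="#")

    n_tested = len(results)
    n_sig_species = int(results["significant_species"].sum())
    n_sig_treatment = int(results["significant_treatment"].sum())
    n_sig_both = int(results["significant_both"].sum())
    report_lines = [
        f"seed: {cfg.seed}",
        f"config_hash: {cfg.config_hash()}",
        "",
        "match statistics:",
        stats_table.to_string(index=False),
        "",
        f"orthologs tested (>= {cfg.min_spectra} spectra): {n_tested}",
        f"significant for species (q < {cfg.alpha}): {n_sig_species}",
        f"significant for treatment (q < {cfg.alpha}): {n_sig_treatment}",
        f"significant for both terms: {n_sig_both}",
        "",
        "physiology group summary:",
        physio_summary.to_string(index=False),
    ]
    report = "\n".join(report_lines) + "\n"
    report_path = cfg.outdir / "report.txt"
    report_path.write_text(report)
    paths["report"] = report_path

    # MatchStats reconstructed from the stats table for programmatic use.
    ms = countmerge.MatchStats()
    lookup = dict(zip(stats_table["category"], stats_table["count"]))
    ms.n_total_entries = int(lookup.get("total entries", 0))
    ms.n_no_ortholog = int(lookup.get("no ortholog named", 0))
    ms.n_named_in_map = int(lookup.get("named in map, unmatched", 0))
    ms.n_both_species = int(lookup.get("matched in both species at alignment", 0))
    ms.n_cross_identified = int(lookup.get("cross-identified via row merge", 0))
    ms.matched_before_merge = int(lookup.get("matched rows before merge", 0))
    ms.matched_after_merge = int(lookup.get("matched rows after merge", 0))

    return RunResult(
        config=cfg,
        paths=paths,
        match_stats=ms,
        de_results=results,
        physio_summary=physio_summary,
        report=report,
    )
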