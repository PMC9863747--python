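"""Align per-species spectral-count rows on an ortholog map and merge splits.

Each species' count table is keyed by that species' protein accessions.  Row
alignment attaches every count row to the ortholog pair named by that
protein's own query direction in the map, yielding one joint row per pair
with a maize vector and a sorghum vector.  When a pair's two sides ended up
in different rows (the paralog-split case: the forward and reverse best hits
disagree on the representative accession), alignment produces two one-sided
rows; :func:`merge_split_rows` rejoins them by per-sample addition, recording
the provenance of the merge.  Proteins with no ortholog in the map are
excluded from the joint matrix and tallied in :class:`MatchStats`.

Match statistics partition the input rows ("entries") into: no ortholog
named; named in the map but never matched; matched to the partner species at
alignment time; and cross-identified (matched only through a merge).
Percentages are reported to the nearest integer of the total entry count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .orthomap import OrthologMap, OrthologPair

__all__ = [
    "JointRow",
    "JointCountMatrix",
    "MatchStats",
    "MergeAmbiguityError",
    "align_rows",
    "merge_split_rows",
    "improvement_percent",
    "match_statistics_report",
    "read_count_table",
]


class MergeAmbiguityError(ValueError):
    """Raised when a merge would combine two rows that are both two-sided."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class JointRow:
    """One row of the joint matrix: an ortholog pair's counts in both species.

    ``maize_accessions`` / ``sorghum_accessions`` list the accessions whose
    counts are actually included (empty on a missing side); ``pairs`` lists
    the map pairs this row represents; ``sources`` records provenance of the
    source count rows combined into this row.
    """

    maize_accessions: tuple[str, ...]
    sorghum_accessions: tuple[str, ...]
    maize_counts: np.ndarray
    sorghum_counts: np.ndarray
    pairs: tuple[tuple[str, str], ...]
    sources: tuple[str, ...]

    @property
    def has_maize(self) -> bool:
        return len(self.maize_accessions) > 0

    @property
    def has_sorghum(self) -> bool:
        return len(self.sorghum_accessions) > 0

    @property
    def one_sided(self) -> bool:
        return not (self.has_maize and self.has_sorghum)

    @property
    def total(self) -> int:
        return int(self.maize_counts.sum() + self.sorghum_counts.sum())

    def key(self) -> tuple[str, str]:
        """Display key: the count-bearing accessions, falling back to the
        first map pair's names for a missing side."""
        m = self.maize_accessions[0] if self.has_maize else self.pairs[0][0]
        s = self.sorghum_accessions[0] if self.has_sorghum else self.pairs[0][1]
        return m, s


@dataclass
class MatchStats:
    """Row-matching tallies; entry categories carry integer percentages."""

    n_total_entries: int = 0
    n_no_ortholog: int = 0
    n_named_in_map: int = 0
    n_both_species: int = 0
    n_cross_identified: int = 0
    matched_before_merge: int = 0
    matched_after_merge: int = 0

    def percent(self, count: int) -> int:
        if self.n_total_entries == 0:
            return 0
        return _round_half_up(100.0 * count / self.n_total_entries)


@dataclass
class JointCountMatrix:
    rows: list[JointRow]
    maize_samples: list[str]
    sorghum_samples: list[str]
    stats: MatchStats | None = None

    def __len__(self) -> int:
        return len(self.rows)

    def accession_set(self, side: str) -> set[str]:
        accs: set[str] = set()
        for r in self.rows:
            accs.update(getattr(r, f"{side}_accessions"))
        return accs

    def totals(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample count totals (maize vector, sorghum vector)."""
        m = np.zeros(len(self.maize_samples), dtype=np.int64)
        s = np.zeros(len(self.sorghum_samples), dtype=np.int64)
        for r in self.rows:
            m += r.maize_counts
            s += r.sorghum_counts
        return m, s

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in sorted(self.rows, key=lambda r: r.key()):
            rec = {
                "maize_accession": ";".join(r.maize_accessions) or "-",
                "sorghum_accession": ";".join(r.sorghum_accessions) or "-",
                "map_pairs": ";".join(f"{m}|{s}" for m, s in r.pairs),
                "one_sided": int(r.one_sided),
                "sources": ";".join(r.sources),
            }
            for name, val in zip(self.maize_samples, r.maize_counts):
                rec[name] = int(val)
            for name, val in zip(self.sorghum_samples, r.sorghum_counts):
                rec[name] = int(val)
            recs.append(rec)
        cols = (
            ["maize_accession", "sorghum_accession", "map_pairs", "one_sided", "sources"]
            + self.maize_samples
            + self.sorghum_samples
        )
        return pd.DataFrame(recs, columns=cols)

    def write_tsv(self, path: str | Path, header_comment: str = "") -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write(
                f"# maize_samples: {','.join(self.maize_samples)}\n"
                f"# sorghum_samples: {','.join(self.sorghum_samples)}\n"
            )
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "JointCountMatrix":
        maize_samples: list[str] = []
        sorghum_samples: list[str] = []
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if line.startswith("# maize_samples:"):
                    val = line.split(":", 1)[1].strip()
                    maize_samples = val.split(",") if val else []
                elif line.startswith("# sorghum_samples:"):
                    val = line.split(":", 1)[1].strip()
                    sorghum_samples = val.split(",") if val else []
        df = pd.read_csv(path, sep="\t", comment="#")
        rows = []
        for r in df.itertuples():
            m_accs = tuple(a for a in str(r.maize_accession).split(";") if a != "-")
            s_accs = tuple(
                a for a in str(r.sorghum_accession).split(";") if a != "-"
            )
            pairs = tuple(
                tuple(p.split("|")) for p in str(r.map_pairs).split(";") if p
            )
            rows.append(
                JointRow(
                    maize_accessions=m_accs,
                    sorghum_accessions=s_accs,
                    maize_counts=np.array(
                        [getattr(r, c) for c in maize_samples], dtype=np.int64
                    ),
                    sorghum_counts=np.array(
                        [getattr(r, c) for c in sorghum_samples], dtype=np.int64
                    ),
                    pairs=pairs,  # type: ignore[arg-type]
                    sources=tuple(str(r.sources).split(";")),
                )
            )
        return cls(
            rows=rows, maize_samples=maize_samples, sorghum_samples=sorghum_samples
        )


def _validate_counts(df: pd.DataFrame, label: str) -> None:
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:3]
        raise ValueError(f"{label} count table has duplicate accessions: {dupes}")
    values = df.to_numpy()
    if values.size and (values < 0).any():
        raise ValueError(f"{label} count table contains negative counts")


def _choose_pair(
    pairs: list[OrthologPair], side: str
) -> OrthologPair:
    """Attach an accession's counts to the pair its own query direction names.

    ``side`` is 'maize' (forward query) or 'sorghum' (reverse query).  Among
    same-direction candidates the highest supporting bit score wins; without
    directional support, lexicographic pair order is used.
    """
    flag = "supported_fwd" if side == "maize" else "supported_rev"
    score = "bitscore_fwd" if side == "maize" else "bitscore_rev"
    own = [p for p in pairs if getattr(p, flag)]
    if own:
        return max(own, key=lambda p: (getattr(p, score), p.maize, p.sorghum))
    return min(pairs, key=lambda p: (p.maize, p.sorghum))


def align_rows(
    counts_maize: pd.DataFrame,
    counts_sorghum: pd.DataFrame,
    omap: OrthologMap,
) -> tuple[JointCountMatrix, MatchStats]:
    """Build the joint matrix, one row per ortholog pair with counts.

    Rows whose accession appears in no map pair are excluded and tallied.
    A pair whose partner has no count row yields a one-sided joint row with
    an all-zero vector on the missing side, retained and flagged.
    """
    shared = set(counts_maize.index) & set(counts_sorghum.index)
    if shared:
        raise ValueError(
            "species accession namespaces must be disjoint; shared: "
            f"{sorted(shared)[:3]}"
        )
    _validate_counts(counts_maize, "maize")
    _validate_counts(counts_sorghum, "sorghum")

    maize_idx = omap.maize_index()
    sorghum_idx = omap.sorghum_index()
    n_mz = len(maize_samples := list(counts_maize.columns))
    n_sb = len(sorghum_samples := list(counts_sorghum.columns))

    stats = MatchStats(n_total_entries=len(counts_maize) + len(counts_sorghum))

    assigned: dict[tuple[str, str], dict] = {}
    for acc in counts_maize.index:
        pairs = maize_idx.get(acc)
        if not pairs:
            stats.n_no_ortholog += 1
            continue
        pair = _choose_pair(pairs, "maize")
        assigned.setdefault((pair.maize, pair.sorghum), {})["maize"] = acc
    for acc in counts_sorghum.index:
        pairs = sorghum_idx.get(acc)
        if not pairs:
            stats.n_no_ortholog += 1
            continue
        pair = _choose_pair(pairs, "sorghum")
        assigned.setdefault((pair.maize, pair.sorghum), {})["sorghum"] = acc

    rows: list[JointRow] = []
    for pair_key in sorted(assigned):
        sides = assigned[pair_key]
        m_acc = sides.get("maize")
        s_acc = sides.get("sorghum")
        maize_counts = (
            counts_maize.loc[m_acc].to_numpy(dtype=np.int64)
            if m_acc is not None
            else np.zeros(n_mz, dtype=np.int64)
        )
        sorghum_counts = (
            counts_sorghum.loc[s_acc].to_numpy(dtype=np.int64)
            if s_acc is not None
            else np.zeros(n_sb, dtype=np.int64)
        )
        sources = tuple(
            f"{side}:{acc}"
            for side, acc in (("maize", m_acc), ("sorghum", s_acc))
            if acc is not None
        )
        rows.append(
            JointRow(
                maize_accessions=(m_acc,) if m_acc is not None else (),
                sorghum_accessions=(s_acc,) if s_acc is not None else (),
                maize_counts=maize_counts,
                sorghum_counts=sorghum_counts,
                pairs=(pair_key,),
                sources=sources,
            )
        )

    matched = sum(1 for r in rows if not r.one_sided)
    stats.matched_before_merge = matched
    stats.matched_after_merge = matched
    stats.n_both_species = 2 * matched
    stats.n_named_in_map = (
        stats.n_total_entries - stats.n_no_ortholog - stats.n_both_species
    )
    matrix = JointCountMatrix(
        rows=rows,
        maize_samples=maize_samples,
        sorghum_samples=sorghum_samples,
        stats=stats,
    )
    return matrix, stats


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_split_rows(
    matrix: JointCountMatrix, omap: OrthologMap
) -> JointCountMatrix:
    """Merge rows that the map links across a split into single joint rows.

    Rows are connected when they share an accession (in counts or in their
    map pairs) or when a map pair names one accession in each.  Each
    connected group is combined by per-sample addition, with provenance
    preserved; a group containing two rows that each already carry both
    species' counts is ambiguous (many-to-many) and raises
    :class:`MergeAmbiguityError`.  The operation is idempotent and conserves
    per-sample totals.
    """
    rows = matrix.rows
    uf = _UnionFind(len(rows))

    acc_to_rows: dict[str, list[int]] = {}
    for i, r in enumerate(rows):
        mentioned = set(r.maize_accessions) | set(r.sorghum_accessions)
        for m, s in r.pairs:
            mentioned.add(m)
            mentioned.add(s)
        for acc in mentioned:
            acc_to_rows.setdefault(acc, []).append(i)
    for indices in acc_to_rows.values():
        for j in indices[1:]:
            uf.union(indices[0], j)
    for p in omap.pairs:
        im = acc_to_rows.get(p.maize)
        is_ = acc_to_rows.get(p.sorghum)
        if im and is_:
            uf.union(im[0], is_[0])

    groups: dict[int, list[int]] = {}
    for i in range(len(rows)):
        groups.setdefault(uf.find(i), []).append(i)

    new_rows: list[JointRow] = []
    n_cross_entries = 0
    for root in sorted(groups):
        members = [rows[i] for i in groups[root]]
        if len(members) == 1:
            new_rows.append(members[0])
            continue
        two_sided = [r for r in members if not r.one_sided]
        if len(two_sided) >= 2:
            offenders = sorted(
                acc for r in two_sided for acc in r.maize_accessions + r.sorghum_accessions
            )
            raise MergeAmbiguityError(
                "ambiguous many-to-many merge: rows with both species' counts "
                f"would be combined; accessions involved: {offenders}"
            )
        merged = JointRow(
            maize_accessions=tuple(
                sorted({a for r in members for a in r.maize_accessions})
            ),
            sorghum_accessions=tuple(
                sorted({a for r in members for a in r.sorghum_accessions})
            ),
            maize_counts=np.sum([r.maize_counts for r in members], axis=0).astype(
                np.int64
            ),
            sorghum_counts=np.sum(
                [r.sorghum_counts for r in members], axis=0
            ).astype(np.int64),
            pairs=tuple(sorted({p for r in members for p in r.pairs})),
            sources=tuple(
                dict.fromkeys(src for r in members for src in r.sources)
            ),
        )
        if not merged.one_sided:
            # entries (input count rows) newly promoted into a matched row
            one_sided_entries = sum(
                len(r.maize_accessions) + len(r.sorghum_accessions)
                for r in members
                if r.one_sided
            )
            n_cross_entries += one_sided_entries
        new_rows.append(merged)

    old = matrix.stats or MatchStats()
    matched_after = sum(1 for r in new_rows if not r.one_sided)
    stats = replace(
        old,
        n_cross_identified=old.n_cross_identified + n_cross_entries,
        n_named_in_map=old.n_named_in_map - n_cross_entries,
        matched_after_merge=matched_after,
    )
    return JointCountMatrix(
        rows=new_rows,
        maize_samples=matrix.maize_samples,
        sorghum_samples=matrix.sorghum_samples,
        stats=stats,
    )


def improvement_percent(before: int, after: int) -> int:
    """Percentage gain in matched proteins from merging, to the nearest integer."""
    if before <= 0:
        raise ValueError("before must be positive")
    if after < before:
        raise ValueError("after must be >= before")
    return _round_half_up(100.0 * (after - before) / before)


def match_statistics_report(stats: MatchStats) -> pd.DataFrame:
    """Tabulate match statistics with integer-rounded percentages of entries."""
    entry_cats = [
        ("total entries", stats.n_total_entries),
        ("no ortholog named", stats.n_no_ortholog),
        ("named in map, unmatched", stats.n_named_in_map),
        ("matched in both species at alignment", stats.n_both_species),
        ("cross-identified via row merge", stats.n_cross_identified),
    ]
    rows = [
        {"category": name, "count": count, "percent": stats.percent(count)}
        for name, count in entry_cats
    ]
    for name, count in (
        ("matched rows before merge", stats.matched_before_merge),
        ("matched rows after merge", stats.matched_after_merge),
    ):
        rows.append({"category": name, "count": count, "percent": pd.NA})
    if stats.matched_before_merge > 0:
        rows.append(
            {
                "category": "merge improvement (%)",
                "count": improvement_percent(
                    stats.matched_before_merge, stats.matched_after_merge
                ),
                "percent": pd.NA,
            }
        )
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV count table (first column accession, one column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.astype(np.int64)
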