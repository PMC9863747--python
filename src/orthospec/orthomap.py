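"""Cross-species ortholog mapping from tabular protein-alignment hits.

Builds a maize<->sorghum ortholog map from blastp-style tabular output
(the standard 12-column format) using a bit-score floor of 50 and best-hit
retention: hits below the floor are discarded and, per query, only the
highest-scoring surviving hit is kept (ties broken by lower e-value, then
lexicographically smaller subject accession, for determinism).

Two combination modes are offered: ``directional-union`` keeps a pair named
by either query direction (the default); ``reciprocal`` requires both
directions to agree, the stricter convention for one-to-one orthology.
Reciprocal pairs are always a subset of directional-union pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import math
import pandas as pd

__all__ = [
    "AlignmentHit",
    "BestHit",
    "OrthologPair",
    "OrthologMap",
    "AlignmentFormatError",
    "DEFAULT_MIN_BITSCORE",
    "parse_alignments",
    "hits_from_frame",
    "split_directions",
    "best_hits",
    "combine_directions",
]

DEFAULT_MIN_BITSCORE = 50.0

MODE_UNION = "directional-union"
MODE_RECIPROCAL = "reciprocal"


class AlignmentFormatError(ValueError):
    """Raised for malformed rows in a tabular alignment file."""


@dataclass(frozen=True)
class AlignmentHit:
    query: str
    subject: str
    percent_identity: float
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class BestHit:
    subject: str
    bitscore: float
    evalue: float


@dataclass(frozen=True)
class OrthologPair:
    maize: str
    sorghum: str
    supported_fwd: bool  # maize query -> sorghum subject
    supported_rev: bool  # sorghum query -> maize subject
    bitscore_fwd: float = math.nan
    bitscore_rev: float = math.nan


@dataclass
class OrthologMap:
    pairs: list[OrthologPair]
    mode: str = MODE_UNION

    def __post_init__(self) -> None:
        self.pairs = sorted(self.pairs, key=lambda p: (p.maize, p.sorghum))

    def pair_set(self) -> set[tuple[str, str]]:
        return {(p.maize, p.sorghum) for p in self.pairs}

    def maize_index(self) -> dict[str, list[OrthologPair]]:
        idx: dict[str, list[OrthologPair]] = {}
        for p in self.pairs:
            idx.setdefault(p.maize, []).append(p)
        return idx

    def sorghum_index(self) -> dict[str, list[OrthologPair]]:
        idx: dict[str, list[OrthologPair]] = {}
        for p in self.pairs:
            idx.setdefault(p.sorghum, []).append(p)
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "maize_accession": [p.maize for p in self.pairs],
                "sorghum_accession": [p.sorghum for p in self.pairs],
                "mode": self.mode,
                "best_bitscore_fwd": [p.bitscore_fwd for p in self.pairs],
                "best_bitscore_rev": [p.bitscore_rev for p in self.pairs],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", comment="#")
        mode = str(df["mode"].iloc[0]) if len(df) else MODE_UNION
        pairs = [
            OrthologPair(
                maize=str(r.maize_accession),
                sorghum=str(r.sorghum_accession),
                supported_fwd=not math.isnan(r.best_bitscore_fwd),
                supported_rev=not math.isnan(r.best_bitscore_rev),
                bitscore_fwd=float(r.best_bitscore_fwd),
                bitscore_rev=float(r.best_bitscore_rev),
            )
            for r in df.itertuples()
        ]
        return cls(pairs=pairs, mode=mode)


def parse_alignments(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column tabular alignment file into hits.

    Rows must carry the conventional columns (qseqid, sseqid, pident, length,
    mismatch, gapopen, qstart, qend, sstart, send, evalue, bitscore).
    Malformed rows raise :class:`AlignmentFormatError` naming the line.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise AlignmentFormatError(
                    f"line {lineno}: expected 12 tab-separated columns, "
                    f"found {len(fields)}"
                )
            try:
                pident = float(fields[2])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise AlignmentFormatError(
                    f"line {lineno}: non-numeric pident/evalue/bitscore "
                    f"({exc})"
                ) from None
            if evalue < 0:
                raise AlignmentFormatError(
                    f"line {lineno}: negative e-value {evalue}"
                )
            if not math.isfinite(bitscore):
                raise AlignmentFormatError(
                    f"line {lineno}: non-finite bitscore {bitscore}"
                )
            hits.append(
                AlignmentHit(
                    query=fields[0],
                    subject=fields[1],
                    percent_identity=pident,
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
    return hits


def hits_from_frame(df: pd.DataFrame) -> list[AlignmentHit]:
    """Build hits from an in-memory alignment table (12-column convention)."""
    return [
        AlignmentHit(
            query=str(r.qseqid),
            subject=str(r.sseqid),
            percent_identity=float(r.pident),
            evalue=float(r.evalue),
            bitscore=float(r.bitscore),
        )
        for r in df.itertuples()
    ]


def split_directions(
    hits: Iterable[AlignmentHit],
    maize_accessions: set[str],
    sorghum_accessions: set[str],
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Partition mixed-direction hits into (maize->sorghum, sorghum->maize)."""
    fwd: list[AlignmentHit] = []
    rev: list[AlignmentHit] = []
    for h in hits:
        if h.query in maize_accessions and h.subject in sorghum_accessions:
            fwd.append(h)
        elif h.query in sorghum_accessions and h.subject in maize_accessions:
            rev.append(h)
        else:
            raise ValueError(
                f"hit {h.query} -> {h.subject} does not map onto the two "
                "species' accession namespaces"
            )
    return fwd, rev


def best_hits(
    hits: Iterable[AlignmentHit],
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
) -> dict[str, BestHit]:
    """Per-query best-hit retention above the bit-score floor.

    The floor is inclusive (bitscore >= min_bitscore survives).  Per query the
    maximum-bitscore survivor is retained; ties are broken by lower e-value,
    then lexicographically smaller subject accession.  All hits in one call
    must share a single query->subject species direction.
    """
    hits = list(hits)
    queries = {h.query for h in hits}
    subjects = {h.subject for h in hits}
    if queries & subjects:
        clash = sorted(queries & subjects)[:3]
        raise ValueError(
            "hits mix query directions: accession(s) appear as both query "
            f"and subject: {clash}"
        )
    best: dict[str, BestHit] = {}
    for h in hits:
        if h.bitscore < min_bitscore:
            continue
        cur = best.get(h.query)
        if cur is None or _beats(h, cur):
            best[h.query] = BestHit(
                subject=h.subject, bitscore=h.bitscore, evalue=h.evalue
            )
    return best


def _beats(h: AlignmentHit, cur: BestHit) -> bool:
    if h.bitscore != cur.bitscore:
        return h.bitscore > cur.bitscore
    if h.evalue != cur.evalue:
        return h.evalue < cur.evalue
    return h.subject < cur.subject


def combine_directions(
    map_sorghum_to_maize: Mapping[str, BestHit],
    map_maize_to_sorghum: Mapping[str, BestHit],
    mode: str = MODE_UNION,
) -> OrthologMap:
    """Combine the two directed best-hit maps into an ortholog map.

    ``directional-union`` keeps any pair named by either direction;
    ``reciprocal`` keeps only pairs on which both directions agree.
    Provenance records which direction(s) support each pair and the
    supporting bit scores.
    """
    if mode not in (MODE_UNION, MODE_RECIPROCAL):
        raise ValueError(f"unknown mode {mode!r}")

    support: dict[tuple[str, str], dict] = {}
    for m_acc, bh in map_maize_to_sorghum.items():
        key = (m_acc, bh.subject)
        entry = support.setdefault(key, {"fwd": math.nan, "rev": math.nan})
        entry["fwd"] = bh.bitscore
    for s_acc, bh in map_sorghum_to_maize.items():
        key = (bh.subject, s_acc)
        entry = support.setdefault(key, {"fwd": math.nan, "rev": math.nan})
        entry["rev"] = bh.bitscore

    pairs = []
    for (m_acc, s_acc), entry in support.items():
        has_fwd = not math.isnan(entry["fwd"])
        has_rev = not math.isnan(entry["rev"])
        if mode == MODE_RECIPROCAL and not (has_fwd and has_rev):
            continue
        pairs.append(
            OrthologPair(
                maize=m_acc,
                sorghum=s_acc,
                supported_fwd=has_fwd,
                supported_rev=has_rev,
                bitscore_fwd=entry["fwd"],
                bitscore_rev=entry["rev"],
            )
        )
    return OrthologMap(pairs=pairs, mode=mode)
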