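import numpy as np
import pytest

from orthospec.countmerge import align_rows, merge_split_rows
from orthospec.orthomap import (
    best_hits,
    combine_directions,
    hits_from_frame,
    split_directions,
)
from orthospec.synthdata import (
    SimConfig,
    generate_alignment_table,
    generate_count_tables,
    generate_protein_dbs,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_ortholog_pairs=6,
        n_paralog_split_pairs=2,
        n_orphans_per_species=3,
        frac_treatment_de=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """Generated databases, truth, map, and count tables for a small design."""
    maize_db, sorghum_db, truth = generate_protein_dbs(small_cfg)
    align = generate_alignment_table(truth, small_cfg)
    fwd, rev = split_directions(
        hits_from_frame(align), set(maize_db), set(sorghum_db)
    )
    omap = combine_directions(best_hits(rev), best_hits(fwd))
    counts_m, counts_s, design = generate_count_tables(truth, small_cfg)
    return {
        "cfg": small_cfg,
        "maize_db": maize_db,
        "sorghum_db": sorghum_db,
        "truth": truth,
        "alignment": align,
        "omap": omap,
        "counts_maize": counts_m,
        "counts_sorghum": counts_s,
        "design": design,
    }


@pytest.fixture(scope="session")
def small_matrix(small_world):
    matrix, stats = align_rows(
        small_world["counts_maize"],
        small_world["counts_sorghum"],
        small_world["omap"],
    )
    return merge_split_rows(matrix, small_world["omap"])
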