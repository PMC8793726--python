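import numpy as np
import pytest

from retrolink.genetic_distance import validate_map
from retrolink.genome_io import GeneLocus, GenomeAssembly, RetrocopyRecord, RetrocopyTable


@pytest.fixture
def toy_assembly():
    """Three chromosomes (3 Mb, 2 Mb, 1 Mb X); X is 1/6 of the genome."""
    return GenomeAssembly(
        chromosomes=(("chr1", 3_000_000), ("chr2", 2_000_000), ("chrX", 1_000_000)),
        x_name="chrX",
    )


@pytest.fixture
def toy_marey():
    """Uniform 2 cM/Mb maps over the toy assembly (0.06, 0.04, 0.02 Morgans)."""
    return validate_map(
        {
            "chr1": (np.array([0, 3_000_000]), np.array([0.0, 6.0])),
            "chr2": (np.array([0, 2_000_000]), np.array([0.0, 4.0])),
            "chrX": (np.array([0, 1_000_000]), np.array([0.0, 2.0])),
        }
    )


@pytest.fixture
def two_marker_map():
    """One chromosome, markers (0 bp, 0 cM) and (1 Mb, 2 cM)."""
    return validate_map({"chr1": (np.array([0, 1_000_000]), np.array([0.0, 2.0]))})


def point(gene_id, chrom, pos):
    return GeneLocus.point(gene_id, chrom, pos)


def make_table(pairs):
    """Build a RetrocopyTable from (parent_chrom, parent_pos, retro_chrom, retro_pos, status) rows."""
    parents = {}
    records = []
    for i, (pc, pp, rc, rp, status) in enumerate(pairs):
        pid = f"p{i}"
        parents[pid] = point(pid, pc, pp)
        records.append(RetrocopyRecord(f"r{i}", pid, point(f"r{i}", rc, rp), status))
    return RetrocopyTable(records=records, parents=parents)
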