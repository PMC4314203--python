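"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import pytest

from gdvprof.alignment_io import AlignmentRecord, AlignmentTable, OrganismGrouping
from gdvprof.coverage import ReferenceProfile, quality_band


def make_table(alns, ref_lengths=None, grouping=None, default_len=1000):
    """Build an AlignmentTable from (read_id, ref_id, pos, aln_len, nm) tuples."""
    records = [
        AlignmentRecord(read_id=r, ref_id=ref, pos=p, aln_len=ln, edit_distance=nm)
        for r, ref, p, ln, nm in alns
    ]
    if ref_lengths is None:
        ref_lengths = {rec.ref_id: default_len for rec in records}
    g = OrganismGrouping(seq_to_organism=grouping) if grouping else None
    return AlignmentTable.build(records, ref_lengths, g)


def make_profile(org, depth, n_reads=100, gdv=0.9, n_unique=10):
    return ReferenceProfile(
        organism_id=org,
        depth=depth,
        gdv=gdv,
        n_reads=n_reads,
        n_unique_reads=n_unique,
        error_rate=0.0,
        ks_p=None,
        quality_band=quality_band(gdv),
    )


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:s1\tLN:1000\n@SQ\tSN:s2\tLN:800\n@SQ\tSN:s3\tLN:500\n"


@pytest.fixture
def sam_file(tmp_path):
    """Hand-built SAM: r1 multi-maps to 3 sequences of 2 organisms (s1+s2 are
    orgX, s3 is orgY), r2 and r3 map once each, r4 is unmapped."""
    lines = [
        SAM_HEADER.rstrip("\n"),
        "r1\t0\ts1\t11\t60\t100M\t*\t0\t0\t*\t*\tNM:i:2",
        "r1\t256\ts2\t1\t60\t100M\t*\t0\t0\t*\t*\tNM:i:3",
        "r1\t256\ts3\t51\t60\t100M\t*\t0\t0\t*\t*\tNM:i:5",
        "r2\t0\ts1\t201\t60\t50M2D48M\t*\t0\t0\t*\t*\tNM:i:2",
        "r3\t0\ts3\t301\t60\t30=1X69=\t*\t0\t0\t*\t*",
        "r4\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*",
    ]
    path = tmp_path / "toy.sam"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def grouping_xy(tmp_path):
    path = tmp_path / "grouping.tsv"
    path.write_text("s1\torgX\ns2\torgX\ns3\torgY\n")
    return path


TOY_TAXONOMY = """\
root\troot\tno rank\troot
bacteria\troot\tdomain\tBacteria
firmicutes\tbacteria\tphylum\tFirmicutes
proteo\tbacteria\tphylum\tProteobacteria
ecoli\tproteo\tspecies\tEscherichia coli
stx1\tecoli\tstrain\tE. coli Stx1
stx2\tecoli\tstrain\tE. coli Stx2
"""


@pytest.fixture
def taxonomy_file(tmp_path):
    path = tmp_path / "taxonomy.tsv"
    path.write_text(TOY_TAXONOMY)
    return path
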