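"""Shared fixtures: small simulated datasets and tiny hand-built gene models."""
from __future__ import annotations

import pytest

from nagnag import (
    Genome,
    extract_contexts,
    extract_introns,
    filter_alignments,
    scan_nagnag_sites,
)
from nagnag.io import read_bed12
from nagnag.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A modest simulated dataset (~80 planted sites) shared across tests."""
    out = tmp_path_factory.mktemp("sim_small")
    return simulate_dataset(SimConfig(seed=5, n_genes=60), outdir=out)


@pytest.fixture(scope="session")
def small_scan(small_sim):
    """(genome, introns, sites, contexts) for the small simulated dataset."""
    genome = Genome(small_sim.genome)
    introns = extract_introns(str(small_sim.paths["annotation"]), genome)
    sites = scan_nagnag_sites(introns, genome)
    contexts = extract_contexts(sites, genome)
    return genome, introns, sites, contexts


@pytest.fixture(scope="session")
def small_kept_alignments(small_sim):
    """The small dataset's alignments after quality filtering."""
    alignments = read_bed12(str(small_sim.paths["alignments"]), pool="sanger")
    return filter_alignments(alignments)


def write_gff3(path, rows):
    """rows: (seqid, type, start, end, strand, attrs)."""
    lines = ["##gff-version 3"]
    for seqid, ftype, start, end, strand, attrs in rows:
        lines.append("\t".join([seqid, "test", ftype, str(start), str(end), ".",
                                strand, ".", attrs]))
    path.write_text("\n".join(lines) + "\n")
    return path
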