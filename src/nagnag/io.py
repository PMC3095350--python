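"""Readers and writers for the pipeline's on-disk formats.

Evidence alignments are exchanged as BED12 (blocks from blockSizes /
blockStarts; two optional extra columns 13-14 carry alignment identity
and read-length coverage as fractions) or as a minimal per-read TSV.
Sites, evidence counts and feature matrices travel as TSV; sequence
contexts as FASTA.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .evidence import EvidenceCount, SiteLabel, SpliceAlignment
from .scan import ContextSequence, NagnagSite

EVIDENCE_TSV_HEADER = ["site_id", "n_E", "n_I", "pools", "observed", "training_class"]
READ_TSV_HEADER = ["read_id", "seqid", "strand", "blocks", "identity", "read_coverage", "pool"]


def read_bed12(path, pool: str = "other") -> list[SpliceAlignment]:
    """Parse BED12 (+ optional identity/coverage columns) into alignments."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 line has {len(f)} columns: {line[:80]!r}")
            chrom, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = tuple(
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            identity = float(f[12]) if len(f) > 12 and f[12] != "" else None
            coverage = float(f[13]) if len(f) > 13 and f[13] != "" else None
            out.append(
                SpliceAlignment(read_id=name, seqid=chrom, strand=strand, blocks=blocks,
                                identity=identity, read_coverage=coverage, pool=pool)
            )
    return out


def write_bed12(alignments: Iterable[SpliceAlignment], path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            chrom_start = a.blocks[0][0] - 1
            chrom_end = a.blocks[-1][1]
            sizes = ",".join(str(e - s + 1) for s, e in a.blocks)
            starts = ",".join(str(s - 1 - chrom_start) for s, _ in a.blocks)
            cols = [
                a.seqid, chrom_start, chrom_end, a.read_id, 0, a.strand,
                chrom_start, chrom_end, "0,0,0", len(a.blocks), sizes, starts,
                "" if a.identity is None else f"{a.identity:.4f}",
                "" if a.read_coverage is None else f"{a.read_coverage:.4f}",
            ]
            fh.write("\t".join(str(c) for c in cols) + "\n")


def read_alignment_tsv(path, pool: str = "other") -> list[SpliceAlignment]:
    """Minimal TSV evidence dialect; blocks encoded as ``s1-e1;s2-e2``."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            blocks = tuple(
                tuple(int(x) for x in b.split("-")) for b in row["blocks"].split(";")
            )
            out.append(
                SpliceAlignment(
                    read_id=row["read_id"], seqid=row["seqid"], strand=row["strand"],
                    blocks=blocks,
                    identity=float(row["identity"]) if row.get("identity") else None,
                    read_coverage=float(row["read_coverage"]) if row.get("read_coverage") else None,
                    pool=row.get("pool") or pool,
                )
            )
    return out


def write_alignment_tsv(alignments: Iterable[SpliceAlignment], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(READ_TSV_HEADER)
        for a in alignments:
            blocks = ";".join(f"{s}-{e}" for s, e in a.blocks)
            w.writerow([a.read_id, a.seqid, a.strand, blocks,
                        "" if a.identity is None else a.identity,
                        "" if a.read_coverage is None else a.read_coverage, a.pool])


def write_sites_tsv(sites: Iterable[NagnagSite], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["site_id", "seqid", "strand", "proximal_junction", "distal_junction",
                    "motif", "annotated_acceptor", "gene_id", "transcript_id",
                    "intron_ordinal"])
        for s in sites:
            w.writerow([s.site_id, s.seqid, s.strand, s.proximal_junction,
                        s.distal_junction, s.motif, s.annotated_acceptor,
                        s.intron.gene_id, s.intron.transcript_id, s.intron.ordinal])


def write_contexts_fasta(contexts: Mapping[str, ContextSequence] | Sequence[ContextSequence],
                         path) -> None:
    if isinstance(contexts, Mapping):
        contexts = list(contexts.values())
    with open(path, "w") as fh:
        for c in contexts:
            fh.write(f">{c.site_id}\n{c.seq49}\n")


def read_contexts_fasta(path) -> dict[str, ContextSequence]:
    from Bio import SeqIO

    return {
        rec.id: ContextSequence(site_id=rec.id, seq49=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_evidence_tsv(counts: Mapping[str, EvidenceCount],
                       labels: Mapping[str, SiteLabel], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(EVIDENCE_TSV_HEADER)
        for site_id in counts:
            c = counts[site_id]
            lab = labels.get(site_id)
            pools = ";".join(f"{p}:{e}:{i}" for p, (e, i) in sorted(c.by_pool.items()))
            w.writerow([site_id, c.n_E, c.n_I, pools,
                        lab.observed if lab else "", lab.training_class if lab else ""])


def read_evidence_tsv(path) -> tuple[dict[str, EvidenceCount], dict[str, SiteLabel]]:
    counts: dict[str, EvidenceCount] = {}
    labels: dict[str, SiteLabel] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pools = {}
            if row["pools"]:
                for item in row["pools"].split(";"):
                    p, e, i = item.split(":")
                    pools[p] = [int(e), int(i)]
            counts[row["site_id"]] = EvidenceCount(
                site_id=row["site_id"], n_E=int(row["n_E"]), n_I=int(row["n_I"]),
                by_pool=pools,
            )
            if row.get("observed"):
                labels[row["site_id"]] = SiteLabel(
                    site_id=row["site_id"], observed=row["observed"],
                    training_class=row.get("training_class") or "none",
                )
    return counts, labels


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def ensure_outdir(path, overwrite: bool = False) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
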