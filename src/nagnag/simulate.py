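"""Synthetic genomes, annotations and spliced reads with known truth.

The generator emulates the three inputs the pipeline consumes: a toy
multi-exon genome (FASTA), its gene models (GFF3), and spliced read
alignments (BED12) supporting each acceptor at controlled counts.  A
fraction of introns carries a planted NAGNAG tandem acceptor of known
class with class-dependent sequence signal:

* functional acceptor Ns follow the C > T > A > G preference; dead
  (unused) acceptor Ns are G-enriched, echoing the rarity of functional
  GAG acceptors;
* alternative (EI) sites carry a stronger polypyrimidine tract than
  constitutive ones;
* the ``signal`` knob interpolates linearly between these class
  distributions and a shared background, so 0 gives a null dataset
  (class-independent sequence) and 1 the full planted signal.

Decoy alignments violating exactly one quality filter each (plus
boundary-ending reads that must be ignored at the affected junction)
are emitted with truth tags in their read ids, so filter behaviour is
exactly testable.  Everything is deterministic given the seed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evidence import SpliceAlignment
from .io import write_bed12, write_fasta
from .scan import revcomp

BACKGROUND = {"A": 0.28, "C": 0.22, "G": 0.22, "T": 0.28}
#: N-letter preference at a functional acceptor: C > T > A > G
ACCEPTOR_N = {"A": 0.15, "C": 0.45, "G": 0.05, "T": 0.35}
#: N-letter distribution at a dead (never used) acceptor: G-enriched
DEAD_N = {"A": 0.25, "C": 0.075, "G": 0.60, "T": 0.075}

CLASSES = ("E", "I", "EI")
DECOY_TYPES = ("low_identity", "low_coverage", "single_exon", "long_intron", "boundary")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_genes: int = 150
    introns_per_gene: int = 2
    exon_len: int = 90
    intron_len: int = 90
    intergenic_len: int = 100
    chrom: str = "chr1"
    p_nagnag: float = 0.7  # fraction of acceptors carrying a tandem AG
    class_mix: tuple = (1 / 3, 1 / 3, 1 / 3)  # (pi_E, pi_I, pi_EI)
    signal: float = 1.0  # 0 = null (class-independent sequence)
    ppt_base: float = 0.55  # per-base pyrimidine probability, background
    ppt_const: float = 0.65  # ... at constitutive (E / I) sites
    ppt_strong: float = 0.85  # ... at alternative (EI) sites
    coverage_prob: float = 0.92  # chance a site receives any reads
    mean_reads: float = 14.0  # Poisson mean reads per covered site
    minor_frac_range: tuple = (0.15, 0.40)  # uniform minor-isoform fraction (EI)
    anchor_len: int = 40  # exonic anchor on each side of a junction
    decoys_per_type: int = 5
    read_identity_range: tuple = (0.96, 1.0)
    read_coverage_range: tuple = (0.92, 1.0)

    def __post_init__(self):
        if not np.isclose(sum(self.class_mix), 1.0):
            raise ValueError("class mixture must sum to 1")
        if min(self.class_mix) < 0 or not 0 <= self.signal <= 1:
            raise ValueError("probabilities must be valid")
        min_intron = 2 + 30 + 6  # donor GT + context window + motif
        if self.intron_len < min_intron:
            raise ValueError(f"intron_len must be >= {min_intron}")
        if self.exon_len < max(13, self.anchor_len):
            raise ValueError("exon_len too short for context/anchors")


@dataclass
class PlantedSite:
    """Truth record for one planted tandem acceptor."""

    gene_id: str
    seqid: str
    strand: str
    true_class: str
    annotated_acceptor: str  # proximal | distal
    motif: str
    proximal_junction: int  # genomic, last intronic base of proximal AG
    distal_junction: int
    intron_ordinal: int
    n_reads_E: int = 0
    n_reads_I: int = 0
    minor_fraction: float = np.nan

    @property
    def site_id(self) -> str:
        return f"{self.seqid}:{self.proximal_junction}:{self.strand}"


@dataclass
class SimResult:
    config: SimConfig
    genome: dict  # seqid -> sequence
    alignments: list  # SpliceAlignment, decoys tagged by read_id prefix
    truth: pd.DataFrame  # one row per planted site
    gff_lines: list
    paths: dict = field(default_factory=dict)

    def truth_by_site(self) -> dict:
        return {row.site_id: row for row in self.truth.itertuples()}


def _sample(rng, dist: dict, k: int = 1) -> str:
    letters = sorted(dist)
    p = np.array([dist[b] for b in letters], dtype=float)
    p = p / p.sum()
    picks = rng.choice(len(letters), size=k, p=p)
    return "".join(letters[i] for i in picks)


def _mix(dist: dict, signal: float) -> dict:
    return {b: (1 - signal) * BACKGROUND[b] + signal * dist[b] for b in BACKGROUND}


def _ppt(rng, n: int, py_prob: float) -> str:
    out = []
    for _ in range(n):
        if rng.random() < py_prob:
            out.append("C" if rng.random() < 0.5 else "T")
        else:
            out.append("A" if rng.random() < 0.56 else "G")
    return "".join(out)


@dataclass
class ContextParts:
    """Class-conditional sequence pieces around a planted tandem acceptor."""

    n1: str
    n2: str
    up30: str  # 10 neutral + 20 PPT-shaped nt immediately 5' of the motif
    down10: str

    @property
    def motif(self) -> str:
        return f"{self.n1}AG{self.n2}AG"


def plant_class_signal(true_class: str, rng, config: SimConfig = SimConfig()) -> ContextParts:
    """Draw the class-dependent sequence neighbourhood for one site.

    EI sites get two functional-looking Ns and a strong polypyrimidine
    tract.  E sites use only the proximal acceptor, so their distal N2
    is drawn from the dead (G-enriched) distribution; I sites use only
    the distal acceptor, so their N1 is dead instead.
    """
    s = config.signal
    if true_class == "EI":
        d1, d2 = ACCEPTOR_N, ACCEPTOR_N
        ppt = config.ppt_base + s * (config.ppt_strong - config.ppt_base)
    elif true_class == "E":
        d1, d2 = ACCEPTOR_N, DEAD_N
        ppt = config.ppt_base + s * (config.ppt_const - config.ppt_base)
    elif true_class == "I":
        d1, d2 = DEAD_N, ACCEPTOR_N
        ppt = config.ppt_base + s * (config.ppt_const - config.ppt_base)
    else:
        raise ValueError(f"unknown class {true_class!r}")
    return ContextParts(
        n1=_sample(rng, _mix(d1, s)),
        n2=_sample(rng, _mix(d2, s)),
        up30=_sample(rng, BACKGROUND, 10) + _ppt(rng, 20, ppt),
        down10=_sample(rng, BACKGROUND, 10),
    )


def _patch(seq: str, idx: int, replacement: str) -> str:
    return seq[:idx] + replacement + seq[idx + 1 :]


def _build_gene(rng, cfg: SimConfig):
    """Coding-sense exon/intron strings plus local site plans.

    Local coordinates are 1-based along the coding-sense gene sequence.
    Patches guarantee that the only AGs within +/-3 of an annotated
    acceptor are the planted ones (so scanner output equals truth).
    """
    n_introns = cfg.introns_per_gene
    exons = [_sample(rng, BACKGROUND, cfg.exon_len)]
    introns = []
    plans = []  # (ordinal, has_nagnag, cls, annotated, motif, tail_len_in_intron)
    for k in range(n_introns):
        has = rng.random() < cfg.p_nagnag
        if has:
            cls = CLASSES[rng.choice(3, p=np.asarray(cfg.class_mix))]
            if cls == "E":
                annotated = "proximal"
            elif cls == "I":
                annotated = "distal"
            else:
                annotated = "proximal" if rng.random() < 0.5 else "distal"
            parts = plant_class_signal(cls, rng, cfg)
            # Patches keep the planted tandem the only AG pair within +/-3 of
            # the annotated acceptor.  Both are applied regardless of which
            # acceptor is annotated, so the patch distribution is identical
            # across classes (no spurious class signal at signal=0).
            up30 = parts.up30
            if up30[-2:] == "AG":  # would create a second, upstream tandem AG
                up30 = _patch(up30, 29, "C")
            down10 = parts.down10
            if down10[1:3] == "AG":  # would create a NAGNAGNAG triple
                down10 = _patch(down10, 2, "C")
            if annotated == "distal":
                tail = parts.motif  # whole motif intronic
                exon = down10 + _sample(rng, BACKGROUND, cfg.exon_len - 10)
            else:
                tail = parts.n1 + "AG"  # N2AG sits at the exon start
                exon = parts.n2 + "AG" + down10 + _sample(rng, BACKGROUND, cfg.exon_len - 13)
            filler = cfg.intron_len - 2 - 30 - len(tail)
            intron = "GT" + _sample(rng, BACKGROUND, filler) + up30 + tail
            motif = parts.motif
        else:
            cls = annotated = motif = None
            ppt20 = _ppt(rng, 20, cfg.ppt_base)
            accn = _sample(rng, ACCEPTOR_N)
            if ppt20[-2:] == "AG":
                ppt20 = _patch(ppt20, 19, "C")
            filler = cfg.intron_len - 2 - 20 - 3
            intron = "GT" + _sample(rng, BACKGROUND, filler) + ppt20 + accn + "AG"
            exon = _sample(rng, BACKGROUND, cfg.exon_len)
            if exon[1:3] == "AG":  # keep plain acceptors plain
                exon = _patch(exon, 2, "C")
        introns.append(intron)
        exons.append(exon)
        plans.append((k + 1, has, cls, annotated, motif))
    return exons, introns, plans


def simulate_dataset(config: SimConfig, outdir=None) -> SimResult:
    """Generate genome + annotation + alignments + truth table.

    Deterministic given ``config.seed``; with ``outdir`` set, writes
    genome.fasta, annotation.gff3, alignments.bed, truth.tsv and
    config.json there.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chrom_parts: list[str] = []
    cursor = 0  # 0-based length so far
    gff = ["##gff-version 3"]
    sites: list[PlantedSite] = []
    # gene_id -> (strand, intron genomic spans in coding order, plans)
    gene_meta: dict[str, tuple] = {}

    for g in range(cfg.n_genes):
        gene_id = f"gene{g + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        exons, introns, plans = _build_gene(rng, cfg)
        pieces, local_exons, local_introns = [], [], []
        local = 0
        for i, ex in enumerate(exons):
            pieces.append(ex)
            local_exons.append((local + 1, local + len(ex)))
            local += len(ex)
            if i < len(introns):
                pieces.append(introns[i])
                local_introns.append((local + 1, local + len(introns[i])))
                local += len(introns[i])
        gene_seq = "".join(pieces)
        gene_len = len(gene_seq)

        chrom_parts.append(_sample(rng, BACKGROUND, cfg.intergenic_len))
        cursor += cfg.intergenic_len
        offset = cursor  # gene occupies genomic [offset+1, offset+gene_len]
        chrom_parts.append(gene_seq if strand == "+" else revcomp(gene_seq))
        cursor += gene_len

        def to_genomic(x: int) -> int:
            return offset + x if strand == "+" else offset + gene_len - x + 1

        def span(lo: int, hi: int) -> tuple[int, int]:
            a, b = to_genomic(lo), to_genomic(hi)
            return (a, b) if a <= b else (b, a)

        g_start, g_end = span(1, gene_len)
        gff.append("\t".join(map(str, [cfg.chrom, "sim", "gene", g_start, g_end, ".",
                                       strand, ".", f"ID={gene_id}"])))
        t_id = f"t{g + 1:05d}"
        gff.append("\t".join(map(str, [cfg.chrom, "sim", "mRNA", g_start, g_end, ".",
                                       strand, ".", f"ID={t_id};Parent={gene_id}"])))
        exon_spans = sorted(span(a, b) for a, b in local_exons)
        for j, (a, b) in enumerate(exon_spans, 1):
            gff.append("\t".join(map(str, [cfg.chrom, "sim", "exon", a, b, ".", strand,
                                           ".", f"ID={t_id}.e{j};Parent={t_id}"])))

        intron_spans = [span(a, b) for a, b in local_introns]
        gene_meta[gene_id] = (strand, intron_spans, plans)

        for (ordinal, has, cls, annotated, motif), (ia, ib) in zip(plans, local_introns):
            if not has:
                continue
            # coding-local junction of the annotated acceptor = last intronic base
            if annotated == "distal":
                distal_l, proximal_l = ib, ib - 3
            else:
                proximal_l, distal_l = ib, ib + 3
            sites.append(PlantedSite(
                gene_id=gene_id, seqid=cfg.chrom, strand=strand, true_class=cls,
                annotated_acceptor=annotated, motif=motif,
                proximal_junction=to_genomic(proximal_l),
                distal_junction=to_genomic(distal_l),
                intron_ordinal=ordinal,
            ))
    chrom_parts.append(_sample(rng, BACKGROUND, cfg.intergenic_len))
    genome = {cfg.chrom: "".join(chrom_parts)}

    alignments: list[SpliceAlignment] = []
    read_no = 0

    def emit_read(site: PlantedSite, which: str, prefix="r", identity=None, coverage=None):
        nonlocal read_no
        read_no += 1
        j = site.proximal_junction if which == "E" else site.distal_junction
        meta = _site_meta(gene_meta, site)
        gs, ge = meta  # genomic span of the site's intron
        a = cfg.anchor_len
        if site.strand == "+":
            blocks = ((gs - a, gs - 1), (j + 1, j + a))
        else:
            blocks = ((j - a, j - 1), (ge + 1, ge + a))
        ident = identity if identity is not None else round(rng.uniform(*cfg.read_identity_range), 4)
        cov = coverage if coverage is not None else round(rng.uniform(*cfg.read_coverage_range), 4)
        alignments.append(SpliceAlignment(
            read_id=f"{prefix}{read_no:06d}", seqid=site.seqid, strand=site.strand,
            blocks=blocks, identity=ident, read_coverage=cov, pool="sanger"))

    for site in sites:
        if rng.random() >= cfg.coverage_prob:
            continue
        n = int(rng.poisson(cfg.mean_reads))
        if n == 0:
            continue
        if site.true_class == "E":
            n_e, n_i = n, 0
        elif site.true_class == "I":
            n_e, n_i = 0, n
        else:
            f = rng.uniform(*cfg.minor_frac_range)
            minor = int(rng.binomial(n, f))
            site.minor_fraction = f
            if site.annotated_acceptor == "proximal":
                n_e, n_i = n - minor, minor
            else:
                n_e, n_i = minor, n - minor
        site.n_reads_E, site.n_reads_I = n_e, n_i
        for _ in range(n_e):
            emit_read(site, "E")
        for _ in range(n_i):
            emit_read(site, "I")

    _emit_decoys(cfg, rng, sites, gene_meta, genome, alignments)

    truth = pd.DataFrame([
        {**dataclasses.asdict(s), "site_id": s.site_id} for s in sites
    ])
    result = SimResult(config=cfg, genome=genome, alignments=alignments,
                       truth=truth, gff_lines=gff)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out / "genome.fasta")
        (out / "annotation.gff3").write_text("\n".join(gff) + "\n")
        write_bed12(alignments, out / "alignments.bed")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        (out / "config.json").write_text(
            json.dumps(dataclasses.asdict(cfg), indent=1, default=list) + "\n")
        result.paths = {
            "genome": out / "genome.fasta",
            "annotation": out / "annotation.gff3",
            "alignments": out / "alignments.bed",
            "truth": out / "truth.tsv",
        }
    return result


def _site_meta(gene_meta, site: PlantedSite) -> tuple[int, int]:
    """Genomic span (start, end) of the intron hosting a planted site."""
    return gene_meta[site.gene_id][1][site.intron_ordinal - 1]


def _emit_decoys(cfg, rng, sites, gene_meta, genome, alignments):
    """Decoy alignments, each violating exactly one rule, truth-tagged."""
    if not sites:
        return
    chrom_len = len(genome[cfg.chrom])
    a = cfg.anchor_len
    k = 0

    def pick_site():
        return sites[int(rng.integers(len(sites)))]

    for _ in range(cfg.decoys_per_type):
        k += 1
        site = pick_site()
        gs, ge = _site_meta(gene_meta, site)
        j = site.proximal_junction
        if site.strand == "+":
            blocks = ((gs - a, gs - 1), (j + 1, j + a))
        else:
            blocks = ((j - a, j - 1), (ge + 1, ge + a))
        alignments.append(SpliceAlignment(
            read_id=f"decoy_low_identity_{k}", seqid=site.seqid, strand=site.strand,
            blocks=blocks, identity=0.90, read_coverage=0.96, pool="sanger"))
        alignments.append(SpliceAlignment(
            read_id=f"decoy_low_coverage_{k}", seqid=site.seqid, strand=site.strand,
            blocks=blocks, identity=0.98, read_coverage=0.80, pool="sanger"))
        # single-exon alignment: one block inside the upstream exon
        if site.strand == "+":
            single = ((gs - a, gs - 1),)
        else:
            single = ((ge + 1, ge + a),)
        alignments.append(SpliceAlignment(
            read_id=f"decoy_single_exon_{k}", seqid=site.seqid, strand=site.strand,
            blocks=single, identity=0.99, read_coverage=0.97, pool="sanger"))
        # oversized intron (only if the chromosome can host the gap)
        gap = 21000  # > the 20,000-nt alignment filter
        if chrom_len > gap + 2 * a + 10:
            start = int(rng.integers(1, chrom_len - gap - 2 * a - 5))
            alignments.append(SpliceAlignment(
                read_id=f"decoy_long_intron_{k}", seqid=cfg.chrom, strand="+",
                blocks=((start, start + a - 1), (start + a + gap, start + 2 * a + gap - 1)),
                identity=0.99, read_coverage=0.97, pool="sanger"))

    # boundary-ending reads: a genuine junction elsewhere, but the alignment
    # terminates exactly at a tandem junction (must be ignored at that site)
    candidates = [
        s for s in sites
        if s.strand == "+" and s.intron_ordinal >= 2
    ]
    for i in range(min(cfg.decoys_per_type, len(candidates))):
        site = candidates[int(rng.integers(len(candidates)))]
        _, intron_spans, plans = gene_meta[site.gene_id]
        prev_ia, prev_ib = intron_spans[site.intron_ordinal - 2]
        prev_plan = plans[site.intron_ordinal - 2]
        if prev_plan[1]:  # previous intron hosts a NAGNAG; its junction would count
            continue
        blocks = ((prev_ia - a, prev_ia - 1), (prev_ib + 1, site.proximal_junction))
        alignments.append(SpliceAlignment(
            read_id=f"decoy_boundary_{i + 1}", seqid=site.seqid, strand="+",
            blocks=blocks, identity=0.99, read_coverage=0.97, pool="sanger"))


def sample_labeled_contexts(config: SimConfig, n_per_class: int, rng=None):
    """Draw bare labelled 49-nt contexts straight from the signal model.

    Convenience for classifier experiments that do not need a genome:
    returns (contexts list, labels dict site_id -> class).
    """
    from .scan import ContextSequence

    rng = np.random.default_rng(config.seed) if rng is None else rng
    contexts, labels = [], {}
    i = 0
    for cls in CLASSES:
        for _ in range(n_per_class):
            i += 1
            parts = plant_class_signal(cls, rng, config)
            exon3 = _sample(rng, BACKGROUND, 3)
            seq49 = exon3 + parts.up30 + parts.motif + parts.down10
            sid = f"ctx{i:05d}"
            contexts.append(ContextSequence(site_id=sid, seq49=seq49))
            labels[sid] = cls
    return contexts, labels
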