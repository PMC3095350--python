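"""Intron extraction and discovery of NAGNAG tandem 3' splice acceptors.

A NAGNAG tandem acceptor is a pair of AG dinucleotides three nucleotides
apart at the 3' end of an intron.  Splicing at the intron-proximal AG
leaves the second NAG in the mRNA (the "E", exonic variant); splicing at
the intron-distal AG removes the whole NAGNAG (the "I", intronic
variant).  This module finds every annotated acceptor with an AG three
positions up- or downstream and extracts the 49-nt sequence context used
downstream for feature extraction.

Coordinates are 1-based inclusive throughout (GFF3 convention).  A
junction coordinate denotes the last intronic base of the acceptor AG.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from pyfaidx import Fasta

log = logging.getLogger(__name__)

SENTINEL = "X"
_COMPLEMENT = str.maketrans("ACGTNXacgtnx", "TGCANXtgcanx")

#: regexp a valid tandem-acceptor motif must match (N1 A G N2 A G)
NAGNAG_RE = re.compile(r"[ACGT]AG[ACGT]AG")

#: GFF3 feature types treated as transcripts
TRANSCRIPT_TYPES = ("mRNA", "transcript")


def revcomp(seq: str) -> str:
    """Reverse complement; the pad sentinel is self-complementary."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """Random access to genome sequence from a FASTA path or a dict.

    ``fetch`` returns uppercase sequence, 1-based inclusive, padding with
    the ``X`` sentinel beyond contig boundaries so callers get windows of
    the exact length they asked for.
    """

    def __init__(self, source):
        if isinstance(source, Genome):
            self._fa, self._dict = source._fa, source._dict
        elif isinstance(source, (str, Path)):
            self._fa = Fasta(str(source), as_raw=True, sequence_always_upper=True)
            self._dict = None
        elif isinstance(source, Mapping):
            self._dict = {k: str(v).upper() for k, v in source.items()}
            self._fa = None
        else:
            raise TypeError(f"cannot open genome from {type(source)!r}")

    def __contains__(self, seqid: str) -> bool:
        return seqid in (self._dict if self._dict is not None else self._fa)

    def keys(self):
        return list(self._dict) if self._dict is not None else list(self._fa.keys())

    def length(self, seqid: str) -> int:
        if seqid not in self:
            raise ValueError(f"sequence {seqid!r} not present in genome FASTA")
        if self._dict is not None:
            return len(self._dict[seqid])
        return len(self._fa[seqid])

    def fetch(self, seqid: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end]`` on the given strand, X-padded."""
        n = self.length(seqid)
        lo, hi = max(start, 1), min(end, n)
        if lo > hi:
            core = ""
        elif self._dict is not None:
            core = self._dict[seqid][lo - 1 : hi]
        else:
            core = str(self._fa[seqid][lo - 1 : hi]).upper()
        seq = SENTINEL * (lo - start) + core + SENTINEL * (end - hi)
        return revcomp(seq) if strand == "-" else seq

    def base_frequencies(self) -> dict:
        """Genome-wide mononucleotide frequencies over A/C/G/T."""
        counts = {b: 0 for b in "ACGT"}
        for seqid in self.keys():
            seq = self.fetch(seqid, 1, self.length(seqid))
            for b in counts:
                counts[b] += seq.count(b)
        total = sum(counts.values())
        if total == 0:
            raise ValueError("genome contains no A/C/G/T bases")
        return {b: c / total for b, c in counts.items()}


@dataclass(frozen=True)
class Intron:
    """One intron derived from two consecutive exons of a transcript."""

    gene_id: str
    transcript_id: str
    seqid: str
    start: int  # 1-based inclusive, genomic
    end: int
    strand: str
    ordinal: int  # 1-based index from the transcription start
    canonical_acceptor: bool = True  # coding-strand sequence ends in AG

    def __post_init__(self):
        if self.end < self.start + 3:
            raise ValueError(f"intron {self.start}-{self.end} too short")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class NagnagSite:
    """A tandem acceptor anchored to an annotated intron.

    ``proximal_junction`` / ``distal_junction`` are the genomic
    coordinates of the last intronic base of each alternative acceptor
    AG; on the coding-strand axis the distal junction lies 3 nt
    downstream of the proximal one.
    """

    site_id: str
    intron: Intron
    motif: str  # 6-mer N1 A G N2 A G, mRNA sense
    proximal_junction: int
    distal_junction: int
    annotated_acceptor: str  # "proximal" | "distal"

    @property
    def seqid(self) -> str:
        return self.intron.seqid

    @property
    def strand(self) -> str:
        return self.intron.strand

    @property
    def has_gag(self) -> bool:
        """True if either NAG of the motif is GAG (rarely functional)."""
        return self.motif[0:3] == "GAG" or self.motif[3:6] == "GAG"

    def __post_init__(self):
        if not NAGNAG_RE.fullmatch(self.motif):
            raise ValueError(f"invalid NAGNAG motif {self.motif!r}")
        step = 3 if self.strand == "+" else -3
        if self.distal_junction - self.proximal_junction != step:
            raise ValueError("junctions must be 3 nt apart in transcript orientation")


# 49-nt context block layout (0-based, half-open):
# [0,3) last 3 nt of upstream exon; [3,33) 30 intronic nt immediately
# upstream of the motif; [33,39) the NAGNAG; [39,49) 10 nt downstream.
CONTEXT_BLOCKS = {"exon": (0, 3), "upstream": (3, 33), "motif": (33, 39), "downstream": (39, 49)}
CONTEXT_LEN = 49


@dataclass(frozen=True)
class ContextSequence:
    """The 49-position mRNA-sense sequence context of a tandem acceptor."""

    site_id: str
    seq49: str

    def __post_init__(self):
        if len(self.seq49) != CONTEXT_LEN:
            raise ValueError(f"context must be {CONTEXT_LEN} nt, got {len(self.seq49)}")

    @property
    def motif(self) -> str:
        return self.seq49[33:39]

    def block(self, name: str) -> str:
        lo, hi = CONTEXT_BLOCKS[name]
        return self.seq49[lo:hi]


def open_annotation(annotation) -> gffutils.FeatureDB:
    """Return a gffutils database for a GFF3 path (or pass one through)."""
    if isinstance(annotation, gffutils.FeatureDB):
        return annotation
    return gffutils.create_db(
        str(annotation), ":memory:", merge_strategy="create_unique", keep_order=True
    )


def extract_introns(annotation, genome) -> list[Intron]:
    """Derive introns from the exon structure of every transcript.

    Transcripts with fewer than two exons yield no introns.  Introns
    whose coding-strand sequence does not end in AG are returned with
    ``canonical_acceptor=False`` rather than dropped.  Gaps shorter than
    4 nt (no room for donor + acceptor) are skipped with a warning.
    """
    db = open_annotation(annotation)
    genome = Genome(genome)
    introns: list[Intron] = []
    transcripts = []
    for ft in TRANSCRIPT_TYPES:
        transcripts.extend(db.features_of_type(ft))
    transcripts.sort(key=lambda t: (t.seqid, t.start, t.id))
    for t in transcripts:
        exons = sorted(db.children(t, featuretype="exon"), key=lambda e: e.start)
        if len(exons) < 2:
            continue
        if t.seqid not in genome:
            raise ValueError(f"sequence {t.seqid!r} not present in genome FASTA")
        gene_id = t.attributes.get("Parent", [t.id])[0]
        gaps = [(a.end + 1, b.start - 1) for a, b in zip(exons, exons[1:])]
        if t.strand == "-":
            gaps = gaps[::-1]  # ordinal counts from the transcription start
        for ordinal, (s, e) in enumerate(gaps, start=1):
            if e < s + 3:
                log.warning("skipping degenerate intron %s:%d-%d of %s", t.seqid, s, e, t.id)
                continue
            if t.strand == "+":
                acc = genome.fetch(t.seqid, e - 1, e, "+")
            else:
                acc = genome.fetch(t.seqid, s, s + 1, "-")
            introns.append(
                Intron(
                    gene_id=gene_id,
                    transcript_id=t.id,
                    seqid=t.seqid,
                    start=s,
                    end=e,
                    strand=t.strand,
                    ordinal=ordinal,
                    canonical_acceptor=(acc == "AG"),
                )
            )
    return introns


def _sites_for_intron(intron: Intron, genome: Genome) -> Iterable[NagnagSite]:
    """Emit 0, 1 or 2 tandem-acceptor configurations for one intron.

    Checks the +/-3 window around the annotated acceptor AG: an AG
    ending 3 nt inside the intron makes the annotated acceptor distal;
    an AG at downstream-exon positions +2/+3 makes it proximal.  A
    NAGNAGNAG triple therefore yields two overlapping sites.
    """
    if intron.strand == "+":
        last6 = genome.fetch(intron.seqid, intron.end - 5, intron.end, "+")
        exon3 = genome.fetch(intron.seqid, intron.end + 1, intron.end + 3, "+")
    else:
        last6 = genome.fetch(intron.seqid, intron.start, intron.start + 5, "-")
        exon3 = genome.fetch(intron.seqid, intron.start - 3, intron.start - 1, "-")
    configs = []
    if last6[1:3] == "AG":  # AG ending 3 nt upstream: annotated acceptor is distal
        if intron.strand == "+":
            prox, dist = intron.end - 3, intron.end
        else:
            prox, dist = intron.start + 3, intron.start
        configs.append((last6, prox, dist, "distal"))
    if exon3[1:3] == "AG":  # AG at exon +2/+3: annotated acceptor is proximal
        if intron.strand == "+":
            prox, dist = intron.end, intron.end + 3
        else:
            prox, dist = intron.start, intron.start - 3
        configs.append((last6[3:] + exon3, prox, dist, "proximal"))
    for motif, prox, dist, which in configs:
        if SENTINEL in motif:
            log.warning("site at %s:%d extends beyond contig boundary; skipped",
                        intron.seqid, prox)
            continue
        if not NAGNAG_RE.fullmatch(motif):
            continue  # non-ACGT letter at an N position
        site_id = f"{intron.seqid}:{prox}:{intron.strand}"
        yield NagnagSite(
            site_id=site_id,
            intron=intron,
            motif=motif,
            proximal_junction=prox,
            distal_junction=dist,
            annotated_acceptor=which,
        )


def scan_nagnag_sites(introns: Iterable[Intron], genome) -> list[NagnagSite]:
    """Identify every NAGNAG tandem acceptor among annotated introns.

    Non-canonical introns (acceptor not AG) are skipped here; they are
    flagged by :func:`extract_introns`.  Sites shared by several
    transcripts are deduplicated on (seqid, strand, proximal junction),
    keeping the representative with the lowest intron ordinal.
    """
    genome = Genome(genome)
    best: dict[tuple, NagnagSite] = {}
    ordered = sorted(introns, key=lambda i: (i.seqid, i.start, i.end, i.transcript_id))
    for intron in ordered:
        if not intron.canonical_acceptor:
            continue
        for site in _sites_for_intron(intron, genome):
            key = (site.seqid, site.strand, site.proximal_junction)
            if key not in best or site.intron.ordinal < best[key].intron.ordinal:
                best[key] = site
    return sorted(best.values(), key=lambda s: (s.seqid, s.proximal_junction, s.strand))


def extract_context(site: NagnagSite, genome) -> ContextSequence:
    """Extract the 49-nt mRNA-sense context around a tandem acceptor.

    The intronic window upstream of the motif is confined to the intron
    and left-padded with ``X`` when the intron is too short; flanking
    exon/contig shortfall is padded the same way.
    """
    genome = Genome(genome)
    intron = site.intron
    if site.strand == "+":
        motif_lo = site.distal_junction - 5
        exon3 = genome.fetch(site.seqid, intron.start - 3, intron.start - 1, "+")
        up_lo = max(motif_lo - 30, intron.start)
        up = genome.fetch(site.seqid, up_lo, motif_lo - 1, "+") if up_lo <= motif_lo - 1 else ""
        motif = genome.fetch(site.seqid, motif_lo, site.distal_junction, "+")
        down = genome.fetch(site.seqid, site.distal_junction + 1, site.distal_junction + 10, "+")
    else:
        motif_hi = site.distal_junction + 5
        exon3 = genome.fetch(site.seqid, intron.end + 1, intron.end + 3, "-")
        up_hi = min(motif_hi + 30, intron.end)
        up = genome.fetch(site.seqid, motif_hi + 1, up_hi, "-") if motif_hi + 1 <= up_hi else ""
        motif = genome.fetch(site.seqid, site.distal_junction, motif_hi, "-")
        down = genome.fetch(site.seqid, site.distal_junction - 10, site.distal_junction - 1, "-")
    up = SENTINEL * (30 - len(up)) + up
    seq49 = exon3 + up + motif + down
    if motif != site.motif:
        raise ValueError(f"genome motif {motif!r} disagrees with site motif {site.motif!r}")
    return ContextSequence(site_id=site.site_id, seq49=seq49)


def extract_contexts(sites: Iterable[NagnagSite], genome) -> dict[str, ContextSequence]:
    genome = Genome(genome)
    return {s.site_id: extract_context(s, genome) for s in sites}
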