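"""Junction-evidence adjudication at NAGNAG tandem acceptors.

Spliced transcript alignments (ESTs, 454-style reads, ...) are filtered
for quality, their intron gaps are matched against the two alternative
junctions of each tandem acceptor, and each site is labelled E
(proximal only), I (distal only), EI (both, i.e. alternative splicing)
or uncovered.  Stricter read-support criteria select the sites reliable
enough to train a classifier on, and evidence pools (e.g. Sanger + 454)
can be merged per site.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .scan import NagnagSite

log = logging.getLogger(__name__)

OBSERVED_LABELS = ("E", "I", "EI", "uncovered")
TRAINING_CLASSES = ("E", "I", "EI", "none")


def round_half_up(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """``100*k/n`` rounded half-up — the convention for printed tallies."""
    if denominator == 0:
        return 0.0
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-ndigits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FilterParams:
    """Alignment quality filters applied before any junction counting."""

    min_identity: float = 0.95
    min_read_coverage: float = 0.90
    max_intron: int = 20000
    boundary_slack: int = 3

    def __post_init__(self):
        if not (0 <= self.min_identity <= 1 and 0 <= self.min_read_coverage <= 1):
            raise ValueError("identity/coverage thresholds must be fractions")
        if self.max_intron <= 0 or self.boundary_slack < 0:
            raise ValueError("max_intron must be positive, boundary_slack non-negative")


@dataclass(frozen=True)
class TrainingCriteria:
    """Read-support thresholds for reliably labelled training sites."""

    min_constitutive_reads: int = 10
    min_reads_per_variant: int = 2
    min_minor_fraction: float = 0.10


@dataclass(frozen=True)
class SpliceAlignment:
    """A spliced alignment: ordered blocks whose gaps are candidate introns."""

    read_id: str
    seqid: str
    strand: str
    blocks: tuple  # ((start, end), ...) 1-based inclusive, sorted
    identity: float | None = None
    read_coverage: float | None = None
    pool: str = "other"

    def __post_init__(self):
        for (a, b), (c, d) in zip(self.blocks, self.blocks[1:]):
            if c <= b:
                raise ValueError(f"blocks of {self.read_id} overlap or are unsorted")

    def gaps(self) -> list[tuple[int, int]]:
        return [(a[1] + 1, b[0] - 1) for a, b in zip(self.blocks, self.blocks[1:])]

    @property
    def aln_start(self) -> int:
        return self.blocks[0][0]

    @property
    def aln_end(self) -> int:
        return self.blocks[-1][1]


@dataclass
class EvidenceCount:
    """Per-site support counts for the proximal (E) and distal (I) acceptor."""

    site_id: str
    n_E: int = 0
    n_I: int = 0
    by_pool: dict = field(default_factory=dict)  # pool -> [n_E, n_I]

    def __post_init__(self):
        if self.n_E < 0 or self.n_I < 0:
            raise ValueError("evidence counts must be non-negative")
        if not self.by_pool and (self.n_E or self.n_I):
            self.by_pool = {"other": [self.n_E, self.n_I]}
        pe = sum(v[0] for v in self.by_pool.values())
        pi = sum(v[1] for v in self.by_pool.values())
        if self.by_pool and (pe != self.n_E or pi != self.n_I):
            raise ValueError(f"pool breakdown of {self.site_id} does not sum to totals")

    @property
    def total(self) -> int:
        return self.n_E + self.n_I


@dataclass(frozen=True)
class SiteLabel:
    site_id: str
    observed: str  # E | I | EI | uncovered
    training_class: str = "none"  # E | I | EI | none
    criteria_trace: str = ""


def filter_alignments(
    alignments: Iterable[SpliceAlignment], params: FilterParams = FilterParams()
) -> list[SpliceAlignment]:
    """Keep multi-block alignments passing identity/coverage/intron-size filters.

    Single-block ("single exon") alignments carry no junction and are
    discarded; alignments missing quality fields are rejected with the
    reason logged.
    """
    kept = []
    for aln in alignments:
        reason = None
        if len(aln.blocks) < 2:
            reason = "single_exon"
        elif aln.identity is None or aln.read_coverage is None:
            reason = "missing_quality_fields"
        elif aln.identity < params.min_identity:
            reason = "low_identity"
        elif aln.read_coverage < params.min_read_coverage:
            reason = "low_read_coverage"
        elif any(hi - lo + 1 > params.max_intron for lo, hi in aln.gaps()):
            reason = "oversized_intron"
        if reason:
            log.debug("rejected %s: %s", aln.read_id, reason)
        else:
            kept.append(aln)
    return kept


def _vote(site: NagnagSite, aln: SpliceAlignment, params: FilterParams) -> str | None:
    """Which acceptor (if any) one filtered alignment supports at a site.

    An alignment whose terminal boundary (its genomic start or end — an
    alignment end, not a splice junction) lies within ``boundary_slack``
    of either junction is ambiguous here and contributes nothing at this
    site, though its junctions still count elsewhere.
    """
    if aln.seqid != site.seqid:
        return None
    junctions = (site.proximal_junction, site.distal_junction)
    for terminus in (aln.aln_start, aln.aln_end):
        if min(abs(terminus - j) for j in junctions) <= params.boundary_slack:
            return None
    for lo, hi in aln.gaps():
        junction = hi if site.strand == "+" else lo
        if junction == site.proximal_junction:
            return "E"
        if junction == site.distal_junction:
            return "I"
    return None


def count_acceptor_support(
    site: NagnagSite,
    alignments: Iterable[SpliceAlignment],
    params: FilterParams = FilterParams(),
) -> EvidenceCount:
    """Count reads supporting each acceptor; each read counts at most once."""
    count = EvidenceCount(site_id=site.site_id)
    seen: set[str] = set()
    for aln in alignments:
        if aln.read_id in seen:
            continue
        v = _vote(site, aln, params)
        if v is None:
            continue
        seen.add(aln.read_id)
        slot = count.by_pool.setdefault(aln.pool, [0, 0])
        if v == "E":
            count.n_E += 1
            slot[0] += 1
        else:
            count.n_I += 1
            slot[1] += 1
    return count


def count_support_bulk(
    sites: Sequence[NagnagSite],
    alignments: Iterable[SpliceAlignment],
    params: FilterParams = FilterParams(),
) -> dict[str, EvidenceCount]:
    """Junction-indexed counting over many sites (single pass over reads)."""
    counts = {s.site_id: EvidenceCount(site_id=s.site_id) for s in sites}
    jmap: dict[tuple, list] = {}
    bmap: dict[tuple, list] = {}
    for s in sites:
        jmap.setdefault((s.seqid, s.strand, s.proximal_junction), []).append((s, "E"))
        jmap.setdefault((s.seqid, s.strand, s.distal_junction), []).append((s, "I"))
        for j in (s.proximal_junction, s.distal_junction):
            for d in range(-params.boundary_slack, params.boundary_slack + 1):
                bmap.setdefault((s.seqid, j + d), []).append(s.site_id)
    for aln in alignments:
        excluded: set[str] = set()
        for terminus in (aln.aln_start, aln.aln_end):
            excluded.update(bmap.get((aln.seqid, terminus), ()))
        voted: set[str] = set()
        for lo, hi in aln.gaps():
            for strand, junction in (("+", hi), ("-", lo)):
                for site, which in jmap.get((aln.seqid, strand, junction), ()):
                    if site.site_id in excluded or site.site_id in voted:
                        continue
                    voted.add(site.site_id)
                    c = counts[site.site_id]
                    slot = c.by_pool.setdefault(aln.pool, [0, 0])
                    if which == "E":
                        c.n_E += 1
                        slot[0] += 1
                    else:
                        c.n_I += 1
                        slot[1] += 1
    return counts


def label_site(count: EvidenceCount) -> SiteLabel:
    """Observed splicing outcome from junction support counts."""
    if count.n_E < 0 or count.n_I < 0:
        raise ValueError("negative evidence counts")
    if count.n_E > 0 and count.n_I > 0:
        obs = "EI"
    elif count.n_E > 0:
        obs = "E"
    elif count.n_I > 0:
        obs = "I"
    else:
        obs = "uncovered"
    return SiteLabel(site_id=count.site_id, observed=obs,
                     criteria_trace=f"n_E={count.n_E},n_I={count.n_I}")


def training_class(count: EvidenceCount,
                   criteria: TrainingCriteria = TrainingCriteria()) -> str:
    """Training label under the strict support criteria, or ``none``.

    Constitutive: one variant with >= min_constitutive_reads reads and the
    other with 0.  Alternative: >= min_reads_per_variant reads for each
    variant and minor fraction >= min_minor_fraction.
    """
    if count.n_E >= criteria.min_constitutive_reads and count.n_I == 0:
        return "E"
    if count.n_I >= criteria.min_constitutive_reads and count.n_E == 0:
        return "I"
    if (
        count.n_E >= criteria.min_reads_per_variant
        and count.n_I >= criteria.min_reads_per_variant
        and min(count.n_E, count.n_I) / count.total >= criteria.min_minor_fraction
    ):
        return "EI"
    return "none"


def select_training_set(
    counts: Iterable[EvidenceCount], criteria: TrainingCriteria = TrainingCriteria()
) -> list[SiteLabel]:
    """Attach observed and training labels to every counted site."""
    out = []
    for c in counts:
        lab = label_site(c)
        tc = training_class(c, criteria)
        out.append(replace(lab, training_class=tc,
                           criteria_trace=lab.criteria_trace + f",training={tc}"))
    return out


def merge_evidence(a: EvidenceCount, b: EvidenceCount) -> EvidenceCount:
    """Element-wise sum of two evidence pools for the same site."""
    if a.site_id != b.site_id:
        raise ValueError(f"cannot merge evidence for {a.site_id!r} and {b.site_id!r}")
    pools: dict[str, list] = {}
    for src in (a, b):
        for pool, (e, i) in src.by_pool.items():
            slot = pools.setdefault(pool, [0, 0])
            slot[0] += e
            slot[1] += i
    return EvidenceCount(site_id=a.site_id, n_E=a.n_E + b.n_E, n_I=a.n_I + b.n_I,
                         by_pool=pools)


@dataclass
class SummaryReport:
    """Coverage accounting over labelled tandem acceptors.

    Percentages are of covered sites, rounded half-up to one decimal.
    The GAG subset covers motifs with GAG as either NAG — acceptors that
    are only rarely functional.
    """

    n_sites: int = 0
    n_covered: int = 0
    n_E: int = 0
    n_I: int = 0
    n_EI: int = 0
    n_uncovered: int = 0
    n_training: int = 0
    gag_total: int = 0
    gag_covered: int = 0
    gag_EI: int = 0

    @property
    def pct_E(self) -> float:
        return round_half_up(self.n_E, self.n_covered)

    @property
    def pct_I(self) -> float:
        return round_half_up(self.n_I, self.n_covered)

    @property
    def pct_EI(self) -> float:
        return round_half_up(self.n_EI, self.n_covered)

    @property
    def pct_gag_EI(self) -> float:
        return round_half_up(self.gag_EI, self.gag_covered)

    def to_text(self) -> str:
        lines = [
            f"tandem acceptor sites: {self.n_sites}",
            f"covered by evidence:   {self.n_covered}",
            f"  E  (proximal only):  {self.n_E} ({self.pct_E}%)",
            f"  I  (distal only):    {self.n_I} ({self.pct_I}%)",
            f"  EI (alternative):    {self.n_EI} ({self.pct_EI}%)",
            f"uncovered:             {self.n_uncovered}",
            f"training-eligible:     {self.n_training}",
            f"GAG-containing motifs: {self.gag_total} "
            f"(covered {self.gag_covered}, alternative {self.gag_EI} = {self.pct_gag_EI}%)",
        ]
        return "\n".join(lines)


def summarize_labels(
    labels: Iterable[SiteLabel], sites: Mapping[str, NagnagSite] | Sequence[NagnagSite]
) -> SummaryReport:
    """Tally observed labels, with the GAG-containing subset broken out."""
    if not isinstance(sites, Mapping):
        sites = {s.site_id: s for s in sites}
    rep = SummaryReport(n_sites=len(sites))
    for lab in labels:
        gag = sites[lab.site_id].has_gag if lab.site_id in sites else False
        if gag:
            rep.gag_total += 1
        if lab.observed == "uncovered":
            rep.n_uncovered += 1
            continue
        rep.n_covered += 1
        if gag:
            rep.gag_covered += 1
        if lab.observed == "E":
            rep.n_E += 1
        elif lab.observed == "I":
            rep.n_I += 1
        else:
            rep.n_EI += 1
            if gag:
                rep.gag_EI += 1
        if lab.training_class != "none":
            rep.n_training += 1
    return rep
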