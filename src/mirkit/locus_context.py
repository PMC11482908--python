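"""Genomic-context classification of miRNA genes from a genome annotation.

Many animal miRNA genes are not free-standing transcription units: they sit
in the introns or exons of host genes, or lie so close to a neighbouring
gene on the same strand that a shared (polycistronic) primary transcript is
plausible — the situation of *Peony* and *miR-317* in Drosophila, where the
lncRNA gene ends ~1.7 kb upstream of the miRNA hairpin.  This module
assigns each miRNA gene exactly one of five categories:

* ``exonic`` — the miRNA span overlaps an exon of a non-miRNA host
  transcript;
* ``intronic`` — the span is contained in a host transcript span but
  overlaps no exon;
* ``co_transcribed_downstream`` — the miRNA lies downstream of (3' of) a
  same-strand neighbour gene ending within ``threshold_bp``;
* ``co_transcribed_upstream`` — the miRNA lies upstream of a same-strand
  neighbour gene starting within ``threshold_bp``;
* ``intergenic`` — none of the above.

Containment beats proximity; exonic beats intronic.  The two co-transcribed
categories together form the "putatively co-transcribed" class.  All
coordinates are 1-based inclusive (GFF3 convention); distances are the gap
between nearest facing edges, 0 for abutting or contained features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from mirkit.errors import ValidationError

#: Categories in report order.
CATEGORIES = (
    "intronic",
    "exonic",
    "intergenic",
    "co_transcribed_upstream",
    "co_transcribed_downstream",
)

#: Default proximity cutoff (bp) for the co-transcribed call.  Chosen to
#: comfortably cover the motivating Peony→miR-317 gap of ~1730 bp.
DEFAULT_THRESHOLD_BP = 2000

_TRANSCRIPT_TYPES = {"transcript", "mRNA", "ncRNA_transcript"}


@dataclass(frozen=True)
class GeneFeature:
    """One annotation interval (gene, transcript, exon or miRNA gene)."""

    feature_id: str
    feature_type: str  # gene | transcript | exon | miRNA_gene
    chrom: str
    strand: str
    start: int
    end: int
    parent_id: Optional[str] = None
    biotype: str = "other"  # coding | ncRNA | miRNA | other

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"feature {self.feature_id!r}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValidationError(f"feature {self.feature_id!r}: start must be >= 1")
        if self.strand not in {"+", "-"}:
            raise ValidationError(
                f"feature {self.feature_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GeneFeature") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GeneFeature") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class MiRNAContext:
    """The per-miRNA genomic-context call."""

    mirna_id: str
    category: str
    host_or_neighbor_id: Optional[str]
    distance_bp: int
    same_strand: bool


def _is_mirna_feature(f: GeneFeature) -> bool:
    return f.feature_type == "miRNA_gene" or f.biotype == "miRNA"


def _edge_gap(a: GeneFeature, b: GeneFeature) -> int:
    """Gap in bp between nearest facing edges; 0 if overlapping/abutting."""
    if a.start <= b.end and b.start <= a.end:
        return 0
    if b.end < a.start:
        return a.start - b.end - 1
    return b.start - a.end - 1


class AnnotationIndex:
    """Light lookup structure over a flat collection of :class:`GeneFeature`.

    Resolves the gene/transcript/exon hierarchy through ``parent_id`` and
    excludes a query miRNA's own lineage from host/neighbour searches.
    """

    def __init__(self, features: Iterable[GeneFeature]):
        self.features = list(features)
        self.by_id = {f.feature_id: f for f in self.features}
        self.children: dict[str, list[GeneFeature]] = {}
        for f in self.features:
            if f.parent_id is not None:
                self.children.setdefault(f.parent_id, []).append(f)
        self.chroms = {f.chrom for f in self.features}

    def exons_of(self, transcript_id: str) -> list[GeneFeature]:
        return [
            c for c in self.children.get(transcript_id, []) if c.feature_type == "exon"
        ]

    def _lineage(self, f: GeneFeature) -> set[str]:
        ids = {f.feature_id}
        cur = f
        while cur.parent_id is not None and cur.parent_id in self.by_id:
            cur = self.by_id[cur.parent_id]
            ids.add(cur.feature_id)
        stack = [f.feature_id]
        while stack:
            for c in self.children.get(stack.pop(), []):
                ids.add(c.feature_id)
                stack.append(c.feature_id)
        return ids

    def host_spans(self, exclude: set[str]) -> list[GeneFeature]:
        """Candidate host spans: non-miRNA transcripts, plus non-miRNA genes
        that have no transcript children (sparse annotations)."""
        spans = []
        for f in self.features:
            if f.feature_id in exclude or _is_mirna_feature(f):
                continue
            parent = self.by_id.get(f.parent_id) if f.parent_id else None
            if f.feature_type in _TRANSCRIPT_TYPES:
                if parent is not None and _is_mirna_feature(parent):
                    continue
                spans.append(f)
            elif f.feature_type == "gene" and not any(
                c.feature_type in _TRANSCRIPT_TYPES
                for c in self.children.get(f.feature_id, [])
            ):
                spans.append(f)
        return spans

    def genes(self, exclude: set[str]) -> list[GeneFeature]:
        return [
            f
            for f in self.features
            if f.feature_type in {"gene", "miRNA_gene"}
            and f.feature_id not in exclude
            and not _is_mirna_feature(f)
        ]


def classify_mirna_context(
    mirna: GeneFeature,
    annotation: Iterable[GeneFeature] | AnnotationIndex,
    threshold_bp: int = DEFAULT_THRESHOLD_BP,
) -> MiRNAContext:
    """Classify one miRNA gene's genomic context.

    Decision order: exonic (exon overlap) → intronic (transcript-span
    containment without exon overlap) → co-transcribed (nearest same-strand
    non-miRNA gene within ``threshold_bp``, smaller gap wins, ties broken
    toward the downstream-of-neighbour call) → intergenic.  Antisense
    containment is still called exonic/intronic, with ``same_strand`` False.
    """
    if threshold_bp <= 0:
        raise ValidationError("threshold_bp must be a positive integer")
    index = (
        annotation
        if isinstance(annotation, AnnotationIndex)
        else AnnotationIndex(annotation)
    )
    if mirna.chrom not in index.chroms:
        raise ValidationError(
            f"miRNA {mirna.feature_id!r}: chromosome {mirna.chrom!r} absent "
            "from the annotation"
        )
    exclude = index._lineage(mirna) if mirna.feature_id in index.by_id else {
        mirna.feature_id
    }

    # 1-2: containment-based categories, most specific (smallest) host wins.
    exonic_hosts: list[GeneFeature] = []
    intronic_hosts: list[GeneFeature] = []
    for host in index.host_spans(exclude):
        if host.chrom != mirna.chrom:
            continue
        exons = index.exons_of(host.feature_id)
        exon_spans = exons if exons else ([host] if host.feature_type == "exon" else [])
        if any(e.overlaps(mirna) for e in exon_spans):
            exonic_hosts.append(host)
        elif host.contains(mirna):
            intronic_hosts.append(host)
    for category, hosts in (("exonic", exonic_hosts), ("intronic", intronic_hosts)):
        if hosts:
            host = min(hosts, key=lambda h: (h.span, h.feature_id))
            return MiRNAContext(
                mirna_id=mirna.feature_id,
                category=category,
                host_or_neighbor_id=host.feature_id,
                distance_bp=0,
                same_strand=host.strand == mirna.strand,
            )

    # 3: proximity-based categories on the same strand.
    genes = [
        g
        for g in index.genes(exclude)
        if g.chrom == mirna.chrom and not g.overlaps(mirna)
    ]
    five_prime: Optional[tuple[int, GeneFeature]] = None  # neighbour 5' of the miRNA
    three_prime: Optional[tuple[int, GeneFeature]] = None
    for g in genes:
        if g.strand != mirna.strand:
            continue
        gap = _edge_gap(mirna, g)
        # is g on the 5' side of the miRNA in transcription orientation?
        g_is_5prime = (g.end < mirna.start) if mirna.strand == "+" else (
            g.start > mirna.end
        )
        if g_is_5prime:
            if five_prime is None or (gap, g.feature_id) < (
                five_prime[0],
                five_prime[1].feature_id,
            ):
                five_prime = (gap, g)
        else:
            if three_prime is None or (gap, g.feature_id) < (
                three_prime[0],
                three_prime[1].feature_id,
            ):
                three_prime = (gap, g)
    candidates = []
    if five_prime is not None and five_prime[0] <= threshold_bp:
        # miRNA downstream of its neighbour
        candidates.append(("co_transcribed_downstream", *five_prime))
    if three_prime is not None and three_prime[0] <= threshold_bp:
        candidates.append(("co_transcribed_upstream", *three_prime))
    if candidates:
        # smaller gap wins; tie → downstream-of-neighbour
        candidates.sort(
            key=lambda c: (c[1], 0 if c[0] == "co_transcribed_downstream" else 1)
        )
        category, gap, g = candidates[0]
        return MiRNAContext(
            mirna_id=mirna.feature_id,
            category=category,
            host_or_neighbor_id=g.feature_id,
            distance_bp=gap,
            same_strand=True,
        )

    # 4: intergenic; report the nearest gene of any strand for context.
    all_genes = [g for g in index.genes(exclude) if g.chrom == mirna.chrom]
    nearest = min(
        ((_edge_gap(mirna, g), g) for g in all_genes),
        key=lambda t: (t[0], t[1].feature_id),
        default=None,
    )
    return MiRNAContext(
        mirna_id=mirna.feature_id,
        category="intergenic",
        host_or_neighbor_id=nearest[1].feature_id if nearest else None,
        distance_bp=nearest[0] if nearest else 0,
        same_strand=(nearest[1].strand == mirna.strand) if nearest else False,
    )


@dataclass(frozen=True)
class ContextSummary:
    """Per-category counts and percentages over a set of miRNA context calls."""

    total: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def percentages(self) -> dict[str, float]:
        return {
            cat: round(100.0 * n / self.total, 1) for cat, n in self.counts.items()
        }

    @property
    def n_co_transcribed(self) -> int:
        return self.counts.get("co_transcribed_upstream", 0) + self.counts.get(
            "co_transcribed_downstream", 0
        )

    @property
    def pct_co_transcribed(self) -> float:
        return round(100.0 * self.n_co_transcribed / self.total, 1)


def summarize_contexts(contexts: Sequence[MiRNAContext]) -> ContextSummary:
    """Tally context categories; errors on empty input (no silent zero report)."""
    contexts = list(contexts)
    if not contexts:
        raise ValidationError("cannot summarize an empty context list")
    counts = {cat: 0 for cat in CATEGORIES}
    for c in contexts:
        if c.category not in counts:
            raise ValidationError(f"unknown category {c.category!r}")
        counts[c.category] += 1
    return ContextSummary(total=len(contexts), counts=counts)
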