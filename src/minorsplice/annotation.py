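"""Gene models, intron derivation and U2 reference-intron selection.

Gene structures are read from GTF (exon features only) and introns are
derived per transcript as the gaps between consecutive exons.  Each intron
carries a splicing-type label -- ``U2`` (major spliceosome), ``U12`` (minor
spliceosome) or ``unknown`` -- supplied by an external annotation table in
the style of the U12 intron database (one row per labelled intron, matched
to derived introns by exact genomic coordinates).

Splicing efficiency of a U12-type intron is always measured relative to two
U2-type reference introns of the same gene; :func:`select_reference_u2_introns`
picks the flanking U2 introns on the canonical transcript (nearest on each
side, falling back to the two nearest on one side for terminal U12 introns).

Coordinate conventions: internal coordinates are 0-based half-open
throughout; GTF I/O is 1-based inclusive; the intron-type table is 1-based
inclusive.  Conversions happen only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, TextIO, Union

import pandas as pd
from gffutils.feature import feature_from_line

from .errors import DataError, GTFParseError, ValidationError

logger = logging.getLogger(__name__)

U2 = "U2"
U12 = "U12"
UNKNOWN = "unknown"

#: reason code for genes whose U12 intron cannot be given two U2 references
INSUFFICIENT_U2_REFERENCES = "insufficient_U2_references"


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"invalid exon interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Intron:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    gene_id: str
    intron_index: int  # 1-based, transcript order 5'->3'
    splice_type: str = UNKNOWN

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"invalid intron interval [{self.start}, {self.end}) in {self.gene_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def span(self) -> tuple[str, int, int]:
        """Genomic key used to match annotation rows and junctions."""
        return (self.chrom, self.start, self.end)


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    exons: list[Exon]  # sorted by genomic coordinate, non-overlapping
    introns: list[Intron] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    def derive_introns(self) -> None:
        """Fill ``introns`` with the gaps between consecutive exons.

        ``intron_index`` follows transcript order (5'->3'), i.e. genomic
        order on '+' and reverse genomic order on '-'.
        """
        exons = sorted(self.exons, key=lambda e: e.start)
        for i in range(1, len(exons)):
            if exons[i].start < exons[i - 1].end:
                raise ValidationError(
                    f"overlapping exons in transcript {self.transcript_id}: "
                    f"[{exons[i - 1].start},{exons[i - 1].end}) and "
                    f"[{exons[i].start},{exons[i].end})"
                )
        self.exons = exons
        n_introns = len(exons) - 1
        introns = []
        for i in range(n_introns):
            genomic_pos = i + 1  # 1-based genomic order
            index = genomic_pos if self.strand == "+" else n_introns - i
            introns.append(
                Intron(
                    chrom=self.chrom,
                    start=exons[i].end,
                    end=exons[i + 1].start,
                    strand=self.strand,
                    gene_id=self.gene_id,
                    intron_index=index,
                )
            )
        self.introns = introns

    def introns_in_transcript_order(self) -> list[Intron]:
        return sorted(self.introns, key=lambda x: x.intron_index)


@dataclass
class Gene:
    gene_id: str
    transcripts: dict[str, Transcript]
    canonical_transcript_id: str

    @property
    def canonical_transcript(self) -> Transcript:
        return self.transcripts[self.canonical_transcript_id]

    @property
    def chrom(self) -> str:
        return self.canonical_transcript.chrom

    @property
    def strand(self) -> str:
        return self.canonical_transcript.strand

    @property
    def exonic_length(self) -> int:
        """Length of the union of canonical-transcript exons, in bp."""
        return sum(e.length for e in self.canonical_transcript.exons)

    @property
    def exon_union(self) -> list[tuple[int, int]]:
        return [(e.start, e.end) for e in self.canonical_transcript.exons]

    @property
    def extent(self) -> tuple[int, int]:
        lo = min(e.start for t in self.transcripts.values() for e in t.exons)
        hi = max(e.end for t in self.transcripts.values() for e in t.exons)
        return (lo, hi)

    @property
    def u12_introns(self) -> list[Intron]:
        """U12-labelled introns of the canonical transcript, 5'->3'."""
        return [
            i
            for i in self.canonical_transcript.introns_in_transcript_order()
            if i.splice_type == U12
        ]

    def all_intron_spans(self) -> set[tuple[str, int, int]]:
        """Genomic spans of every annotated intron of every transcript."""
        return {i.span for t in self.transcripts.values() for i in t.introns}


@dataclass
class GeneModelSet:
    genome: dict[str, int]  # chrom -> length (bp)
    genes: dict[str, Gene]

    def validate(self) -> None:
        for chrom, length in self.genome.items():
            if length <= 0:
                raise ValidationError(f"chromosome {chrom} has non-positive length")
        for gene in self.genes.values():
            for t in gene.transcripts.values():
                for intron in t.introns:
                    if intron.chrom not in self.genome:
                        raise ValidationError(
                            f"intron chromosome {intron.chrom} missing from genome"
                        )
                    if intron.end > self.genome[intron.chrom]:
                        raise ValidationError(
                            f"intron [{intron.start},{intron.end}) beyond end of {intron.chrom}"
                        )

    def u12_genes(self) -> list[str]:
        return sorted(g for g, gene in self.genes.items() if gene.u12_introns)


@dataclass(frozen=True)
class ReferencePair:
    """A U12 intron and its two U2 reference introns (same transcript)."""

    gene_id: str
    u12_intron: Intron
    u2_ref_a: Intron
    u2_ref_b: Intron

    def __post_init__(self):
        if self.u2_ref_a.splice_type != U2 or self.u2_ref_b.splice_type != U2:
            raise ValidationError("reference introns must be U2-labelled")
        if self.u2_ref_a.span == self.u2_ref_b.span:
            raise ValidationError("the two U2 references must be distinct")


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def read_gene_models(
    gtf_source: Union[str, TextIO],
    genome: Optional[Mapping[str, int]] = None,
) -> GeneModelSet:
    """Read exon features from a GTF file and derive transcripts and introns.

    Parameters
    ----------
    gtf_source
        Path to a GTF file, or an open text handle.  Only ``exon`` features
        are used; they must carry ``gene_id`` and ``transcript_id``
        attributes.  Coordinates are 1-based inclusive per the GTF standard.
    genome
        Optional chrom -> length map.  When omitted, chromosome lengths are
        inferred as the rightmost exon end per chromosome.

    Returns
    -------
    GeneModelSet
        With internal 0-based half-open coordinates, introns derived per
        transcript, and the canonical transcript chosen as the one with the
        longest exonic length (ties broken by smallest transcript_id).
    """
    close = False
    if isinstance(gtf_source, str):
        handle = open(gtf_source)
        close = True
    else:
        handle = gtf_source
    exons_by_transcript: dict[tuple[str, str], list[Exon]] = {}
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(lineno, f"expected 9 tab-separated fields, got {len(fields)}")
            try:
                feature = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GTFParseError(lineno, str(exc)) from exc
            if feature.featuretype != "exon":
                continue
            try:
                gene_id = feature.attributes["gene_id"][0]
                transcript_id = feature.attributes["transcript_id"][0]
            except (KeyError, IndexError) as exc:
                raise GTFParseError(lineno, "exon missing gene_id/transcript_id attribute") from exc
            if feature.strand not in "+-":
                raise GTFParseError(lineno, f"invalid strand {feature.strand!r}")
            try:
                exon = Exon(
                    chrom=feature.seqid,
                    start=feature.start - 1,  # GTF 1-based inclusive -> 0-based half-open
                    end=feature.end,
                    strand=feature.strand,
                )
            except ValidationError as exc:
                raise GTFParseError(lineno, str(exc)) from exc
            exons_by_transcript.setdefault((gene_id, transcript_id), []).append(exon)
    finally:
        if close:
            handle.close()

    transcripts_by_gene: dict[str, dict[str, Transcript]] = {}
    for (gene_id, transcript_id), exons in exons_by_transcript.items():
        t = Transcript(transcript_id=transcript_id, gene_id=gene_id, exons=exons)
        t.derive_introns()
        transcripts_by_gene.setdefault(gene_id, {})[transcript_id] = t

    genes: dict[str, Gene] = {}
    for gene_id, transcripts in transcripts_by_gene.items():
        canonical = min(transcripts.values(), key=lambda t: (-t.exonic_length, t.transcript_id))
        genes[gene_id] = Gene(
            gene_id=gene_id,
            transcripts=transcripts,
            canonical_transcript_id=canonical.transcript_id,
        )

    if genome is None:
        inferred: dict[str, int] = {}
        for transcripts in transcripts_by_gene.values():
            for t in transcripts.values():
                inferred[t.chrom] = max(inferred.get(t.chrom, 0), t.exons[-1].end)
        genome = inferred
    models = GeneModelSet(genome=dict(genome), genes=genes)
    models.validate()
    return models


def write_gtf(models: GeneModelSet, path: str, source: str = "minorsplice") -> None:
    """Write exon features (1-based inclusive, GTF2.2 quoted attributes)."""
    rows = []
    for gene_id in sorted(models.genes):
        gene = models.genes[gene_id]
        for transcript_id in sorted(gene.transcripts):
            t = gene.transcripts[transcript_id]
            for exon in t.exons:
                rows.append(
                    (exon.chrom, exon.start, exon.end, exon.strand, gene_id, transcript_id)
                )
    rows.sort(key=lambda r: (r[0], r[1], r[4], r[5]))
    with open(path, "w") as out:
        for chrom, start, end, strand, gene_id, transcript_id in rows:
            attrs = f'gene_id "{gene_id}"; transcript_id "{transcript_id}";'
            out.write(
                f"{chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )


def write_genome_tsv(models: GeneModelSet, path: str) -> None:
    with open(path, "w") as out:
        out.write("chrom\tlength\n")
        for chrom in sorted(models.genome):
            out.write(f"{chrom}\t{models.genome[chrom]}\n")


def read_genome_tsv(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "length": int})
    genome = dict(zip(df["chrom"], df["length"]))
    if len(genome) != len(df):
        raise ValidationError("duplicate chromosome names in genome table")
    return genome


# ---------------------------------------------------------------------------
# Intron-type table
# ---------------------------------------------------------------------------

INTRON_TYPE_COLUMNS = ["chrom", "start", "end", "strand", "gene_id", "splice_type"]


def read_intron_types(
    tsv_source: Union[str, TextIO], models: GeneModelSet
) -> tuple[GeneModelSet, dict]:
    """Apply U2/U12 labels from a tab-separated annotation table.

    The table has a header and columns ``chrom, start, end, strand, gene_id,
    splice_type`` with 1-based inclusive coordinates.  Each row is matched by
    exact coordinates to the derived introns of its gene (all transcripts);
    unmatched rows are skipped with a warning and counted in the returned
    report.  Derived introns with no matching row stay ``unknown``.

    Returns the (mutated in place) model set and a report dict with keys
    ``n_rows, n_matched_rows, n_skipped_rows, skipped``.
    """
    df = pd.read_csv(tsv_source, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = [c for c in INTRON_TYPE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"intron-type table missing columns: {missing}")
    bad = set(df["splice_type"]) - {U2, U12}
    if bad:
        raise DataError(f"invalid splice_type values: {sorted(bad)}")

    # exact-coordinate index over all derived introns
    index: dict[tuple[str, str, int, int], list[tuple[Transcript, int]]] = {}
    for gene in models.genes.values():
        for t in gene.transcripts.values():
            for pos, intron in enumerate(t.introns):
                index.setdefault((gene.gene_id, intron.chrom, intron.start, intron.end), []).append(
                    (t, pos)
                )

    labels: dict[tuple[str, str, int, int], str] = {}
    skipped = []
    for row in df.itertuples(index=False):
        key = (row.gene_id, row.chrom, int(row.start) - 1, int(row.end))
        if key not in index:
            skipped.append(key)
            continue
        prior = labels.get(key)
        if prior is not None and prior != row.splice_type:
            raise DataError(
                f"conflicting splice_type labels for intron {key}: {prior} vs {row.splice_type}"
            )
        labels[key] = row.splice_type

    for key, splice_type in labels.items():
        for t, pos in index[key]:
            t.introns[pos] = replace(t.introns[pos], splice_type=splice_type)

    if skipped:
        logger.warning(
            "intron-type table: %d row(s) matched no derived intron and were skipped", len(skipped)
        )
    report = {
        "n_rows": len(df),
        "n_matched_rows": len(df) - len(skipped),
        "n_skipped_rows": len(skipped),
        "skipped": skipped,
    }
    return models, report


def write_intron_types(models: GeneModelSet, path: str) -> None:
    """Write U2/U12 labels of all labelled derived introns (1-based coords)."""
    rows = []
    for gene_id in sorted(models.genes):
        gene = models.genes[gene_id]
        seen = set()
        for transcript_id in sorted(gene.transcripts):
            for intron in gene.transcripts[transcript_id].introns:
                if intron.splice_type == UNKNOWN or intron.span in seen:
                    continue
                seen.add(intron.span)
                rows.append(
                    (intron.chrom, intron.start + 1, intron.end, intron.strand, gene_id, intron.splice_type)
                )
    rows.sort()
    with open(path, "w") as out:
        out.write("\t".join(INTRON_TYPE_COLUMNS) + "\n")
        for r in rows:
            out.write("\t".join(map(str, r)) + "\n")


# ---------------------------------------------------------------------------
# Reference selection
# ---------------------------------------------------------------------------

def select_reference_u2_introns(gene: Gene, u12: Intron) -> Optional[ReferencePair]:
    """Pick the two U2 reference introns for a U12 intron.

    Uses the canonical transcript's intron chain in transcript order.  The
    nearest U2-labelled intron on each side of the U12 intron is chosen;
    when the U12 intron is terminal (no U2 intron on one side) the two
    nearest U2 introns on the available side are used.  ``unknown``-type
    introns are never eligible.

    Returns None when fewer than two U2 introns exist in the canonical
    transcript (the caller records the gene as unquantifiable with reason
    :data:`INSUFFICIENT_U2_REFERENCES`).
    """
    chain = gene.canonical_transcript.introns_in_transcript_order()
    try:
        pos = next(i for i, x in enumerate(chain) if x.span == u12.span)
    except StopIteration:
        raise ValidationError(
            f"U12 intron {u12.span} not found in canonical transcript of {gene.gene_id}"
        )
    upstream = [x for x in chain[:pos] if x.splice_type == U2]
    downstream = [x for x in chain[pos + 1:] if x.splice_type == U2]
    if len(upstream) + len(downstream) < 2:
        return None
    if upstream and downstream:
        ref_a, ref_b = upstream[-1], downstream[0]
    elif downstream:
        ref_a, ref_b = downstream[0], downstream[1]
    else:
        ref_a, ref_b = upstream[-2], upstream[-1]
    return ReferencePair(gene_id=gene.gene_id, u12_intron=u12, u2_ref_a=ref_a, u2_ref_b=ref_b)


def build_reference_pairs(
    models: GeneModelSet,
) -> tuple[list[ReferencePair], dict[str, str]]:
    """Reference pairs for every U12 intron of every gene.

    Returns (pairs, exclusions) where exclusions maps gene_id -> reason code
    for U12-bearing genes that could not be quantified.
    """
    pairs: list[ReferencePair] = []
    exclusions: dict[str, str] = {}
    for gene_id in sorted(models.genes):
        gene = models.genes[gene_id]
        gene_pairs = []
        ok = True
        for u12 in gene.u12_introns:
            pair = select_reference_u2_introns(gene, u12)
            if pair is None:
                ok = False
                break
            gene_pairs.append(pair)
        if not gene.u12_introns:
            continue
        if ok:
            pairs.extend(gene_pairs)
        else:
            exclusions[gene_id] = INSUFFICIENT_U2_REFERENCES
    return pairs, exclusions
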