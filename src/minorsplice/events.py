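"""Aberrant-processing events at U12 introns: cryptic splice sites and
exon skipping.

When U12-type splicing fails, nearby cryptic U2-type donors/acceptors can
be activated and exons can be skipped, producing novel splice junctions
absent from the annotation.  This module enumerates every N-op span inside
a gene that matches no annotated intron (of any transcript), classifies it
relative to the gene's U12 intron, and quantifies its abundance as a
fraction of transcripts: support / (support + canonical U12 junction
reads).

Classification (in transcript orientation; donor = 5' splice site):

* shares the U12 donor, acceptor within ``window`` bp of the U12 acceptor
  (inside or beyond the intron) -> ``cryptic_3p``
* mirror case (shared acceptor, shifted donor)  -> ``cryptic_5p``
* joins an annotated donor to a downstream annotated acceptor spanning the
  entire U12 intron (necessarily omitting >= 1 exon) -> ``exon_skip``
* anything else -> ``other``

Events are additionally pooled by condition; an event is marked
``case_exclusive`` when its pooled control fraction is below 1% while the
pooled case fraction exceeds 5% (patient-specific aberrant transcripts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotation import Gene, GeneModelSet, Intron
from .errors import ConfigError
from .quantify import JunctionKey, SampleScan

DEFAULT_MIN_SUPPORT = 3
DEFAULT_WINDOW = 100

CRYPTIC_5P = "cryptic_5p"
CRYPTIC_3P = "cryptic_3p"
EXON_SKIP = "exon_skip"
OTHER = "other"

CASE_EXCLUSIVE_CONTROL_MAX = 0.01
CASE_EXCLUSIVE_CASE_MIN = 0.05


@dataclass(frozen=True)
class NovelJunctionEvent:
    gene_id: str
    sample_id: str
    junction: JunctionKey
    event_class: str
    support_reads: int
    canonical_reads: int

    @property
    def fraction(self) -> float:
        denom = self.support_reads + self.canonical_reads
        return self.support_reads / denom if denom else float("nan")


def enumerate_novel_junctions(
    scan: SampleScan, gene: Gene, min_support: int = DEFAULT_MIN_SUPPORT
) -> list[tuple[JunctionKey, int]]:
    """All N-op spans within the gene's extent matching no annotated intron.

    Counts use the same anchor rule as canonical junction counting (the
    scan was built with it).  Junctions with fewer than ``min_support``
    supporting reads are dropped.
    """
    if min_support < 1:
        raise ConfigError("min_support must be >= 1")
    lo, hi = gene.extent
    annotated = gene.all_intron_spans()
    out = []
    for (chrom, start, end), count in scan.junction_counts.items():
        if chrom != gene.chrom or start < lo or end > hi:
            continue
        if (chrom, start, end) in annotated or count < min_support:
            continue
        out.append((JunctionKey(chrom, start, end, gene.strand), count))
    out.sort(key=lambda x: (x[0].donor_pos, x[0].acceptor_pos))
    return out


def classify_event(
    junction: JunctionKey, gene: Gene, u12: Intron, window: int = DEFAULT_WINDOW
) -> str:
    """Assign an event class to a novel junction (see module docstring)."""
    if window <= 0:
        raise ConfigError("window must be > 0")
    s, e = junction.donor_pos, junction.acceptor_pos
    plus = gene.strand == "+"
    # genomic-left/right splice sites of the U12 intron in transcript sense
    if plus:
        u12_donor, u12_acceptor = u12.start, u12.end
        donor, acceptor = s, e
    else:
        u12_donor, u12_acceptor = u12.end, u12.start
        donor, acceptor = e, s
    if donor == u12_donor and acceptor != u12_acceptor and abs(acceptor - u12_acceptor) <= window:
        return CRYPTIC_3P
    if acceptor == u12_acceptor and donor != u12_donor and abs(donor - u12_donor) <= window:
        return CRYPTIC_5P
    # exon skip: both ends on annotated splice sites, spanning the U12 intron
    donors = set()
    acceptors = set()
    for t in gene.transcripts.values():
        for intron in t.introns:
            left, right = intron.start, intron.end
            if plus:
                donors.add(left)
                acceptors.add(right)
            else:
                donors.add(right)
                acceptors.add(left)
    spans_u12 = s <= u12.start and e >= u12.end
    if donor in donors and acceptor in acceptors and spans_u12:
        return EXON_SKIP
    return OTHER


def detect_events(
    scans: Mapping[str, SampleScan],
    models: GeneModelSet,
    u12_by_gene: Mapping[str, Sequence[Intron]],
    conditions: Mapping[str, str],
    min_support: int = DEFAULT_MIN_SUPPORT,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Enumerate, classify and quantify novel junctions across samples.

    Parameters
    ----------
    scans
        sample_id -> SampleScan (the quantify-stage scan is reused).
    u12_by_gene
        gene_id -> U12 introns (canonical transcript); genes without U12
        introns are still scanned for novel junctions but classified
        against no U12 intron (class ``other`` unless exon-skip-like).
    conditions
        sample_id -> "case"/"control", for pooled fractions.

    Returns a tidy table with per-sample support, canonical counts and
    fractions, plus pooled per-condition fractions and the case_exclusive
    flag (constant within an event across its rows).
    """
    rows = []
    for sample_id, scan in scans.items():
        for gene_id in sorted(models.genes):
            gene = models.genes[gene_id]
            u12s = list(u12_by_gene.get(gene_id, []))
            for junction, count in enumerate_novel_junctions(scan, gene, min_support):
                cls = OTHER
                nearest_u12 = None
                for u12 in u12s:
                    cls = classify_event(junction, gene, u12, window)
                    if cls != OTHER:
                        nearest_u12 = u12
                        break
                canonical = 0
                if nearest_u12 is not None:
                    canonical = scan.junction_count(
                        nearest_u12.chrom, nearest_u12.start, nearest_u12.end
                    )
                elif u12s:
                    canonical = scan.junction_count(u12s[0].chrom, u12s[0].start, u12s[0].end)
                rows.append(
                    {
                        "gene_id": gene_id,
                        "sample_id": sample_id,
                        "condition": conditions.get(sample_id, ""),
                        "chrom": junction.chrom,
                        "donor": junction.donor_pos + 1,  # 1-based at the I/O boundary
                        "acceptor": junction.acceptor_pos,
                        "event_class": cls,
                        "support_reads": count,
                        "canonical_reads": canonical,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "sample_id", "condition", "chrom", "donor", "acceptor",
            "event_class", "support_reads", "canonical_reads",
        ],
    )
    if df.empty:
        df["fraction"] = pd.Series(dtype=float)
        df["case_fraction"] = pd.Series(dtype=float)
        df["control_fraction"] = pd.Series(dtype=float)
        df["case_exclusive"] = pd.Series(dtype=bool)
        return df
    denom = df["support_reads"] + df["canonical_reads"]
    df["fraction"] = df["support_reads"] / denom.where(denom > 0)
    # canonical U12 junction reads summed over every sample of a condition,
    # so pooled fractions are not biased toward samples showing the event
    canon_rows = []
    for sample_id, scan in scans.items():
        cond = conditions.get(sample_id, "")
        for gene_id, u12s in u12_by_gene.items():
            total = sum(scan.junction_count(u.chrom, u.start, u.end) for u in u12s)
            canon_rows.append({"gene_id": gene_id, "condition": cond, "canonical": total})
    canonical_totals = (
        pd.DataFrame(canon_rows).groupby(["gene_id", "condition"])["canonical"].sum()
        if canon_rows
        else None
    )
    pooled = event_fractions(df, canonical_totals)
    df = df.merge(
        pooled[["gene_id", "chrom", "donor", "acceptor", "case_fraction", "control_fraction", "case_exclusive"]],
        on=["gene_id", "chrom", "donor", "acceptor"],
        how="left",
    )
    return df.sort_values(["gene_id", "donor", "acceptor", "sample_id"]).reset_index(drop=True)


def event_fractions(
    events: pd.DataFrame, canonical_totals: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Pool events by condition: fraction = support / (support + canonical).

    ``canonical_totals``, when given, is a Series indexed by
    (gene_id, condition) holding canonical U12 junction reads summed over
    every sample of the condition; otherwise the canonical counts of the
    samples carrying the event are used.  Support below ``min_support`` in
    a sample never reaches this table, so pooled support is conservative.
    """
    key = ["gene_id", "chrom", "donor", "acceptor"]
    out = []
    for group_key, grp in events.groupby(key, sort=True):
        rec = dict(zip(key, group_key))
        rec["event_class"] = grp["event_class"].iloc[0]
        for cond in ("case", "control"):
            sub = grp[grp["condition"] == cond]
            support = int(sub["support_reads"].sum())
            if canonical_totals is not None:
                canonical = int(canonical_totals.get((group_key[0], cond), 0))
            else:
                canonical = int(sub["canonical_reads"].sum())
            denom = support + canonical
            rec[f"{cond}_fraction"] = support / denom if denom else float("nan")
            rec[f"{cond}_support"] = support
        out.append(rec)
    pooled = pd.DataFrame(out)
    ctrl = pooled["control_fraction"].fillna(0.0)
    case = pooled["case_fraction"].fillna(0.0)
    pooled["case_exclusive"] = (ctrl < CASE_EXCLUSIVE_CONTROL_MAX) & (
        case > CASE_EXCLUSIVE_CASE_MIN
    )
    return pooled
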