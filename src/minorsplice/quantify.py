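"""Split-read junction counting, intron-body depth and per-gene FPKM.

Three raw measurements feed the splicing metrics:

* ``J`` -- the number of split reads whose N operation skips exactly one
  annotated intron, with at least ``min_anchor`` aligned bases immediately
  on each side of the skip.  Reads skipping a superset region (e.g.
  exon-skipping reads) do not count toward the canonical junction; they are
  distinct events handled by :mod:`minorsplice.events`.
* ``D`` -- mean per-base M-op coverage over the intron body, with
  ``edge_trim`` bp excluded at each end to avoid junction-adjacent bleed.
* ``FPKM`` -- reads whose leftmost position falls in the gene's canonical
  exon union, per kilobase of exonic length, per million mapped reads.

Counting is unstranded and exact: rerunning on the same input is
bit-identical, and results do not depend on record order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import GeneModelSet, Gene, Intron, ReferencePair
from .errors import ConfigError, DataError
from .simulate import AlignmentRecord

DEFAULT_MIN_ANCHOR = 6
DEFAULT_EDGE_TRIM = 10

#: reason code for introns too short to support a trimmed body depth
INTRON_TOO_SHORT = "intron_too_short_after_trim"


class JunctionKey(NamedTuple):
    chrom: str
    donor_pos: int  # 0-based genomic coordinate of intron start
    acceptor_pos: int  # 0-based coordinate of intron end (half-open)
    strand: str = "."


@dataclass
class QuantParams:
    min_anchor: int = DEFAULT_MIN_ANCHOR
    edge_trim: int = DEFAULT_EDGE_TRIM

    def validate(self) -> None:
        if self.min_anchor < 1:
            raise ConfigError("min_anchor must be >= 1")
        if self.edge_trim < 0:
            raise ConfigError("edge_trim must be >= 0")


@dataclass
class GeneQuant:
    """Raw per-gene, per-sample measurements for one U12 intron."""

    gene_id: str
    sample_id: str
    chrom: str
    u12_start: int  # 0-based half-open
    u12_end: int
    j_u12: int
    j_u2a: int
    j_u2b: int
    d_u12: float
    d_u2a: float
    d_u2b: float
    fpkm: float
    total_mapped: int


def _iter_reads(alignments: Iterable) -> Iterable[tuple[str, int, tuple[tuple[str, int], ...]]]:
    """Normalise AlignmentRecord / pysam.AlignedSegment to (chrom, pos0, ops)."""
    for rec in alignments:
        if isinstance(rec, AlignmentRecord):
            yield rec.chrom, rec.pos - 1, rec.ops
        elif isinstance(rec, pysam.AlignedSegment):
            if rec.is_unmapped:
                continue
            ops = tuple(
                ("M" if op == 0 else "N" if op == 3 else "?", length)
                for op, length in rec.cigartuples
            )
            yield rec.reference_name, rec.reference_start, ops
        else:  # pre-normalised tuple
            yield rec


def _read_segments(pos0: int, ops: Sequence[tuple[str, int]]):
    """Yield (op, ref_start, ref_end) reference segments of one read."""
    p = pos0
    for op, length in ops:
        if op in ("M", "N"):
            yield op, p, p + length
            p += length


def count_junction_reads(
    alignments: Iterable, junction: JunctionKey, min_anchor: int = DEFAULT_MIN_ANCHOR
) -> int:
    """Count split reads whose N op skips exactly [donor, acceptor).

    A read counts when it contains an N operation with genomic span equal to
    the junction's and at least ``min_anchor`` M bases immediately flanking
    the N op on both sides.  Reads on other chromosomes are ignored.
    """
    if min_anchor < 1:
        raise ConfigError("min_anchor must be >= 1")
    count = 0
    for chrom, pos0, ops in _iter_reads(alignments):
        if chrom != junction.chrom:
            continue
        p = pos0
        for i, (op, length) in enumerate(ops):
            if op == "N" and p == junction.donor_pos and p + length == junction.acceptor_pos:
                left_ok = i > 0 and ops[i - 1][0] == "M" and ops[i - 1][1] >= min_anchor
                right_ok = (
                    i + 1 < len(ops) and ops[i + 1][0] == "M" and ops[i + 1][1] >= min_anchor
                )
                if left_ok and right_ok:
                    count += 1
            if op in ("M", "N"):
                p += length
    return count


def intron_depth(
    alignments: Iterable, intron: Intron, edge_trim: int = DEFAULT_EDGE_TRIM
) -> Optional[float]:
    """Mean per-base M-op coverage over the trimmed intron body.

    The body is ``[start + edge_trim, end - edge_trim)``; N ops contribute
    nothing.  Returns None (unquantifiable) when the intron is too short to
    leave a positive-length body.
    """
    lo, hi = intron.start + edge_trim, intron.end - edge_trim
    if hi <= lo:
        return None
    total = 0
    for chrom, pos0, ops in _iter_reads(alignments):
        if chrom != intron.chrom:
            continue
        for op, s, e in _read_segments(pos0, ops):
            if op == "M":
                total += max(0, min(e, hi) - max(s, lo))
    return total / (hi - lo)


def gene_fpkm(alignments: Iterable, gene: Gene, total_mapped: int) -> float:
    """FPKM from leftmost-position counting over the canonical exon union."""
    if total_mapped <= 0:
        raise DataError("total_mapped must be positive to compute FPKM")
    union = gene.exon_union
    n = 0
    for chrom, pos0, _ in _iter_reads(alignments):
        if chrom != gene.chrom:
            continue
        if any(s <= pos0 < e for s, e in union):
            n += 1
    return n / (gene.exonic_length / 1000.0) / (total_mapped / 1e6)


# ---------------------------------------------------------------------------
# Single-pass sample scan
# ---------------------------------------------------------------------------

class SampleScan:
    """One pass over a SAM file collecting everything the pipeline needs.

    Stores anchored junction counts for every observed N span, per-chromosome
    M-op coverage (as difference arrays), sorted leftmost read positions, and
    the library-wide mapped-read count.  Junction/depth/FPKM queries then run
    off these structures without touching the SAM again; the events module
    reuses the same junction table.
    """

    def __init__(
        self,
        sam_path: str,
        genome: dict[str, int],
        min_anchor: int = DEFAULT_MIN_ANCHOR,
    ):
        self.sam_path = sam_path
        self.min_anchor = min_anchor
        self.junction_counts: Counter[tuple[str, int, int]] = Counter()
        self._cov: dict[str, np.ndarray] = {}
        self._starts: dict[str, np.ndarray] = {}
        self.total_mapped = 0
        diff = {c: np.zeros(length + 1, dtype=np.int32) for c, length in genome.items()}
        starts: dict[str, list[int]] = {c: [] for c in genome}
        jc = self.junction_counts
        with pysam.AlignmentFile(sam_path, "r", check_sq=False) as af:
            for n_rec, rec in enumerate(af, start=1):
                if rec.is_unmapped:
                    continue
                chrom = rec.reference_name
                if chrom not in diff:
                    raise DataError(
                        f"{sam_path}: record {n_rec} on unknown chromosome {chrom!r}"
                    )
                self.total_mapped += 1
                pos = rec.reference_start
                starts[chrom].append(pos)
                ct = rec.cigartuples
                if ct is None:
                    raise DataError(f"{sam_path}: record {n_rec} has no CIGAR")
                d = diff[chrom]
                p = pos
                for i, (op, length) in enumerate(ct):
                    if op == 0:  # M
                        d[p] += 1
                        d[p + length] -= 1
                        p += length
                    elif op == 3:  # N
                        left = ct[i - 1] if i > 0 else None
                        right = ct[i + 1] if i + 1 < len(ct) else None
                        if (
                            left is not None
                            and right is not None
                            and left[0] == 0
                            and right[0] == 0
                            and left[1] >= min_anchor
                            and right[1] >= min_anchor
                        ):
                            jc[(chrom, p, p + length)] += 1
                        p += length
                    else:
                        raise DataError(
                            f"{sam_path}: record {n_rec} has unsupported CIGAR op {op}"
                        )
        for chrom, d in diff.items():
            self._cov[chrom] = np.cumsum(d[:-1], dtype=np.int64)
            self._starts[chrom] = np.sort(np.array(starts[chrom], dtype=np.int64))

    def junction_count(self, chrom: str, start: int, end: int) -> int:
        return self.junction_counts.get((chrom, start, end), 0)

    def depth(self, chrom: str, start: int, end: int, edge_trim: int) -> Optional[float]:
        lo, hi = start + edge_trim, end - edge_trim
        if hi <= lo:
            return None
        return float(self._cov[chrom][lo:hi].mean())

    def reads_starting_in(self, chrom: str, intervals: Sequence[tuple[int, int]]) -> int:
        pos = self._starts[chrom]
        n = 0
        for s, e in intervals:
            n += int(np.searchsorted(pos, e) - np.searchsorted(pos, s))
        return n

    def fpkm(self, gene: Gene) -> float:
        if self.total_mapped <= 0:
            raise DataError("total_mapped must be positive to compute FPKM")
        n = self.reads_starting_in(gene.chrom, gene.exon_union)
        return n / (gene.exonic_length / 1000.0) / (self.total_mapped / 1e6)


def quantify_sample(
    sam_path: str,
    models: GeneModelSet,
    reference_pairs: Sequence[ReferencePair],
    sample_id: str,
    params: Optional[QuantParams] = None,
    scan: Optional[SampleScan] = None,
) -> tuple[list[GeneQuant], SampleScan]:
    """Quantify one sample: one :class:`GeneQuant` per U12 intron.

    A sample with zero mapped reads is rejected (FPKM undefined).  The scan
    is returned so downstream event detection can reuse it.
    """
    params = params or QuantParams()
    params.validate()
    if scan is None:
        scan = SampleScan(sam_path, models.genome, min_anchor=params.min_anchor)
    if scan.total_mapped == 0:
        raise DataError(f"sample {sample_id}: no mapped reads, cannot quantify")
    quants: list[GeneQuant] = []
    for pair in reference_pairs:
        gene = models.genes[pair.gene_id]
        u12, ra, rb = pair.u12_intron, pair.u2_ref_a, pair.u2_ref_b
        depths = {}
        for tag, intron in (("u12", u12), ("a", ra), ("b", rb)):
            d = scan.depth(intron.chrom, intron.start, intron.end, params.edge_trim)
            depths[tag] = d
        if any(v is None for v in depths.values()):
            continue  # unquantifiable intron body; excluded with reason in report
        quants.append(
            GeneQuant(
                gene_id=pair.gene_id,
                sample_id=sample_id,
                chrom=u12.chrom,
                u12_start=u12.start,
                u12_end=u12.end,
                j_u12=scan.junction_count(u12.chrom, u12.start, u12.end),
                j_u2a=scan.junction_count(ra.chrom, ra.start, ra.end),
                j_u2b=scan.junction_count(rb.chrom, rb.start, rb.end),
                d_u12=depths["u12"],
                d_u2a=depths["a"],
                d_u2b=depths["b"],
                fpkm=scan.fpkm(gene),
                total_mapped=scan.total_mapped,
            )
        )
    return quants, scan


QUANT_COLUMNS = [
    "gene_id", "sample_id", "chrom", "u12_start", "u12_end",
    "j_u12", "j_u2a", "j_u2b", "d_u12", "d_u2a", "d_u2b", "fpkm", "total_mapped",
]


def quants_to_frame(quants: Sequence[GeneQuant]) -> pd.DataFrame:
    df = pd.DataFrame([q.__dict__ for q in quants], columns=QUANT_COLUMNS)
    # 1-based inclusive coordinates at the I/O boundary
    if len(df):
        df["u12_start"] = df["u12_start"] + 1
    return df


def frame_to_internal(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["u12_start"] = df["u12_start"] - 1
    return df
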