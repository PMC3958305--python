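"""Spliced-read simulator with a known per-intron ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: genes carrying one U12-type intron among several U2-type introns,
per-gene expression levels shared across samples, a low baseline level of
intron retention in every sample, and -- for an affected subset of genes in
case samples only -- strongly elevated U12 intron retention together with
activation of gene-specific cryptic U2-type splice sites and exon skipping.

Each mRNA molecule yields exactly one 100-bp read (alignment is assumed to
have happened upstream; bases are arbitrary seeded sequence).  A molecule's
isoform is drawn hierarchically: with probability ``r`` the U12 intron is
retained; conditional on being spliced, a cryptic donor/acceptor is used
with probability ``c`` (split evenly between the 5' and 3' site) or an exon
is skipped with probability ``k``, otherwise splicing is canonical.  The
hierarchical form makes the expected cryptic/(cryptic+canonical)
junction-read fraction equal ``c`` regardless of the retention level.
Independently, every U2-type intron of the molecule is retained with the
baseline probability in all samples and conditions.

A gene's cryptic splice sites and skipped exon are drawn once per gene and
are fixed across samples: recurrent aberrant transcripts are a property of
the gene's sequence, not of the sample.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields as dc_fields, replace
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    U2,
    U12,
    Exon,
    Gene,
    GeneModelSet,
    Intron,
    Transcript,
    write_genome_tsv,
    write_gtf,
    write_intron_types,
)
from .errors import ConfigError, DataError

CANONICAL = "canonical"
RETAINED = "retained"
CRYPTIC_5P = "cryptic_5p"
CRYPTIC_3P = "cryptic_3p"
EXON_SKIP = "exon_skip"
ISOFORM_CLASSES = [CANONICAL, RETAINED, CRYPTIC_5P, CRYPTIC_3P, EXON_SKIP]
# integer codes used internally; order matters for reproducibility
_CLASS_CODE = {name: i for i, name in enumerate(ISOFORM_CLASSES)}

CASE = "case"
CONTROL = "control"


@dataclass
class SimulationConfig:
    """All knobs of the simulator; every field is settable from YAML."""

    n_genes: int = 500
    n_case_samples: int = 2
    n_control_samples: int = 4
    read_length: int = 100
    mean_fragments_per_gene: float = 4000.0
    expression_dispersion: float = 60.0  # negative-binomial size
    expression_log_sigma: float = 0.5  # lognormal spread of per-gene expression
    baseline_retention: float = 0.02
    baseline_cryptic: float = 0.0
    baseline_skip: float = 0.0
    affected_gene_fraction: float = 0.04
    case_retention: float = 0.3
    case_cryptic: float = 0.3
    case_skip: float = 0.05
    u12_gene_fraction: float = 0.9
    n_chromosomes: int = 4
    exon_length_range: tuple[int, int] = (80, 300)
    intron_length_range: tuple[int, int] = (200, 2000)
    n_exons_range: tuple[int, int] = (4, 8)
    cryptic_offset_range: tuple[int, int] = (30, 90)
    gene_spacing: int = 1000
    per_read_truth: bool = False
    seed: int = 0
    #: optional per-gene relative expression multipliers (length n_genes);
    #: overrides the lognormal draw when given
    expression_profile: Optional[list[float]] = None

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.n_case_samples < 0 or self.n_control_samples < 0:
            raise ConfigError("sample counts must be non-negative")
        if self.read_length < 20:
            raise ConfigError("read_length too short")
        if self.mean_fragments_per_gene <= 0 or self.expression_dispersion <= 0:
            raise ConfigError("mean_fragments_per_gene and expression_dispersion must be positive")
        for name in (
            "baseline_retention",
            "baseline_cryptic",
            "baseline_skip",
            "affected_gene_fraction",
            "case_retention",
            "case_cryptic",
            "case_skip",
            "u12_gene_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v}")
        if self.baseline_cryptic + self.baseline_skip > 1.0:
            raise ConfigError("baseline_cryptic + baseline_skip must not exceed 1")
        if self.case_cryptic + self.case_skip > 1.0:
            raise ConfigError("case_cryptic + case_skip must not exceed 1")
        lo, hi = self.cryptic_offset_range
        if not (0 < lo <= hi < self.intron_length_range[0]):
            raise ConfigError("cryptic offsets must fit inside the shortest intron")
        if self.n_exons_range[0] < 3:
            raise ConfigError("genes need at least 3 exons for U2 reference selection")
        if self.exon_length_range[0] * self.n_exons_range[0] <= self.read_length:
            raise ConfigError("shortest possible mRNA must exceed the read length")
        if self.expression_profile is not None and len(self.expression_profile) != self.n_genes:
            raise ConfigError("expression_profile length must equal n_genes")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"simulation config {path} must be a YAML mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        for key in ("exon_length_range", "intron_length_range", "n_exons_range", "cryptic_offset_range"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        out = {}
        for f in dc_fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read; ops use SAM M/N semantics on the reference."""

    read_id: str
    sample_id: str
    chrom: str
    pos: int  # 1-based leftmost, SAM convention
    strand: str
    ops: tuple[tuple[str, int], ...]
    truth_class: str = CANONICAL  # written to the truth sidecar only, never to SAM

    def cigar(self) -> str:
        return "".join(f"{length}{op}" for op, length in self.ops)


@dataclass
class GeneSim:
    """Per-gene generative structure, fixed across samples."""

    gene: Gene
    mu: float  # expected molecules per sample
    u12: Optional[Intron]
    u2_introns: list[Intron]  # canonical transcript, genomic order
    class_blocks: dict[str, list[tuple[int, int]]]
    #: genomic N-op span produced by each non-canonical junction class
    class_junctions: dict[str, tuple[int, int]]
    affected: bool = False


@dataclass
class SimulationState:
    config: SimulationConfig
    models: GeneModelSet
    gene_sims: dict[str, GeneSim]
    affected_genes: set[str]

    def sample_ids(self) -> list[tuple[str, str]]:
        out = [(f"case_{i + 1:02d}", CASE) for i in range(self.config.n_case_samples)]
        out += [(f"control_{i + 1:02d}", CONTROL) for i in range(self.config.n_control_samples)]
        return out


def _sample_rng(config: SimulationConfig, sample_id: str) -> np.random.Generator:
    """Per-sample substream: master seed combined with a stable hash of the id."""
    return np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode())])
    )


# ---------------------------------------------------------------------------
# Gene-set generation
# ---------------------------------------------------------------------------

def simulate_gene_set(config: SimulationConfig) -> SimulationState:
    """Draw gene structures, intron types, expression levels and affected set.

    Each gene gets 4-8 exons (seeded draw) laid out non-overlapping along
    synthetic chromosomes; 90% of genes carry exactly one U12-type intron at
    a random position, the rest are all-U2 negative controls.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF]))
    n = config.n_genes
    width = max(4, len(str(n)))
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {c: config.gene_spacing for c in chroms}

    genes: dict[str, Gene] = {}
    gene_sims: dict[str, GeneSim] = {}

    if config.expression_profile is not None:
        rel = np.asarray(config.expression_profile, dtype=float)
    else:
        sigma = config.expression_log_sigma
        rel = rng.lognormal(0.0, sigma, n) / np.exp(sigma**2 / 2)

    for gi in range(n):
        gene_id = f"G{gi + 1:0{width}d}"
        chrom = chroms[gi % len(chroms)]
        n_exons = int(rng.integers(config.n_exons_range[0], config.n_exons_range[1] + 1))
        exon_lens = rng.integers(
            config.exon_length_range[0], config.exon_length_range[1] + 1, n_exons
        )
        intron_lens = rng.integers(
            config.intron_length_range[0], config.intron_length_range[1] + 1, n_exons - 1
        )
        strand = "+" if rng.random() < 0.5 else "-"
        has_u12 = rng.random() < config.u12_gene_fraction
        u12_genomic_idx = int(rng.integers(0, n_exons - 1)) if has_u12 else -1
        d5 = int(rng.integers(config.cryptic_offset_range[0], config.cryptic_offset_range[1] + 1))
        d3 = int(rng.integers(config.cryptic_offset_range[0], config.cryptic_offset_range[1] + 1))

        start = cursors[chrom]
        exons = []
        pos = start
        for i in range(n_exons):
            exons.append(Exon(chrom=chrom, start=pos, end=pos + int(exon_lens[i]), strand=strand))
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        cursors[chrom] = pos + config.gene_spacing

        transcript = Transcript(transcript_id=f"{gene_id}.t1", gene_id=gene_id, exons=exons)
        transcript.derive_introns()
        # introns are created in genomic order with transcript-order indices
        genomic_introns = sorted(transcript.introns, key=lambda x: x.start)
        for i, intron in enumerate(genomic_introns):
            splice_type = U12 if i == u12_genomic_idx else U2
            j = transcript.introns.index(intron)
            transcript.introns[j] = replace(intron, splice_type=splice_type)
        gene = Gene(
            gene_id=gene_id,
            transcripts={transcript.transcript_id: transcript},
            canonical_transcript_id=transcript.transcript_id,
        )
        genes[gene_id] = gene
        gene_sims[gene_id] = _build_gene_sim(
            gene, mu=config.mean_fragments_per_gene * float(rel[gi]), d5=d5, d3=d3
        )

    genome = {c: cursors[c] for c in chroms}
    models = GeneModelSet(genome=genome, genes=genes)
    models.validate()

    u12_gene_ids = models.u12_genes()
    n_affected = int(round(config.affected_gene_fraction * n))
    n_affected = min(n_affected, len(u12_gene_ids))
    affected = set(
        rng.choice(np.array(u12_gene_ids, dtype=object), size=n_affected, replace=False)
    ) if n_affected else set()
    for g in affected:
        gene_sims[g].affected = True

    return SimulationState(config=config, models=models, gene_sims=gene_sims, affected_genes=affected)


def _build_gene_sim(gene: Gene, mu: float, d5: int, d3: int) -> GeneSim:
    """Precompute isoform block structures and aberrant junction spans."""
    t = gene.canonical_transcript
    exons = [(e.start, e.end) for e in t.exons]  # genomic order
    genomic_introns = sorted(t.introns, key=lambda x: x.start)
    u12_list = [i for i in genomic_introns if i.splice_type == U12]
    u2_introns = [i for i in genomic_introns if i.splice_type == U2]
    blocks = {CANONICAL: exons}
    junctions: dict[str, tuple[int, int]] = {}

    u12 = u12_list[0] if u12_list else None
    if u12 is not None:
        k = next(i for i, x in enumerate(genomic_introns) if x.span == u12.span)
        # retained: merge the two exons flanking the U12 intron
        merged = exons[:k] + [(exons[k][0], exons[k + 1][1])] + exons[k + 2:]
        blocks[RETAINED] = merged
        if t.strand == "+":
            # 5' cryptic donor shifted d5 into the intron (from the genomic left)
            c5 = exons[:k] + [(exons[k][0], u12.start + d5)] + exons[k + 1:]
            junctions[CRYPTIC_5P] = (u12.start + d5, u12.end)
            # 3' cryptic acceptor shifted d3 into the intron (from the genomic right)
            c3 = exons[:k + 1] + [(u12.end - d3, exons[k + 1][1])] + exons[k + 2:]
            junctions[CRYPTIC_3P] = (u12.start, u12.end - d3)
        else:
            # transcript 5' end is the genomic right side on '-'
            c5 = exons[:k + 1] + [(u12.end - d5, exons[k + 1][1])] + exons[k + 2:]
            junctions[CRYPTIC_5P] = (u12.start, u12.end - d5)
            c3 = exons[:k] + [(exons[k][0], u12.start + d3)] + exons[k + 1:]
            junctions[CRYPTIC_3P] = (u12.start + d3, u12.end)
        blocks[CRYPTIC_5P] = c5
        blocks[CRYPTIC_3P] = c3
        # exon skip: prefer the transcript-upstream exon flanking the U12 intron
        upstream_genomic = k if t.strand == "+" else k + 1
        skip_idx = upstream_genomic
        if skip_idx == 0:
            skip_idx = k + 1
        if skip_idx == len(exons) - 1:
            skip_idx = k
        skipped = exons[:skip_idx] + exons[skip_idx + 1:]
        blocks[EXON_SKIP] = skipped
        junctions[EXON_SKIP] = (exons[skip_idx - 1][1], exons[skip_idx + 1][0])
    return GeneSim(
        gene=gene,
        mu=mu,
        u12=u12,
        u2_introns=u2_introns,
        class_blocks=blocks,
        class_junctions=junctions,
    )


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

def _class_probs(config: SimulationConfig, condition: str, affected: bool) -> tuple[float, float, float]:
    """(retention, cryptic|spliced, skip|spliced) for a U12 intron."""
    if condition == CASE and affected:
        return config.case_retention, config.case_cryptic, config.case_skip
    return config.baseline_retention, config.baseline_cryptic, config.baseline_skip


def _merge_retained_u2(
    blocks: list[tuple[int, int]], retained_spans: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Fill the gaps of retained U2 introns; spans absent as gaps are ignored."""
    blocks = list(blocks)
    for s, e in retained_spans:
        for i in range(len(blocks) - 1):
            if blocks[i][1] == s and blocks[i + 1][0] == e:
                blocks[i:i + 2] = [(blocks[i][0], blocks[i + 1][1])]
                break
    return blocks


def _gene_reads(
    sim: GeneSim, config: SimulationConfig, condition: str, rng: np.random.Generator
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Generate one sample's reads for one gene.

    Returns (pos0, cigars, class_codes, class_counts) with reads sorted by
    leftmost genomic position; ``class_counts`` is indexed by isoform class
    code and counts molecules, not reads (they are equal: one read each).
    """
    size = config.expression_dispersion
    mu = sim.mu
    n = int(rng.negative_binomial(size, size / (size + mu)))
    counts = np.zeros(len(ISOFORM_CLASSES), dtype=int)
    if n == 0:
        return np.empty(0, dtype=int), [], np.empty(0, dtype=int), counts

    if sim.u12 is not None:
        r, c, k = _class_probs(config, condition, sim.affected)
        p = np.array(
            [(1 - r) * (1 - c - k), r, (1 - r) * c / 2, (1 - r) * c / 2, (1 - r) * k]
        )
        classes = rng.choice(len(ISOFORM_CLASSES), size=n, p=p)
    else:
        classes = np.zeros(n, dtype=int)
    n_u2 = len(sim.u2_introns)
    if n_u2 and config.baseline_retention > 0:
        flags = rng.random((n, n_u2)) < config.baseline_retention
    else:
        flags = np.zeros((n, n_u2), dtype=bool)
    sig = classes.astype(np.int64)
    for j in range(n_u2):
        sig = sig * 2 + flags[:, j]

    read_len = config.read_length
    pos_all = np.empty(n, dtype=np.int64)
    cig_all: list[Optional[str]] = [None] * n
    cls_all = classes
    uniq, inverse = np.unique(sig, return_inverse=True)
    for ui, signature in enumerate(uniq):
        idx = np.nonzero(inverse == ui)[0]
        m = len(idx)
        bits = []
        s = int(signature)
        for _ in range(n_u2):
            bits.append(s & 1)
            s >>= 1
        bits.reverse()
        cls = s
        base = sim.class_blocks[ISOFORM_CLASSES[cls]]
        retained_spans = [
            (intron.start, intron.end) for b, intron in zip(bits, sim.u2_introns) if b
        ]
        blocks = _merge_retained_u2(base, retained_spans) if retained_spans else base
        starts = np.array([b[0] for b in blocks], dtype=np.int64)
        lens = np.array([b[1] - b[0] for b in blocks], dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(lens)])
        L = int(cum[-1])
        if L < read_len:  # cannot happen under config validation; guard anyway
            raise DataError(f"isoform of {sim.gene.gene_id} shorter than read length")
        s0 = rng.integers(0, L - read_len + 1, m)
        bi = np.searchsorted(cum, s0, side="right") - 1
        off = s0 - cum[bi]
        pos = starts[bi] + off
        within = off + read_len <= lens[bi]
        pos_all[idx] = pos
        for local in np.nonzero(within)[0]:
            cig_all[idx[local]] = f"{read_len}M"
        for local in np.nonzero(~within)[0]:
            b = int(bi[local])
            remaining = read_len - int(lens[b] - off[local])
            parts = [f"{int(lens[b] - off[local])}M"]
            while remaining > 0:
                gap = int(starts[b + 1] - (starts[b] + lens[b]))
                parts.append(f"{gap}N")
                b += 1
                take = min(remaining, int(lens[b]))
                parts.append(f"{take}M")
                remaining -= take
            cig_all[idx[local]] = "".join(parts)
    np.add.at(counts, classes, 1)
    order = np.argsort(pos_all, kind="stable")
    return pos_all[order], [cig_all[i] for i in order], cls_all[order], counts


_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _seqs(rng: np.random.Generator, m: int, read_len: int) -> bytes:
    return _BASE_LUT[rng.integers(0, 4, (m, read_len), dtype=np.uint8)].tobytes()


# ---------------------------------------------------------------------------
# Sample simulation
# ---------------------------------------------------------------------------

def _genes_in_genomic_order(state: SimulationState) -> list[GeneSim]:
    return sorted(
        state.gene_sims.values(),
        key=lambda s: (s.gene.chrom, s.gene.canonical_transcript.exons[0].start),
    )


def _truth_rows(
    sim: GeneSim, sample_id: str, condition: str, counts: np.ndarray, config: SimulationConfig
) -> dict:
    n = int(counts.sum())
    r, c, k = _class_probs(config, condition, sim.affected)
    u12 = sim.u12
    row = {
        "sample_id": sample_id,
        "condition": condition,
        "gene_id": sim.gene.gene_id,
        "affected": sim.affected,
        "chrom": u12.chrom if u12 else "",
        "u12_start": u12.start + 1 if u12 else -1,
        "u12_end": u12.end if u12 else -1,
        "n_molecules": n,
        "true_mu": sim.mu,
        "true_expression": sim.mu / (sim.gene.exonic_length / 1000.0),
        "true_retention": r if u12 else 0.0,
        "true_cryptic": c if u12 else 0.0,
        "true_skip": k if u12 else 0.0,
    }
    for name in ISOFORM_CLASSES:
        row[f"n_{name}"] = int(counts[_CLASS_CODE[name]])
    denom = max(n, 1)
    row["retained_frac"] = counts[_CLASS_CODE[RETAINED]] / denom
    row["cryptic_frac"] = (counts[_CLASS_CODE[CRYPTIC_5P]] + counts[_CLASS_CODE[CRYPTIC_3P]]) / denom
    row["skip_frac"] = counts[_CLASS_CODE[EXON_SKIP]] / denom
    return row


def simulate_sample(
    state: SimulationState, sample_id: str, condition: str
) -> tuple[list[AlignmentRecord], pd.DataFrame]:
    """In-memory variant; suitable for small simulations and tests."""
    if condition not in (CASE, CONTROL):
        raise ConfigError(f"condition must be {CASE!r} or {CONTROL!r}, got {condition!r}")
    rng = _sample_rng(state.config, sample_id)
    records: list[AlignmentRecord] = []
    truth = []
    serial = 0
    for sim in _genes_in_genomic_order(state):
        pos0, cigars, cls, counts = _gene_reads(sim, state.config, condition, rng)
        _seqs(rng, len(pos0), state.config.read_length)  # keep RNG stream aligned with writer
        strand = sim.gene.strand
        for p, cig, cl in zip(pos0, cigars, cls):
            records.append(
                AlignmentRecord(
                    read_id=f"{sample_id}.r{serial}",
                    sample_id=sample_id,
                    chrom=sim.gene.chrom,
                    pos=int(p) + 1,
                    strand=strand,
                    ops=_parse_ops(cig),
                    truth_class=ISOFORM_CLASSES[cl],
                )
            )
            serial += 1
        truth.append(_truth_rows(sim, sample_id, condition, counts, state.config))
    return records, pd.DataFrame(truth)


def _parse_ops(cigar: str) -> tuple[tuple[str, int], ...]:
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return tuple(ops)


def sam_header(genome: dict[str, int]) -> str:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom in sorted(genome):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{genome[chrom]}")
    return "\n".join(lines) + "\n"


def write_sam(
    records: Iterable[AlignmentRecord],
    genome: dict[str, int],
    path: str,
    read_length: int = 100,
    seed: int = 0,
) -> None:
    """Write a record list as a valid coordinate-sorted SAM file.

    SEQ fields are deterministic seeded bases; QUAL is ``'I' * read_length``;
    FLAG is 0/16 by strand and MAPQ 60 throughout.
    """
    rng = np.random.default_rng(seed)
    records = list(records)
    order = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].pos))
    if order != list(range(len(records))):
        raise DataError("write_sam requires records sorted by (chrom, pos)")
    qual = "I" * read_length
    with open(path, "w") as out:
        out.write(sam_header(genome))
        for rec in records:
            if rec.chrom not in genome:
                raise DataError(f"record chromosome {rec.chrom} absent from genome")
            mlen = sum(length for op, length in rec.ops if op == "M")
            if mlen != read_length:
                raise DataError(f"read {rec.read_id}: M lengths sum to {mlen} != {read_length}")
            seq = _seqs(rng, 1, read_length).decode()
            flag = 0 if rec.strand == "+" else 16
            out.write(
                f"{rec.read_id}\t{flag}\t{rec.chrom}\t{rec.pos}\t60\t{rec.cigar()}"
                f"\t*\t0\t0\t{seq}\t{qual}\n"
            )


def write_sample_sam(
    state: SimulationState,
    sample_id: str,
    condition: str,
    sam_path: str,
    per_read_truth_path: Optional[str] = None,
) -> pd.DataFrame:
    """Streaming writer used at cohort scale: one pass, bounded memory.

    Returns the per-gene truth table for the sample.  When
    ``per_read_truth_path`` is given, a read-level sidecar TSV
    (read_id, gene_id, truth_class) is written alongside the SAM; the truth
    class never appears in the SAM itself.
    """
    if condition not in (CASE, CONTROL):
        raise ConfigError(f"condition must be {CASE!r} or {CONTROL!r}, got {condition!r}")
    cfg = state.config
    rng = _sample_rng(cfg, sample_id)
    qual = "I" * cfg.read_length
    truth = []
    serial = 0
    sidecar = open(per_read_truth_path, "w") if per_read_truth_path else None
    try:
        if sidecar:
            sidecar.write("read_id\tgene_id\ttruth_class\n")
        with open(sam_path, "w") as out:
            out.write(sam_header(state.models.genome))
            for sim in _genes_in_genomic_order(state):
                pos0, cigars, cls, counts = _gene_reads(sim, cfg, condition, rng)
                m = len(pos0)
                seqs = _seqs(rng, m, cfg.read_length)
                flag = 0 if sim.gene.strand == "+" else 16
                chrom = sim.gene.chrom
                rl = cfg.read_length
                lines = []
                for i in range(m):
                    rid = f"{sample_id}.r{serial + i}"
                    seq = seqs[i * rl:(i + 1) * rl].decode()
                    lines.append(
                        f"{rid}\t{flag}\t{chrom}\t{int(pos0[i]) + 1}\t60\t{cigars[i]}"
                        f"\t*\t0\t0\t{seq}\t{qual}"
                    )
                if lines:
                    out.write("\n".join(lines))
                    out.write("\n")
                if sidecar and m:
                    sidecar.write(
                        "".join(
                            f"{sample_id}.r{serial + i}\t{sim.gene.gene_id}\t{ISOFORM_CLASSES[cls[i]]}\n"
                            for i in range(m)
                        )
                    )
                serial += m
                truth.append(_truth_rows(sim, sample_id, condition, counts, cfg))
    finally:
        if sidecar:
            sidecar.close()
    return pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Whole-cohort convenience
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig, outdir: str) -> dict:
    """Generate gene set + all samples into ``outdir``; returns file paths.

    Writes: genome.tsv, models.gtf, intron_types.tsv, samples.tsv,
    truth_introns.tsv (per sample x gene), one ``<sample>.sam`` per sample,
    and optional per-read truth sidecars.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    state = simulate_gene_set(config)
    paths = {
        "genome": os.path.join(outdir, "genome.tsv"),
        "gtf": os.path.join(outdir, "models.gtf"),
        "intron_types": os.path.join(outdir, "intron_types.tsv"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "truth": os.path.join(outdir, "truth_introns.tsv"),
        "sams": {},
        "read_truth": {},
    }
    write_genome_tsv(state.models, paths["genome"])
    write_gtf(state.models, paths["gtf"])
    write_intron_types(state.models, paths["intron_types"])
    samples = state.sample_ids()
    with open(paths["samples"], "w") as fh:
        fh.write("sample_id\tcondition\n")
        for sid, cond in samples:
            fh.write(f"{sid}\t{cond}\n")
    truths = []
    for sid, cond in samples:
        sam = os.path.join(outdir, f"{sid}.sam")
        sidecar = os.path.join(outdir, f"{sid}.read_truth.tsv") if config.per_read_truth else None
        truths.append(write_sample_sam(state, sid, cond, sam, sidecar))
        paths["sams"][sid] = sam
        if sidecar:
            paths["read_truth"][sid] = sidecar
    pd.concat(truths, ignore_index=True).to_csv(paths["truth"], sep="\t", index=False)
    paths["state"] = state
    return paths
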