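"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own counting code paths (and
pysam): SAM is re-parsed with plain string splitting, junctions are
re-counted by walking CIGAR strings, and coverage is accumulated
position-by-position into a per-base array.
"""

from __future__ import annotations

import re
from collections import Counter

import numpy as np
import pytest

from minorsplice.simulate import SimulationConfig, simulate_cohort

CIGAR_RE = re.compile(r"(\d+)([MN])")


def parse_sam_text(path):
    """Plain-text SAM parse -> list of (qname, flag, chrom, pos1, ops)."""
    reads = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            ops = tuple((m.group(2), int(m.group(1))) for m in CIGAR_RE.finditer(f[5]))
            reads.append((f[0], int(f[1]), f[2], int(f[3]), ops))
    return reads


def naive_junction_counts(reads, min_anchor):
    """Brute-force anchored N-span counting from parsed SAM reads."""
    counts = Counter()
    for _, _, chrom, pos1, ops in reads:
        p = pos1 - 1
        for i, (op, length) in enumerate(ops):
            if op == "N":
                left = ops[i - 1] if i > 0 else None
                right = ops[i + 1] if i + 1 < len(ops) else None
                if (
                    left and right
                    and left[0] == "M" and right[0] == "M"
                    and left[1] >= min_anchor and right[1] >= min_anchor
                ):
                    counts[(chrom, p, p + length)] += 1
            p += length
    return counts


def naive_pileup(reads, chrom, start, end):
    """Per-base M-op coverage over [start, end), one position at a time."""
    cov = np.zeros(end - start, dtype=int)
    for _, _, rchrom, pos1, ops in reads:
        if rchrom != chrom:
            continue
        p = pos1 - 1
        for op, length in ops:
            if op == "M":
                for x in range(p, p + length):
                    if start <= x < end:
                        cov[x - start] += 1
            p += length
    return cov


def naive_depth(reads, chrom, start, end, edge_trim):
    lo, hi = start + edge_trim, end - edge_trim
    cov = naive_pileup(reads, chrom, lo, hi)
    return cov.sum() / (hi - lo)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """50-gene, 1 case + 1 control simulation with a per-read truth sidecar."""
    outdir = tmp_path_factory.mktemp("small_cohort")
    cfg = SimulationConfig(
        n_genes=50,
        n_case_samples=1,
        n_control_samples=1,
        mean_fragments_per_gene=200.0,
        affected_gene_fraction=0.2,
        per_read_truth=True,
        seed=7,
    )
    paths = simulate_cohort(cfg, str(outdir))
    paths["config"] = cfg
    return paths
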