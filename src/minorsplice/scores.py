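"""Per-gene, per-sample splicing metrics and the detection filter.

Four metrics summarise U12 splicing per gene and sample, covering two
readings of "splicing efficiency" (junction-based) and two of "intron
retention" (depth-based), each normalised either within-gene (two U2
reference introns) or by expression (FPKM):

* ``r_u12_u2``  = J_u12 / (mean(J_u2a, J_u2b) + pc)   -- splicing efficiency
* ``r_u12_fpkm``= J_u12 / (FPKM + pc)                 -- splicing efficiency
* ``ir_u2``     = D_u12 / (mean(D_u2a, D_u2b) + pc)   -- intron retention
* ``ir_fpkm``   = D_u12 / (FPKM + pc)                 -- intron retention

The pseudocount ``pc`` (default 0.5) applies to denominators only: a zero
numerator is meaningful (no U12-spliced reads at all), while a zero
denominator would otherwise make the ratio undefined.  Genes with several
U12 introns are averaged arithmetically across introns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

METRICS = ["r_u12_u2", "r_u12_fpkm", "ir_u2", "ir_fpkm"]
#: deficiency direction per metric: -1 = decreases, +1 = increases
METRIC_DIRECTION = {"r_u12_u2": -1, "r_u12_fpkm": -1, "ir_u2": +1, "ir_fpkm": +1}

DEFAULT_PSEUDOCOUNT = 0.5


def compute_scores(quants: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-(gene, sample) metric table from raw quantifications.

    ``quants`` is the per-U12-intron table produced by the quantify stage
    (one row per intron per sample); multi-U12 genes are averaged.  Returns
    columns gene_id, sample_id, the four metrics, n_u12_introns_averaged.
    """
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be > 0")
    required = {"gene_id", "sample_id", "j_u12", "j_u2a", "j_u2b", "d_u12", "d_u2a", "d_u2b", "fpkm"}
    missing = required - set(quants.columns)
    if missing:
        raise DataError(f"quant table missing columns: {sorted(missing)}")
    df = quants.copy()
    j_ref = (df["j_u2a"] + df["j_u2b"]) / 2.0
    d_ref = (df["d_u2a"] + df["d_u2b"]) / 2.0
    df["r_u12_u2"] = df["j_u12"] / (j_ref + pseudocount)
    df["r_u12_fpkm"] = df["j_u12"] / (df["fpkm"] + pseudocount)
    df["ir_u2"] = df["d_u12"] / (d_ref + pseudocount)
    df["ir_fpkm"] = df["d_u12"] / (df["fpkm"] + pseudocount)
    grouped = (
        df.groupby(["gene_id", "sample_id"], sort=True)
        .agg(
            r_u12_u2=("r_u12_u2", "mean"),
            r_u12_fpkm=("r_u12_fpkm", "mean"),
            ir_u2=("ir_u2", "mean"),
            ir_fpkm=("ir_fpkm", "mean"),
            n_u12_introns_averaged=("r_u12_u2", "size"),
        )
        .reset_index()
    )
    return grouped


@dataclass
class DetectionThresholds:
    min_fpkm: float = 1.0
    min_ref_junction_reads: int = 10  # on J_u2a + J_u2b


def detection_filter(
    quants: pd.DataFrame, thresholds: DetectionThresholds | None = None
) -> tuple[set[str], pd.DataFrame]:
    """Genes detected at sufficient levels for case/control comparison.

    A gene is detected iff in EVERY sample each of its U12 introns has
    FPKM >= min_fpkm and J_u2a + J_u2b >= min_ref_junction_reads.  Returns
    the detected gene set and a per-gene report of failures.
    """
    thresholds = thresholds or DetectionThresholds()
    df = quants.copy()
    df["_fpkm_ok"] = df["fpkm"] >= thresholds.min_fpkm
    df["_ref_ok"] = (df["j_u2a"] + df["j_u2b"]) >= thresholds.min_ref_junction_reads
    per_gene = df.groupby("gene_id").agg(
        n_rows=("gene_id", "size"),
        fpkm_fail=("_fpkm_ok", lambda s: int((~s).sum())),
        ref_fail=("_ref_ok", lambda s: int((~s).sum())),
        min_fpkm=("fpkm", "min"),
        min_ref_reads=("j_u2a", lambda s: np.nan),  # placeholder, replaced below
    )
    ref_min = (df["j_u2a"] + df["j_u2b"]).groupby(df["gene_id"]).min()
    per_gene["min_ref_reads"] = ref_min
    per_gene["detected"] = (per_gene["fpkm_fail"] == 0) & (per_gene["ref_fail"] == 0)

    def _reason(row):
        if row["detected"]:
            return ""
        reasons = []
        if row["fpkm_fail"]:
            reasons.append("low_fpkm")
        if row["ref_fail"]:
            reasons.append("low_reference_junction_reads")
        return ";".join(reasons)

    per_gene["reason"] = per_gene.apply(_reason, axis=1)
    report = per_gene.reset_index()[
        ["gene_id", "detected", "reason", "min_fpkm", "min_ref_reads"]
    ]
    detected = set(report.loc[report["detected"], "gene_id"])
    return detected, report
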