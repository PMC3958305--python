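"""Case-vs-control outlier analysis of per-gene splicing metrics.

The comparison follows an SD-threshold outlier design rather than formal
hypothesis tests: genes whose control-sample metric values are too variable
(coefficient of variation above ``cv_max`` on any metric) are discarded;
for the remainder each metric is converted to a z-score against the control
mean and SD; and a gene is flagged when at least ``min_metrics`` metrics
exceed ``z_threshold`` standard deviations in the deficiency direction
(splicing-efficiency metrics decreased, retention metrics increased).

The public surface is statsmodels-like: build a
:class:`SplicingOutlierModel` from a scores table and a sample->condition
mapping, call :meth:`~SplicingOutlierModel.fit`, and read estimates,
flags and the ranked table off the returned
:class:`SplicingOutlierResults` (``summary()`` renders a text report).

Case aggregation
----------------
With very few case samples the group mean is dominated by single-sample
noise and the z statistic has heavy t-like tails (the control SD is
estimated from few samples), so the default here is consistency-based:
``case_aggregation="all"`` flags a metric only when *every* case sample
exceeds the threshold, and reports the least-extreme case z.  The
group-mean variant (``"mean"``) is available via config.  See
docs/methods.md for the calibration analysis behind this default.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .scores import METRICS, METRIC_DIRECTION

CASE = "case"
CONTROL = "control"


@dataclass
class CohortConfig:
    z_threshold: float = 2.0
    min_metrics: int = 2
    cv_max: float = 0.5
    sd_floor: float = 1e-6
    case_aggregation: str = "all"  # "all" (consistency) or "mean" (group mean)
    two_sided: bool = False

    def validate(self) -> None:
        if self.z_threshold <= 0:
            raise ConfigError("z_threshold must be > 0")
        if not 1 <= self.min_metrics <= len(METRICS):
            raise ConfigError(f"min_metrics must be in [1, {len(METRICS)}]")
        if self.cv_max <= 0:
            raise ConfigError("cv_max must be > 0")
        if self.sd_floor <= 0:
            raise ConfigError("sd_floor must be > 0")
        if self.case_aggregation not in ("mean", "all"):
            raise ConfigError("case_aggregation must be 'mean' or 'all'")


# ---------------------------------------------------------------------------
# Functional operations
# ---------------------------------------------------------------------------

def filter_variable_genes(
    control_scores: pd.DataFrame, cv_max: float, sd_floor: float = 1e-6
) -> tuple[set[str], pd.DataFrame]:
    """Discard genes with high control variability on any metric.

    For each metric, CV = sample SD / mean over control samples (mean
    floored at ``sd_floor``); a gene is discarded iff CV > cv_max on ANY
    metric.  Requires >= 2 control samples.  Returns (retained gene ids,
    per-gene report with CVs and the discard flag).
    """
    n_ctrl = control_scores["sample_id"].nunique()
    if n_ctrl < 2:
        raise DataError("control variability is undefined with fewer than 2 control samples")
    g = control_scores.groupby("gene_id")[METRICS]
    mean = g.mean()
    sd = g.std(ddof=1)
    cv = sd / mean.clip(lower=sd_floor)
    report = cv.add_prefix("cv_").reset_index()
    report["discarded"] = (cv > cv_max).any(axis=1).values
    retained = set(report.loc[~report["discarded"], "gene_id"])
    return retained, report


def compute_zscores(
    case_scores: pd.DataFrame,
    control_scores: pd.DataFrame,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """z per gene per metric: (case statistic - control mean) / control SD.

    The control SD is floored at ``sd_floor``.  With
    ``case_aggregation="mean"`` the case statistic is the mean over case
    samples; with ``"all"`` a z is computed per case sample and the
    minimum-|z| (least extreme) sample is reported, so a threshold on the
    reported z is a threshold every case sample must clear.  Returns a
    frame indexed by gene_id with columns ``z_<metric>`` plus, for "all",
    ``all_<metric>`` booleans recording whether every case sample exceeded
    the threshold in the metric's deficiency direction.
    """
    config = config or CohortConfig()
    config.validate()
    n_ctrl = control_scores["sample_id"].nunique()
    n_case = case_scores["sample_id"].nunique()
    if n_ctrl < 2:
        raise DataError("need >= 2 control samples")
    if n_case < 1:
        raise DataError("need >= 1 case sample")
    g = control_scores.groupby("gene_id")[METRICS]
    mean = g.mean()
    sd = g.std(ddof=1).clip(lower=config.sd_floor)

    case_by_gene = case_scores.pivot_table(
        index="gene_id", columns="sample_id", values=METRICS, sort=True
    )
    genes = mean.index.intersection(case_by_gene.index)
    out = pd.DataFrame(index=genes)
    for metric in METRICS:
        zs = case_by_gene[metric].loc[genes].sub(mean.loc[genes, metric], axis=0).div(
            sd.loc[genes, metric], axis=0
        )  # genes x case samples
        if config.case_aggregation == "mean":
            out[f"z_{metric}"] = zs.mean(axis=1)
        else:
            # report the least-extreme case sample
            amin = zs.abs().values.argmin(axis=1)
            out[f"z_{metric}"] = zs.values[np.arange(len(zs)), amin]
            direction = METRIC_DIRECTION[metric]
            if config.two_sided:
                exceed = (zs.abs() >= config.z_threshold).all(axis=1) & (
                    np.sign(zs).nunique(axis=1) == 1
                )
            else:
                exceed = (zs * direction >= config.z_threshold).all(axis=1)
            out[f"all_{metric}"] = exceed
    out.index.name = "gene_id"
    return out


def rank_genes(zscores: pd.DataFrame, config: CohortConfig | None = None) -> pd.DataFrame:
    """Apply the >=2-SD-in->=min_metrics rule and rank genes.

    A metric is flagged when its z exceeds the threshold in the deficiency
    direction (z <= -threshold for efficiency metrics, z >= +threshold for
    retention metrics; both directions when ``two_sided``).  A gene is
    flagged when at least ``min_metrics`` metrics are flagged.  The output
    is sorted by rank_score (max |z| over flagged metrics, 0 for unflagged
    genes) descending with ties broken by gene_id ascending; ``rank`` is a
    1-based permutation.
    """
    config = config or CohortConfig()
    config.validate()
    df = zscores.reset_index() if zscores.index.name == "gene_id" else zscores.copy()
    flags = {}
    for metric in METRICS:
        z = df[f"z_{metric}"]
        direction = METRIC_DIRECTION[metric]
        if config.two_sided:
            hit = z.abs() >= config.z_threshold
        else:
            hit = z * direction >= config.z_threshold
        if f"all_{metric}" in df.columns:
            hit = hit & df[f"all_{metric}"]
        flags[metric] = hit
        df[f"flag_{metric}"] = hit
    flag_frame = pd.DataFrame(flags)
    df["n_flagged_metrics"] = flag_frame.sum(axis=1)
    df["flagged"] = df["n_flagged_metrics"] >= config.min_metrics
    zcols = df[[f"z_{m}" for m in METRICS]].abs()
    zcols = zcols.where(flag_frame.values, other=0.0)
    df["rank_score"] = zcols.max(axis=1)
    df = df.sort_values(["rank_score", "gene_id"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    keep = (
        ["gene_id"]
        + [f"z_{m}" for m in METRICS]
        + [f"flag_{m}" for m in METRICS]
        + ["n_flagged_metrics", "flagged", "rank_score", "rank"]
    )
    return df[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class SplicingOutlierModel:
    """Case-vs-control splicing-deficiency outlier model.

    Parameters
    ----------
    scores
        Long-format metric table with columns gene_id, sample_id and the
        four metrics (output of the scores stage).
    samples
        Mapping sample_id -> condition ("case"/"control"), or a DataFrame
        with columns sample_id, condition.
    config, **overrides
        Analysis parameters; keyword overrides update the config fields.
    """

    def __init__(
        self,
        scores: pd.DataFrame,
        samples,
        config: CohortConfig | None = None,
        **overrides,
    ):
        if isinstance(samples, pd.DataFrame):
            if not {"sample_id", "condition"} <= set(samples.columns):
                raise DataError("samples table needs columns sample_id, condition")
            samples = dict(zip(samples["sample_id"], samples["condition"]))
        bad = set(samples.values()) - {CASE, CONTROL}
        if bad:
            raise DataError(f"invalid condition values: {sorted(bad)}")
        missing = set(scores["sample_id"]) - set(samples)
        if missing:
            raise DataError(f"samples with scores but no condition: {sorted(missing)}")
        self.scores = scores.copy()
        self.samples = dict(samples)
        self.config = config or CohortConfig()
        for key, value in overrides.items():
            if not hasattr(self.config, key):
                raise ConfigError(f"unknown cohort config field {key!r}")
            setattr(self.config, key, value)
        self.config.validate()

    @classmethod
    def from_tables(cls, scores_path: str, samples_path: str, **kwargs) -> "SplicingOutlierModel":
        scores = pd.read_csv(scores_path, sep="\t")
        samples = pd.read_csv(samples_path, sep="\t")
        return cls(scores, samples, **kwargs)

    @property
    def case_sample_ids(self) -> list[str]:
        return sorted(s for s, c in self.samples.items() if c == CASE)

    @property
    def control_sample_ids(self) -> list[str]:
        return sorted(s for s, c in self.samples.items() if c == CONTROL)

    def fit(self) -> "SplicingOutlierResults":
        ctrl = self.scores[self.scores["sample_id"].isin(self.control_sample_ids)]
        case = self.scores[self.scores["sample_id"].isin(self.case_sample_ids)]
        if ctrl["sample_id"].nunique() < 2:
            raise DataError("need >= 2 control samples")
        if case["sample_id"].nunique() < 1:
            raise DataError("need >= 1 case sample")
        retained, cv_report = filter_variable_genes(
            ctrl, cv_max=self.config.cv_max, sd_floor=self.config.sd_floor
        )
        # genes must be scored in every sample to be comparable
        counts = self.scores.groupby("gene_id")["sample_id"].nunique()
        complete = set(counts[counts == len(self.samples)].index)
        usable = sorted(retained & complete)
        zscores = compute_zscores(
            case[case["gene_id"].isin(usable)],
            ctrl[ctrl["gene_id"].isin(usable)],
            self.config,
        )
        ranked = rank_genes(zscores, self.config)
        return SplicingOutlierResults(
            model=self,
            ranked=ranked,
            zscores=zscores,
            cv_report=cv_report,
            retained_genes=set(usable),
        )


@dataclass
class SplicingOutlierResults:
    """Fit output: ranked genes, z-scores and the variability filter report."""

    model: SplicingOutlierModel
    ranked: pd.DataFrame
    zscores: pd.DataFrame
    cv_report: pd.DataFrame
    retained_genes: set[str] = field(default_factory=set)

    @property
    def flagged_genes(self) -> list[str]:
        return sorted(self.ranked.loc[self.ranked["flagged"], "gene_id"])

    @property
    def n_discarded(self) -> int:
        return int(self.cv_report["discarded"].sum())

    def summary(self, top: int = 15) -> str:
        cfg = self.model.config
        buf = io.StringIO()
        buf.write("Splicing-deficiency outlier analysis\n")
        buf.write("=" * 52 + "\n")
        buf.write(
            f"samples: {len(self.model.case_sample_ids)} case, "
            f"{len(self.model.control_sample_ids)} control\n"
        )
        buf.write(
            f"rule: |z| >= {cfg.z_threshold:g} (deficiency direction) in >= "
            f"{cfg.min_metrics} of {len(METRICS)} metrics; "
            f"case aggregation: {cfg.case_aggregation}\n"
        )
        buf.write(
            f"genes analysed: {len(self.ranked)}  "
            f"(discarded by control CV > {cfg.cv_max:g}: {self.n_discarded})\n"
        )
        buf.write(f"flagged genes: {len(self.flagged_genes)}\n\n")
        head = self.ranked.head(top)
        cols = ["rank", "gene_id"] + [f"z_{m}" for m in METRICS] + ["n_flagged_metrics", "flagged"]
        buf.write(head[cols].to_string(index=False, float_format=lambda v: f"{v:8.2f}"))
        buf.write("\n")
        return buf.getvalue()
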