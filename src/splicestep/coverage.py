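"""Per-feature coverage, cross-sample normalization, bias diagnostics and
intron splicing-speed classification.

The working assumption is kinetic: the slower an intron is removed, the
longer it exists in the nuclear RNA pool and the higher its sequencing
coverage.  Raw per-intron medians are put on a common depth scale by
normalizing each sample with the ratio of the grand mean exon coverage to
that sample's mean exon coverage, so the fast/slow cutoffs (defaults 90 and
130) stay interpretable as read depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .gene_model import GeneModel
from .read_classify import _passes_filters

__all__ = [
    "CoverageError",
    "RegressionResult",
    "depth_from_alignments",
    "feature_depths",
    "median_feature_coverage",
    "feature_median_table",
    "normalize_coverage",
    "gc_bias_regression",
    "positional_bias_regression",
    "classify_intron_speed",
    "window_reports",
    "detect_coverage_outliers",
    "replicate_correlation",
    "gc_fraction",
]

SPEED_CLASSES = ("fast", "intermediate", "slow")


class CoverageError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    degenerate: bool = False


def depth_from_alignments(path: str, model: GeneModel, max_mismatches: int = 5) -> np.ndarray:
    """Per-base depth over the gene span from matched alignment blocks.

    Skipped ('N') gaps contribute no depth.  Works on unindexed SAM: a single
    sequential pass with difference-array accumulation.
    """
    s, e = model.span
    diff = np.zeros(model.span_length + 1, dtype=np.int64)
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for seg in fh:
            if not _passes_filters(seg, max_mismatches):
                continue
            for bs0, be0 in seg.get_blocks():  # 0-based half-open
                lo = max(bs0 + 1, s)
                hi = min(be0, e)
                if hi >= lo:
                    diff[lo - s] += 1
                    diff[hi - s + 1] -= 1
    return np.cumsum(diff[:-1])


def feature_depths(depth: np.ndarray, feature, model: GeneModel) -> np.ndarray:
    """Depth values over the feature's unmasked positions (zeros retained)."""
    s, _ = model.span
    vals = depth[feature.start - s : feature.end - s + 1]
    return vals[model.unmasked_bool(feature.start, feature.end)]


def median_feature_coverage(values: np.ndarray) -> float:
    """Median depth over unmasked positions; even count -> mean of central pair."""
    values = np.asarray(values)
    if values.size == 0:
        raise CoverageError("no coverage basis: feature fully masked")
    return float(np.median(values))


def feature_median_table(depth: np.ndarray, model: GeneModel) -> pd.DataFrame:
    """Raw median coverage for every exon and intron of one sample."""
    rows = []
    for kind, feats in (("exon", model.exons), ("intron", model.introns)):
        for f in feats:
            vals = feature_depths(depth, f, model)
            rows.append(
                {
                    "feature": kind,
                    "index": f.index,
                    "fully_masked": vals.size == 0,
                    "raw_median": np.nan if vals.size == 0 else float(np.median(vals)),
                }
            )
    return pd.DataFrame(rows)


def normalize_coverage(
    tables: dict[str, pd.DataFrame], reference_depth: float | None = None
) -> pd.DataFrame:
    """Cross-sample normalization of per-feature medians.

    ``tables`` maps sample id -> feature_median_table output.  Each sample is
    scaled by ``reference_depth`` / (its own mean exon coverage), keeping
    values in read-depth units so fixed fast/slow cutoffs stay meaningful;
    the reported per-feature value is the mean of normalized medians over
    samples.  ``reference_depth`` defaults to the grand mean exon coverage of
    the supplied samples; pin it explicitly to make normalized values exactly
    independent of any one sample's sequencing depth.
    """
    exon_means = {}
    for sid, tab in tables.items():
        m = tab.loc[(tab.feature == "exon") & ~tab.fully_masked, "raw_median"].mean()
        if not np.isfinite(m) or m == 0:
            raise CoverageError(f"sample {sid} rejected: zero mean exon coverage")
        exon_means[sid] = m
    grand = (
        float(np.mean(list(exon_means.values())))
        if reference_depth is None
        else float(reference_depth)
    )
    frames = []
    for sid, tab in tables.items():
        t = tab.copy()
        t["sample_id"] = sid
        t["normalized_median"] = t.raw_median * (grand / exon_means[sid])
        frames.append(t)
    long = pd.concat(frames, ignore_index=True)
    avg = (
        long.groupby(["feature", "index"], as_index=False)
        .normalized_median.mean()
        .rename(columns={"normalized_median": "cross_sample_mean"})
    )
    return long.merge(avg, on=["feature", "index"])


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or np.allclose(x, x[0]):
        return RegressionResult(np.nan, np.nan, np.nan, degenerate=True)
    res = stats.linregress(x, y)
    return RegressionResult(res.slope, res.intercept, res.pvalue)


def gc_bias_regression(gc: np.ndarray, medians: np.ndarray) -> RegressionResult:
    """OLS of median coverage on GC fraction; the pipeline only warns (and
    proceeds uncorrected) when p < 0.05."""
    return _ols(gc, medians)


def positional_bias_regression(medians: np.ndarray) -> RegressionResult:
    """OLS of per-intron medians on intron index 1..N; a significantly
    negative slope indicates a 5'->3' coverage bias (post-transcriptional
    splicing signature)."""
    return _ols(np.arange(1, len(medians) + 1), medians)


def classify_intron_speed(values, cutoffs: tuple[float, float] = (90.0, 130.0)) -> list[str]:
    """fast (< low cutoff), slow (> high cutoff), else intermediate."""
    lo, hi = cutoffs
    out = []
    for v in values:
        if not np.isfinite(v):
            out.append("intermediate")
        elif v < lo:
            out.append("fast")
        elif v > hi:
            out.append("slow")
        else:
            out.append("intermediate")
    return out


def window_reports(values, window: int = 5, step: int = 3) -> list[dict]:
    """Sliding units of ``window`` introns shifted by ``step`` (final partial
    window allowed): each reports its members ranked by normalized coverage.
    78 introns with the defaults give 26 units."""
    values = list(values)
    n = len(values)
    if n < window:
        raise CoverageError(f"need at least {window} introns")
    reports = []
    for start in range(0, n, step):
        members = list(range(start + 1, min(start + window, n) + 1))
        vals = [values[i - 1] for i in members]
        order = [members[i] for i in np.argsort(vals, kind="stable")]
        reports.append({"start": start + 1, "members": members, "ranked": order})
    return reports


def detect_coverage_outliers(
    depth: np.ndarray, model: GeneModel, spike_ratio: float = 5.0
) -> list[int]:
    """Introns whose masked profile still has a >spike_ratio local spike
    (95th percentile / median); these are excluded from regressions."""
    out = []
    for intr in model.introns:
        vals = feature_depths(depth, intr, model)
        if vals.size == 0:
            continue
        med = np.median(vals)
        p95 = np.percentile(vals, 95)
        if med > 0 and p95 / med > spike_ratio:
            out.append(intr.index)
    return out


def replicate_correlation(x, y, log: bool = True) -> tuple[float, float]:
    """Pearson R between two replicates' intron medians (log scale by
    default; non-positive values are excluded pairwise)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if log:
        keep = (x > 0) & (y > 0)
        x, y = np.log(x[keep]), np.log(y[keep])
    if x.size < 3 or np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise CoverageError("degenerate correlation input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt
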