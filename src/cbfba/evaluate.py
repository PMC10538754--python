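"""Comparison of predicted fluxes against experimentally estimated fluxes.

Implements the evaluation battery used to judge flux predictions against
labeling-experiment (13C-MFA) estimates: active/blocked concordance,
range overlap with confidence intervals, categorization of variability
ranges, log-flux Pearson concordance, per-reaction location tests of the
sampling distribution against the experimental mean (FDR-adjusted),
regression-residual outlier detection, Euclidean metabolic-adjustment
distances between paired sample sets, and per-subsystem summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

#: flux magnitude below which a reaction is considered blocked
ACTIVE_THRESHOLD = 1e-6

#: tolerance for "same endpoint" / "identical range" comparisons
TIE_TOL = 1e-9

RANGE_CATEGORIES = (
    "same_min_higher_max",    # pFBA same minimum, higher maximum
    "containment",            # pFBA range strictly contains the cbFBA range
    "shifted_overlap",        # pFBA shifted higher, ranges overlap
    "shifted_disjoint",       # pFBA shifted higher, no overlap
    "identical",
    "other",
)


@dataclass
class ExperimentalFluxes:
    """Experimental flux estimates with confidence intervals for one strain."""

    table: pd.DataFrame   # columns: reaction_id, mean, ci_lower, ci_upper
    strain_id: str = "experiment"

    def __post_init__(self):
        required = {"reaction_id", "mean", "ci_lower", "ci_upper"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"experimental table needs columns {sorted(required)}")
        t = self.table
        complete = t.dropna(subset=["mean", "ci_lower", "ci_upper"])
        bad = complete[(complete.ci_lower > complete["mean"] + TIE_TOL)
                       | (complete["mean"] > complete.ci_upper + TIE_TOL)]
        if len(bad):
            raise ValueError(
                "confidence interval does not contain the mean for "
                + ", ".join(bad.reaction_id.astype(str).head()))
        self.table = self.table.set_index("reaction_id", drop=False)

    @property
    def reaction_ids(self):
        return list(self.table.reaction_id)

    def mean(self, rid):
        return float(self.table.loc[rid, "mean"])

    def interval(self, rid):
        row = self.table.loc[rid]
        return float(row.ci_lower), float(row.ci_upper)


def read_experimental_fluxes(path, strain_id=None):
    """Read a CSV/TSV of experimental fluxes (reaction_id, mean, ci_lower, ci_upper)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    return ExperimentalFluxes(df, strain_id or "experiment")


# ---------------------------------------------------------------------------
# Activity classification
# ---------------------------------------------------------------------------

def classify_active(flux, threshold=ACTIVE_THRESHOLD):
    """Active/blocked call for a flux value or a (min, max) range.

    A value is active iff |flux| >= threshold; a range is active iff the
    maximal |flux| over the interval reaches the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if np.ndim(flux) == 1 and len(flux) == 2:
        lo, hi = flux
        return max(abs(lo), abs(hi)) >= threshold
    return bool(abs(float(flux)) >= threshold)


def confusion_metrics(predicted, experimental):
    """Sensitivity, specificity and accuracy of active-reaction calls.

    Experimental-active is the positive class. Undefined ratios (empty
    positive or negative class) are reported as NaN, never silently zero.
    """
    predicted = np.asarray(predicted, dtype=bool)
    experimental = np.asarray(experimental, dtype=bool)
    if predicted.shape != experimental.shape:
        raise ValueError("flag vectors must have the same length")
    if predicted.size == 0:
        raise ValueError("empty comparison set")
    tp = int(np.sum(predicted & experimental))
    tn = int(np.sum(~predicted & ~experimental))
    fp = int(np.sum(predicted & ~experimental))
    fn = int(np.sum(~predicted & experimental))
    sens = tp / (tp + fn) if (tp + fn) else math.nan
    spec = tn / (tn + fp) if (tn + fp) else math.nan
    acc = (tp + tn) / predicted.size
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "tp": tp, "tn": tn, "fp": fp, "fn": fn}


# ---------------------------------------------------------------------------
# Range comparisons
# ---------------------------------------------------------------------------

def range_overlap(predicted, experimental):
    """Per-reaction overlap between predicted flux ranges and experimental CIs.

    Intervals are closed: touching endpoints count as overlap. Reactions
    missing an interval on either side are excluded and listed.

    Parameters
    ----------
    predicted : FluxRanges or dict reaction_id -> (lo, hi)
    experimental : ExperimentalFluxes

    Returns
    -------
    dict with per-reaction ``overlaps`` (bool), the overall ``fraction`` and
    the ``excluded`` reaction list.
    """
    pred = predicted.as_dict() if hasattr(predicted, "as_dict") else dict(predicted)
    overlaps = {}
    excluded = []
    for rid in experimental.reaction_ids:
        lo_e, hi_e = experimental.interval(rid)
        if rid not in pred or not (np.isfinite(lo_e) and np.isfinite(hi_e)):
            excluded.append(rid)
            continue
        lo_p, hi_p = pred[rid]
        overlaps[rid] = max(lo_p, lo_e) <= min(hi_p, hi_e)
    fraction = (sum(overlaps.values()) / len(overlaps)) if overlaps else math.nan
    return {"overlaps": overlaps, "fraction": fraction, "excluded": excluded}


def categorize_ranges(pfba_range, cbfba_range, tie_tol=TIE_TOL):
    """Assign one of the range-comparison categories to a reaction.

    Compares the pFBA variability interval to the cbFBA one: same minimum
    with a higher maximum in pFBA, strict containment of the cbFBA range,
    upward shift with or without overlap, identical ranges, or ``other``.
    The categories are mutually exclusive under the tie tolerance.
    """
    p_lo, p_hi = map(float, pfba_range)
    c_lo, c_hi = map(float, cbfba_range)
    same_lo = abs(p_lo - c_lo) <= tie_tol
    same_hi = abs(p_hi - c_hi) <= tie_tol
    if same_lo and same_hi:
        return "identical"
    if same_lo and p_hi > c_hi + tie_tol:
        return "same_min_higher_max"
    if p_lo < c_lo - tie_tol and p_hi > c_hi + tie_tol:
        return "containment"
    if p_lo > c_lo + tie_tol and p_hi > c_hi + tie_tol:
        # shifted higher; overlap decided on closed intervals
        return "shifted_overlap" if p_lo <= c_hi + tie_tol else "shifted_disjoint"
    return "other"


def categorize_range_sets(pfba_ranges, cbfba_ranges, tie_tol=TIE_TOL):
    """Category per reaction for two :class:`FluxRanges` on the same reactions."""
    p = pfba_ranges.as_dict()
    c = cbfba_ranges.as_dict()
    return {rid: categorize_ranges(p[rid], c[rid], tie_tol)
            for rid in p if rid in c}


# ---------------------------------------------------------------------------
# Flux concordance
# ---------------------------------------------------------------------------

def log_flux_correlation(mean_a, mean_b, joint_active_mask=None,
                         threshold=ACTIVE_THRESHOLD):
    """Pearson correlation of log10 |flux| over jointly active reactions.

    Returns NaN (with a warning) when fewer than three reactions are jointly
    active. Zero fluxes never enter the logarithm: the active mask excludes
    them by construction.
    """
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if joint_active_mask is None:
        joint_active_mask = (np.abs(a) >= threshold) & (np.abs(b) >= threshold)
    mask = np.asarray(joint_active_mask, dtype=bool)
    if mask.sum() < 3:
        warnings.warn("fewer than 3 jointly active reactions; correlation "
                      "undefined", stacklevel=2)
        return math.nan
    la = np.log10(np.abs(a[mask]))
    lb = np.log10(np.abs(b[mask]))
    if np.ptp(la) == 0 or np.ptp(lb) == 0:
        warnings.warn("constant log-flux vector; correlation undefined",
                      stacklevel=2)
        return math.nan
    return float(stats.pearsonr(la, lb).statistic)


def mean_difference_test(samples, experimental, fdr_level=0.05,
                         test="t", degenerate_atol=ACTIVE_THRESHOLD):
    """Per-reaction location test of sampled fluxes against experimental means.

    For every experimental reaction present in the sample set, tests whether
    the sampling distribution's location differs from the experimental mean
    (one-sample t-test by default; ``test="quantile"`` uses the empirical
    two-sided tail probability of the experimental mean under the samples).
    P-values are Benjamini-Hochberg adjusted across reactions; a reaction is
    flagged "no significant difference" when its adjusted p exceeds
    ``fdr_level``. Zero-variance sampling distributions are compared to the
    mean with absolute tolerance ``degenerate_atol`` and flagged degenerate.

    Returns
    -------
    pandas.DataFrame with columns reaction_id, sample_mean, experimental_mean,
    p, p_adjusted, degenerate, no_difference; plus a ``fraction_no_difference``
    entry in ``.attrs``.
    """
    rid_index = {rid: j for j, rid in enumerate(samples.reaction_ids)}
    rows = []
    for rid in experimental.reaction_ids:
        if rid not in rid_index:
            continue
        x = samples.V[:, rid_index[rid]]
        mu = experimental.mean(rid)
        degenerate = bool(np.ptp(x) < 1e-12)
        if degenerate:
            p = math.nan
            nodiff = abs(float(x.mean()) - mu) <= degenerate_atol
        elif test == "t":
            p = float(stats.ttest_1samp(x, popmean=mu).pvalue)
            nodiff = None
        elif test == "quantile":
            frac = float(np.mean(x <= mu))
            p = max(min(2.0 * min(frac, 1.0 - frac), 1.0), 1.0 / (len(x) + 1))
            nodiff = None
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"reaction_id": rid, "sample_mean": float(x.mean()),
                     "experimental_mean": mu, "p": p,
                     "degenerate": degenerate, "no_difference": nodiff})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no experimental reaction maps into the sample set")
    tested = df[~df.degenerate]
    df["p_adjusted"] = np.nan
    if len(tested):
        adj = stats.false_discovery_control(tested.p.values, method="bh")
        df.loc[tested.index, "p_adjusted"] = adj
        df.loc[tested.index, "no_difference"] = adj > fdr_level
    df["no_difference"] = df["no_difference"].astype(bool)
    df.attrs["fraction_no_difference"] = float(df.no_difference.mean())
    df.attrs["fdr_level"] = fdr_level
    df.attrs["test"] = test
    return df


def detect_outliers(predicted_means, experimental_means, joint_active_mask=None,
                    threshold=ACTIVE_THRESHOLD):
    """Outlier reactions from the log-log regression of experiment on prediction.

    Fits an ordinary least-squares line to (log10 |predicted|,
    log10 |experimental|) over jointly active reactions; with residual scale
    ``s = sqrt(sum((y_hat - y)^2) / (n - 2))``, a reaction is an outlier iff
    its |residual| exceeds 2 s (single pass, no refitting).

    Returns
    -------
    dict with ``outliers`` (indices into the input vectors), ``s``, ``slope``,
    ``intercept`` and the boolean ``mask`` of compared reactions.
    """
    x = np.asarray(predicted_means, dtype=float)
    y = np.asarray(experimental_means, dtype=float)
    if joint_active_mask is None:
        joint_active_mask = (np.abs(x) >= threshold) & (np.abs(y) >= threshold)
    mask = np.asarray(joint_active_mask, dtype=bool)
    n = int(mask.sum())
    if n <= 2:
        raise ValueError("need at least 3 jointly active reactions")
    lx = np.log10(np.abs(x[mask]))
    ly = np.log10(np.abs(y[mask]))
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    s = math.sqrt(float(np.sum(resid ** 2)) / (n - 2))
    idx = np.nonzero(mask)[0]
    outliers = set(idx[np.abs(resid) > 2.0 * s]) if s > 0 else set()
    return {"outliers": outliers, "s": s, "slope": float(slope),
            "intercept": float(intercept), "mask": mask}


# ---------------------------------------------------------------------------
# Metabolic adjustment
# ---------------------------------------------------------------------------

def metabolic_adjustment(samples_mutant, samples_wildtype, pairing_seed=None,
                         trim=0.05):
    """Euclidean distances between paired mutant and wild-type flux samples.

    Pairs each mutant sample with a randomly chosen wild-type sample
    (reproducible via ``pairing_seed``) and returns the distribution of
    Euclidean distances over the shared reaction universe together with its
    trimmed ("robust") mean. Mismatched universes are intersected with a
    warning.
    """
    shared = [rid for rid in samples_mutant.reaction_ids
              if rid in set(samples_wildtype.reaction_ids)]
    if not shared:
        raise ValueError("sample sets share no reactions")
    if len(shared) != len(samples_mutant.reaction_ids) or \
            len(shared) != len(samples_wildtype.reaction_ids):
        warnings.warn("reaction universes differ; using their intersection "
                      f"({len(shared)} reactions)", stacklevel=2)
    mi = [samples_mutant.reaction_ids.index(rid) for rid in shared]
    wi = [samples_wildtype.reaction_ids.index(rid) for rid in shared]
    M = samples_mutant.V[:, mi]
    W = samples_wildtype.V[:, wi]
    n = min(M.shape[0], W.shape[0])
    rng = np.random.default_rng(pairing_seed)
    mut_idx = rng.permutation(M.shape[0])[:n]
    wt_idx = rng.permutation(W.shape[0])[:n]
    distances = np.linalg.norm(M[mut_idx] - W[wt_idx], axis=1)
    from .optimize import robust_mean
    rm = float(robust_mean(distances[:, None], trim=trim)[0])
    return {"distances": distances, "robust_mean": rm,
            "reactions": shared, "n_pairs": int(n)}


# ---------------------------------------------------------------------------
# Subsystem aggregation
# ---------------------------------------------------------------------------

def subsystem_summary(ranges_by_method, model, categories=None,
                      width_floor=ACTIVE_THRESHOLD):
    """Per-subsystem aggregates of flux-range widths (and category counts).

    For each subsystem and each method, reports the mean of
    ``log10(max - min)`` over reactions with width above ``width_floor``
    (degenerate widths are counted separately rather than entering the
    logarithm). No enrichment statistics are computed — only the grouping.

    Parameters
    ----------
    ranges_by_method : dict method name -> FluxRanges
    model : MetabolicModel (supplies subsystem labels)
    categories : optional dict reaction_id -> category
    """
    if not model.subsystems:
        raise ValueError("model carries no subsystem labels")
    rows = []
    for method, ranges in ranges_by_method.items():
        d = ranges.as_dict()
        groups = {}
        for rid, (lo, hi) in d.items():
            sub = model.subsystems.get(rid)
            if sub is None:
                continue
            groups.setdefault(sub, []).append((rid, hi - lo))
        for sub, vals in groups.items():
            widths = np.array([w for _, w in vals])
            wide = widths[widths > width_floor]
            row = {"subsystem": sub, "method": method,
                   "n_reactions": len(vals),
                   "n_variable": int(wide.size),
                   "mean_log10_range": float(np.mean(np.log10(wide)))
                   if wide.size else math.nan}
            if categories:
                for cat in RANGE_CATEGORIES:
                    row[f"n_{cat}"] = sum(
                        1 for rid, _ in vals if categories.get(rid) == cat)
            rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["subsystem", "method", "n_reactions",
                                     "n_variable", "mean_log10_range"])
    df = pd.DataFrame(rows)
    return df[df.n_reactions > 0].reset_index(drop=True)


@dataclass
class EvaluationReport:
    """Bundle of every comparison statistic for one strain/method."""

    strain_id: str
    method: str
    confusion: dict
    overlap: dict
    log_pearson: float
    mean_difference: pd.DataFrame
    outliers: Optional[dict] = None
    categories: Optional[dict] = None
    extras: dict = field(default_factory=dict)

    def summary(self):
        return {
            "strain_id": self.strain_id,
            "method": self.method,
            "sensitivity": self.confusion["sensitivity"],
            "specificity": self.confusion["specificity"],
            "accuracy": self.confusion["accuracy"],
            "overlap_fraction": self.overlap["fraction"],
            "log_pearson": self.log_pearson,
            "fraction_no_difference":
                self.mean_difference.attrs.get("fraction_no_difference"),
            "n_outliers": len(self.outliers["outliers"]) if self.outliers else None,
        }


def evaluate_predictions(method, ranges, samples, experimental,
                         threshold=ACTIVE_THRESHOLD, fdr_level=0.05,
                         pfba_ranges=None):
    """Assemble an :class:`EvaluationReport` from predictions and experiment."""
    means = robustly_mapped_means(samples, experimental)
    pred_flags, exp_flags = [], []
    pred_means, exp_means = [], []
    rdict = ranges.as_dict()
    for rid in experimental.reaction_ids:
        if rid not in rdict:
            continue
        pred_flags.append(classify_active(rdict[rid], threshold))
        exp_flags.append(classify_active(experimental.mean(rid), threshold))
        pred_means.append(means[rid])
        exp_means.append(experimental.mean(rid))
    confusion = confusion_metrics(pred_flags, exp_flags)
    overlap = range_overlap(ranges, experimental)
    pearson = log_flux_correlation(pred_means, exp_means, threshold=threshold)
    meandiff = mean_difference_test(samples, experimental, fdr_level=fdr_level)
    try:
        outliers = detect_outliers(pred_means, exp_means, threshold=threshold)
    except ValueError:
        outliers = None
    categories = None
    if pfba_ranges is not None:
        categories = categorize_range_sets(pfba_ranges, ranges)
    return EvaluationReport(experimental.strain_id, method, confusion, overlap,
                            pearson, meandiff, outliers, categories)


def robustly_mapped_means(samples, experimental, trim=0.0):
    """Per-reaction robust mean of the samples, keyed by reaction id."""
    from .optimize import robust_mean
    mu = robust_mean(samples, trim=trim)
    return {rid: float(mu[j]) for j, rid in enumerate(samples.reaction_ids)}
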