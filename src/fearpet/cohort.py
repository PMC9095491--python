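"""End-to-end cohort analysis.

Takes per-subject raw data (regional TACs, SCR trial tables, BOLD
contrasts), runs the nested two-step SRTM per subject and region, computes
the SCR learning delta, and assembles the subject-level result structure of
a fear-conditioning release study: directed baseline-vs-post binding tests
per region, directed Pearson correlations between amygdala/striatal release,
SCR learning and BOLD contrast, a bivariate Mahalanobis outlier screen for
every correlated pair, and the comparison of the two dependent release-SCR
correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scr import LearningIndex, process_scr_table
from .srtm import fit_post_challenge, fit_srtm_baseline, release_percent
from .stats import (CorrelationResult, RegionSummary, dependent_corr_compare,
                    mahalanobis_screen, paired_directed_test, pearson_directed)
from .synthetic import SubjectBundle

logger = logging.getLogger("fearpet")

__all__ = ["SubjectRecord", "CohortReport", "analyze_cohort", "report_render",
           "report_parse"]

#: correlation pairs examined, as (x, y) keys into SubjectRecord fields
CORRELATION_PAIRS = [
    ("release_amygdala", "scr_delta"),
    ("release_amygdala", "bold_amygdala"),
    ("release_striatum", "bold_striatum"),
    ("release_striatum", "scr_delta"),
    ("bold_amygdala", "scr_delta"),
]

TARGET_REGIONS = ("amygdala", "striatum", "frontal")


@dataclass
class SubjectRecord:
    """Fitted per-subject quantities entering the cohort statistics."""

    subject_id: str
    bp_base: dict
    bp_post: dict
    release: dict              # percent, = release_percent(bp_base, bp_post)
    scr: LearningIndex
    bold: dict
    flags: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def value(self, key: str) -> float:
        if key.startswith("release_"):
            return self.release[key.split("_", 1)[1]]
        if key.startswith("bold_"):
            return self.bold[key.split("_", 1)[1]]
        if key == "scr_delta":
            return self.scr.delta
        raise KeyError(key)


@dataclass
class CohortReport:
    """Cohort-level statistics in the structure the study reports."""

    n: int
    region_tests: dict               # region -> RegionSummary
    correlations: dict               # (x, y) -> CorrelationResult
    outlier_flags: dict              # (x, y) -> number of flagged subjects
    dependent_z: float               # amygdala vs striatal release against SCR
    dependent_p: float
    records: list = field(default_factory=list)
    skipped: list = field(default_factory=list)


def fit_subject(bundle: SubjectBundle, baseline_window=(0.0, 50.0),
                post_window=(70.0, 90.0)) -> SubjectRecord:
    """Run the nested fit on every target region of one subject."""
    ref = bundle.tacs["reference"]
    bp_base, bp_post, release, flags = {}, {}, {}, {}
    for region in TARGET_REGIONS:
        fit = fit_srtm_baseline(bundle.tacs[region], ref, bundle.frames,
                                window=baseline_window)
        nf = fit_post_challenge(bundle.tacs[region], ref, bundle.frames, fit,
                                window=post_window)
        bp_base[region] = fit.params.BP_ND
        bp_post[region] = nf.bp_post
        release[region] = (release_percent(fit.params.BP_ND, nf.bp_post)
                           if fit.params.BP_ND > 0 else np.nan)
        flags[region] = fit.flags + nf.flags
    _, idx = process_scr_table(bundle.scr, subject_id=bundle.subject_id)
    return SubjectRecord(subject_id=bundle.subject_id, bp_base=bp_base,
                         bp_post=bp_post, release=release, scr=idx,
                         bold=dict(bundle.bold), flags=flags,
                         truth=dict(bundle.truth))


def analyze_cohort(bundles: list[SubjectBundle],
                   baseline_window=(0.0, 50.0),
                   post_window=(70.0, 90.0)) -> CohortReport:
    """Full subject-level analysis of a cohort of raw data bundles.

    Subjects with incomplete records (missing regions, non-finite fits) are
    skipped with a logged reason; at least 4 complete subjects are required.
    """
    records, skipped = [], []
    for b in bundles:
        try:
            rec = fit_subject(b, baseline_window, post_window)
        except (ValueError, KeyError) as exc:
            logger.warning("subject %s skipped: %s", b.subject_id, exc)
            skipped.append((b.subject_id, str(exc)))
            continue
        needed = ([rec.bp_base[r] for r in TARGET_REGIONS]
                  + [rec.bp_post[r] for r in TARGET_REGIONS]
                  + [rec.release["amygdala"], rec.release["striatum"],
                     rec.scr.delta]
                  + [rec.bold.get(r, np.nan) for r in ("amygdala", "striatum")])
        if not np.all(np.isfinite(needed)):
            logger.warning("subject %s skipped: non-finite fitted values",
                           b.subject_id)
            skipped.append((b.subject_id, "non-finite fitted values"))
            continue
        records.append(rec)
    if len(records) < 4:
        raise ValueError("fewer than 4 complete subjects after skipping")

    region_tests = {}
    for region in TARGET_REGIONS:
        base = np.array([r.bp_base[region] for r in records])
        post = np.array([r.bp_post[region] for r in records])
        region_tests[region] = paired_directed_test(base, post,
                                                    direction="decrease")

    correlations, outlier_flags = {}, {}
    for x, y in CORRELATION_PAIRS:
        xv = np.array([r.value(x) for r in records])
        yv = np.array([r.value(y) for r in records])
        correlations[(x, y)] = pearson_directed(xv, yv, direction="positive")
        _, flagged, _ = mahalanobis_screen(np.column_stack([xv, yv]))
        outlier_flags[(x, y)] = int(flagged.sum())

    amy = np.array([r.release["amygdala"] for r in records])
    stri = np.array([r.release["striatum"] for r in records])
    scr = np.array([r.scr.delta for r in records])
    r12 = correlations[("release_amygdala", "scr_delta")].r
    r13 = correlations[("release_striatum", "scr_delta")].r
    r23 = float(np.corrcoef(amy, stri)[0, 1])
    if len(records) >= 10:
        z, p = dependent_corr_compare(r12, r13, r23, len(records))
    else:                      # Z test needs a minimally sized sample
        logger.warning("cohort too small for the dependent-correlation Z")
        z, p = np.nan, np.nan

    return CohortReport(n=len(records), region_tests=region_tests,
                        correlations=correlations,
                        outlier_flags=outlier_flags,
                        dependent_z=z, dependent_p=p,
                        records=records, skipped=skipped)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def report_to_frame(report: CohortReport) -> pd.DataFrame:
    """Flatten a CohortReport into a tidy machine-readable table."""
    rows = []
    for region, s in report.region_tests.items():
        rows.append(dict(kind="paired", name=region, statistic=s.t, df=s.df,
                         p_one_sided=s.p_one_sided,
                         estimate=s.mean_pct_change,
                         ci_low=s.ci_low, ci_high=s.ci_high, n_outliers=-1))
    for (x, y), c in report.correlations.items():
        rows.append(dict(kind="pearson", name=f"{x}~{y}", statistic=c.r,
                         df=c.n - 2, p_one_sided=c.p_one_sided, estimate=c.r,
                         ci_low=c.ci_low, ci_high=c.ci_high,
                         n_outliers=report.outlier_flags[(x, y)]))
    rows.append(dict(kind="steiger", name="release_amy_vs_str~scr",
                     statistic=report.dependent_z, df=report.n,
                     p_one_sided=report.dependent_p, estimate=report.dependent_z,
                     ci_low=np.nan, ci_high=np.nan, n_outliers=-1))
    return pd.DataFrame(rows)


def report_render(report: CohortReport) -> str:
    """Human-readable results block in the study's reporting style."""
    lines = [f"Cohort analysis (n = {report.n}"
             + (f", {len(report.skipped)} skipped)" if report.skipped else ")")]
    for region, s in report.region_tests.items():
        lines.append(
            f"  {region}: {s.mean_pct_change:.1f}% change "
            f"(95% CI: {s.ci_low:.1f} to {s.ci_high:.1f}%), "
            f"t({s.df}) = {s.t:.2f}, one-sided P = {s.p_one_sided:.4g}")
    for (x, y), c in report.correlations.items():
        nf = report.outlier_flags[(x, y)]
        lines.append(
            f"  {x} ~ {y}: r({c.n - 2}) = {c.r:.2f}, "
            f"one-sided P = {c.p_one_sided:.4g}, "
            f"95% CI: {c.ci_low:.2f} to {c.ci_high:.0f} "
            f"[{nf} outlier(s) flagged]")
    lines.append(f"  amygdala vs striatal release ~ SCR: "
                 f"Z = {report.dependent_z:.2f}, "
                 f"one-sided P = {report.dependent_p:.4g}")
    return "\n".join(lines)


def report_write_tsv(report: CohortReport, path) -> None:
    report_to_frame(report).to_csv(path, sep="\t", index=False)


def report_parse(path_or_buffer) -> pd.DataFrame:
    """Re-read a rendered TSV report (round-trips report_to_frame)."""
    return pd.read_csv(path_or_buffer, sep="\t")
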