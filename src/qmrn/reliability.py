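"""Reliability statistics: ICC, SEM, MDD, and Bland-Altman agreement.

Implements the classical single-measurement absolute-agreement intraclass
correlation from a two-way crossed ANOVA without replication:

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

where MSR, MSC and MSE are the between-target (row), between-rater (column)
and error mean squares of an n x k table. The point estimate is identical
under the two-way random-effects (raters sampled; the interreader design,
"ICC(2,1)") and two-way mixed-effects (raters fixed; the test-retest
design, "ICC(3,1)" with absolute agreement) readings; the model tag is
recorded for reporting. 95% confidence intervals use the exact F-based
method of McGraw & Wong with Satterthwaite degrees of freedom.

The standard error of measurement (SEM) follows the ANOVA decomposition:
the *agreement* flavour includes the rater variance component,
sqrt((MSC - MSE)/n + MSE); the *consistency* flavour is sqrt(MSE). The
minimum detectable difference is MDD = SEM * 1.96 * sqrt(2), with 1.96
treated as a literal constant at the 95% level. ICC point estimates are
classified as poor (< 0.5), moderate [0.5, 0.75), good [0.75, 0.9) and
excellent (>= 0.9); boundary values go to the upper category.

Bland-Altman analysis reports the bias (mean paired difference) and 95%
limits of agreement bias +/- 1.96 * SD(differences); the repeated-measures
mode corrects the SD for multiple difference pairs per subject via a
one-way ANOVA on the differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import norm

from .errors import DesignError, QmrnError
from .synthetic import BIOMARKERS

logger = logging.getLogger("qmrn.reliability")

MDD_Z_95 = 1.96          # literal constant of the 95% MDD formula
MDD_SQRT2 = math.sqrt(2.0)

ICC_CLASS_BOUNDS = ((0.9, "excellent"), (0.75, "good"), (0.5, "moderate"))


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------


@dataclass
class MeasurementTable:
    """Complete n x k table of one biomarker: targets x raters.

    For the interreader design, rows are subject x scan combinations and
    columns are readers; for the test-retest design, rows are subjects and
    columns are scans (one table per reader).
    """

    values: np.ndarray
    design: str = "interreader"
    biomarker: str = ""
    row_ids: list = field(default_factory=list)
    col_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("table must be 2-D (targets x raters)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise DesignError(f"need >= 2 rows and >= 2 columns, got {n}x{k}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                "table contains missing values; apply listwise deletion "
                "(build_tables) before the ANOVA")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class AnovaDecomposition:
    """Two-way crossed mean squares without replication."""

    ms_rows: float
    ms_cols: float
    ms_error: float
    df_rows: int
    df_cols: int
    df_error: int
    n: int
    k: int


@dataclass
class ReliabilityResult:
    """ICC with CI, SEM, MDD and qualitative class for one table."""

    icc: float
    ci_low: float
    ci_high: float
    model: str                      # "two-way-random-A1" | "two-way-mixed-A1"
    sem: float | None = None
    sem_flavor: str | None = None
    mdd: float | None = None
    icc_class: str | None = None
    biomarker: str = ""
    design: str = ""


@dataclass
class BlandAltmanResult:
    """Bias and 95% limits of agreement for paired measurements."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    differences: np.ndarray
    means: np.ndarray
    repeated: bool
    n_subjects: int | None = None


# --------------------------------------------------------------------------
# ANOVA and ICC
# --------------------------------------------------------------------------


def _as_matrix(table) -> np.ndarray:
    if isinstance(table, MeasurementTable):
        return table.values
    return MeasurementTable(np.asarray(table, dtype=float)).values


def anova_two_way(table) -> AnovaDecomposition:
    """Two-way crossed decomposition (targets x raters, one obs per cell).

    Sums of squares are computed in centred form for numerical stability:
    SS_error falls out as SS_total - SS_rows - SS_cols.
    """
    x = _as_matrix(table)
    n, k = x.shape
    grand = x.mean()
    xc = x - grand
    ss_rows = k * float(np.sum(xc.mean(axis=1) ** 2))
    ss_cols = n * float(np.sum(xc.mean(axis=0) ** 2))
    ss_total = float(np.sum(xc**2))
    ss_error = max(ss_total - ss_rows - ss_cols, 0.0)
    return AnovaDecomposition(
        ms_rows=ss_rows / (n - 1), ms_cols=ss_cols / (k - 1),
        ms_error=ss_error / ((n - 1) * (k - 1)),
        df_rows=n - 1, df_cols=k - 1, df_error=(n - 1) * (k - 1),
        n=n, k=k)


def icc_absolute_single(table, model: str = "random",
                        confidence: float = 0.95) -> ReliabilityResult:
    """Single-measurement absolute-agreement ICC with an F-based CI.

    ``model`` is "random" (two-way random effects; raters are a sample —
    the interreader reading) or "mixed" (raters fixed — the test-retest
    reading). The point estimate and interval are identical; the tag
    governs reporting only.
    """
    if model not in ("random", "mixed"):
        raise ValueError("model must be 'random' or 'mixed'")
    d = anova_two_way(table)
    n, k = d.n, d.k
    msr, msc, mse = d.ms_rows, d.ms_cols, d.ms_error
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise QmrnError("ICC undefined: non-positive denominator "
                        f"({denom:.4g}); the table may be constant")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    one_minus = n * (1.0 - icc)
    if abs(one_minus) < 1e-12 * max(1.0, abs(n)):
        ci_low = ci_high = icc          # degenerate: zero error variance
    else:
        a = k * icc / one_minus
        b = 1.0 + k * icc * (n - 1) / one_minus
        v_num = (a * msc + b * mse) ** 2
        v_den = ((a * msc) ** 2 / (k - 1)
                 + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        v = v_num / v_den if v_den > 0 else 1.0
        with np.errstate(all="ignore"):
            f_low = f_dist.ppf(1 - alpha / 2, n - 1, v)
            f_up = f_dist.ppf(1 - alpha / 2, v, n - 1)
            ci_low = (n * (msr - f_low * mse)
                      / (f_low * (k * msc + (k * n - k - n) * mse)
                         + n * msr))
            ci_high = (n * (f_up * msr - mse)
                       / (k * msc + (k * n - k - n) * mse + n * f_up * msr))
        # tiny Satterthwaite df drives the F quantiles to infinity
        # (strongly negative ICCs); use the analytic limits
        if not np.isfinite(f_low) or not np.isfinite(ci_low):
            ci_low = -n * mse / (k * msc + (k * n - k - n) * mse)
        if not np.isfinite(f_up) or not np.isfinite(ci_high):
            ci_high = 1.0
        ci_low = min(max(ci_low, -1.0), icc)
        ci_high = max(min(ci_high, 1.0), icc)
    tag = "two-way-random-A1" if model == "random" else "two-way-mixed-A1"
    if isinstance(table, MeasurementTable):
        bio, design = table.biomarker, table.design
    else:
        bio, design = "", ""
    return ReliabilityResult(icc=float(icc), ci_low=float(ci_low),
                             ci_high=float(ci_high), model=tag,
                             biomarker=bio, design=design)


def sem_from_anova(decomp: AnovaDecomposition, flavor: str = "agreement"
                   ) -> float:
    """Standard error of measurement from the ANOVA mean squares.

    ``agreement`` (default) includes the rater variance component,
    sqrt((MSC - MSE)/n + MSE); ``consistency`` is sqrt(MSE). A negative
    rater-variance estimate is truncated at zero with a warning.
    """
    if flavor == "consistency":
        return math.sqrt(decomp.ms_error)
    if flavor != "agreement":
        raise ValueError("flavor must be 'agreement' or 'consistency'")
    rater_var = (decomp.ms_cols - decomp.ms_error) / decomp.n
    if rater_var < 0:
        logger.warning("negative rater variance estimate (%.4g) truncated "
                       "at 0", rater_var)
        rater_var = 0.0
    return math.sqrt(rater_var + decomp.ms_error)


def mdd(sem: float, confidence: float = 0.95) -> float:
    """Minimum detectable difference, MDD = SEM * z * sqrt(2).

    At the default 95% level the critical value is the literal constant
    1.96 (so that published MDDs reproduce exactly from published SEMs);
    other confidence levels use the exact normal quantile.
    """
    if sem < 0:
        raise ValueError("sem must be >= 0")
    if abs(confidence - 0.95) < 1e-12:
        z = MDD_Z_95
    else:
        z = float(norm.ppf(0.5 + confidence / 2.0))
    return sem * z * MDD_SQRT2


def classify_icc(icc: float) -> str:
    """Qualitative agreement class; boundaries go to the upper category."""
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    for bound, label in ICC_CLASS_BOUNDS:
        if icc >= bound:
            return label
    return "poor"


def analyze_table(table: MeasurementTable, model: str = "random",
                  sem_flavor: str = "agreement",
                  confidence: float = 0.95) -> ReliabilityResult:
    """Full reliability summary (ICC + CI + SEM + MDD + class) of a table."""
    result = icc_absolute_single(table, model=model, confidence=confidence)
    decomp = anova_two_way(table)
    result.sem = sem_from_anova(decomp, flavor=sem_flavor)
    result.sem_flavor = sem_flavor
    result.mdd = mdd(result.sem)
    result.icc_class = classify_icc(result.icc)
    return result


# --------------------------------------------------------------------------
# Bland-Altman
# --------------------------------------------------------------------------


def bland_altman(a, b, subjects=None, repeated: bool = False,
                 z: float = 1.96) -> BlandAltmanResult:
    """Bias and limits of agreement for paired measurements a vs b.

    Simple mode: LoA = bias +/- z * SD of the differences. Repeated mode
    (``subjects`` groups difference pairs by subject): the SD is corrected
    for within-subject repetition by a one-way ANOVA on the differences —
    the variance of a single future difference is the between-subject
    variance component plus the within-subject mean square.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    d = a - b
    if d.size < 3:
        raise DesignError("need >= 3 difference values")
    bias = float(d.mean())
    means = (a + b) / 2.0
    n_subjects = None
    if repeated:
        if subjects is None:
            raise DesignError("repeated mode requires subject labels")
        subjects = np.asarray(subjects)
        if subjects.shape != d.shape:
            raise ValueError("subjects must align with the pairs")
        groups = pd.Series(d).groupby(pd.Series(subjects))
        sizes = groups.size().to_numpy(dtype=float)
        n_groups = sizes.size
        if n_groups < 2:
            raise DesignError("repeated mode needs >= 2 subjects")
        total = d.size
        if total == n_groups:
            raise DesignError(
                "repeated mode needs repeated differences per subject")
        group_means = groups.mean().to_numpy()
        msb = float(np.sum(sizes * (group_means - bias) ** 2) / (n_groups - 1))
        msw = float(sum(((g - g.mean()) ** 2).sum()
                        for _, g in groups) / (total - n_groups))
        m0 = (total - float(np.sum(sizes**2)) / total) / (n_groups - 1)
        var_between = max((msb - msw) / m0, 0.0)
        sd = math.sqrt(var_between + msw)
        n_subjects = int(n_groups)
    else:
        sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, sd_diff=sd,
                             loa_low=bias - z * sd, loa_high=bias + z * sd,
                             differences=d, means=means, repeated=repeated,
                             n_subjects=n_subjects)


# --------------------------------------------------------------------------
# Table construction from the biomarker measurement frame
# --------------------------------------------------------------------------


def build_tables(df: pd.DataFrame, biomarkers=None):
    """Build reliability tables and descriptives from a measurement frame.

    ``df`` holds one row per (subject, scan, reader) with one column per
    biomarker. Returns ``(tables, descriptives)`` where ``tables`` maps
    biomarker -> {"interreader": MeasurementTable,
    "test_retest": {reader: MeasurementTable}}. Rows with missing cells are
    dropped listwise per design, with a log message.
    """
    required = {"subject", "scan", "reader"}
    if not required <= set(df.columns):
        raise DesignError(f"measurement frame needs columns {required}")
    biomarkers = list(biomarkers) if biomarkers is not None else [
        c for c in BIOMARKERS if c in df.columns]
    readers = sorted(df["reader"].unique())
    scans = sorted(df["scan"].unique())
    if len(readers) < 2:
        raise DesignError("need >= 2 readers for the interreader design")
    if len(scans) < 2:
        raise DesignError("need >= 2 scans for the test-retest design")

    tables: dict[str, dict] = {}
    for bio in biomarkers:
        inter = df.pivot_table(index=["subject", "scan"], columns="reader",
                               values=bio, aggfunc="first")
        complete = inter.dropna()
        if len(complete) < len(inter):
            logger.info("%s interreader: dropped %d incomplete rows",
                        bio, len(inter) - len(complete))
        tables[bio] = {
            "interreader": MeasurementTable(
                complete.to_numpy(), design="interreader", biomarker=bio,
                row_ids=list(complete.index), col_ids=list(complete.columns)),
            "test_retest": {},
        }
        for r in readers:
            per = df[df["reader"] == r].pivot_table(
                index="subject", columns="scan", values=bio, aggfunc="first")
            complete_r = per.dropna()
            if len(complete_r) < len(per):
                logger.info("%s test-retest reader %s: dropped %d subjects",
                            bio, r, len(per) - len(complete_r))
            tables[bio]["test_retest"][r] = MeasurementTable(
                complete_r.to_numpy(), design="test-retest", biomarker=bio,
                row_ids=list(complete_r.index),
                col_ids=list(complete_r.columns))

    descriptives = (
        df.melt(id_vars=["subject", "scan", "reader"],
                value_vars=biomarkers, var_name="biomarker")
        .groupby(["biomarker", "scan", "reader"])["value"]
        .agg(["mean", "std", "count"]).reset_index())
    return tables, descriptives


def analyze_cohort(df: pd.DataFrame, sem_flavor: str = "agreement",
                   ba_mode: str = "repeated", biomarkers=None):
    """Run the full reliability suite over a measurement frame.

    Returns ``(reliability_df, ba_results, descriptives)``:

    * ``reliability_df`` — one row per biomarker x design (test-retest per
      reader) with ICC, CI, class, SEM, MDD;
    * ``ba_results`` — {(biomarker, design): BlandAltmanResult}; the
      interreader analysis pairs the two readers over subject x scan, the
      test-retest analysis pools all scan pairs over readers, both grouped
      by subject when ``ba_mode == "repeated"``;
    * ``descriptives`` — mean/SD/count per biomarker x scan x reader.
    """
    if ba_mode not in ("simple", "repeated"):
        raise ValueError("ba_mode must be 'simple' or 'repeated'")
    tables, descriptives = build_tables(df, biomarkers=biomarkers)
    rows = []
    ba_results: dict[tuple[str, str], BlandAltmanResult] = {}
    repeated = ba_mode == "repeated"
    for bio, designs in tables.items():
        inter = designs["interreader"]
        res = analyze_table(inter, model="random", sem_flavor=sem_flavor)
        rows.append({"biomarker": bio, "design": "interreader",
                     "reader": "all", "model": res.model, "icc": res.icc,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "icc_class": res.icc_class, "sem": res.sem,
                     "sem_flavor": sem_flavor, "mdd": res.mdd})
        # Bland-Altman between the two first readers over subject x scan
        subj = np.array([sid[0] for sid in inter.row_ids])
        ba_results[(bio, "interreader")] = bland_altman(
            inter.values[:, 0], inter.values[:, 1],
            subjects=subj if repeated else None, repeated=repeated)

        tr_a, tr_b, tr_subj = [], [], []
        for reader, table in designs["test_retest"].items():
            res = analyze_table(table, model="mixed", sem_flavor=sem_flavor)
            rows.append({"biomarker": bio, "design": "test-retest",
                         "reader": reader, "model": res.model,
                         "icc": res.icc, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "icc_class": res.icc_class,
                         "sem": res.sem, "sem_flavor": sem_flavor,
                         "mdd": res.mdd})
            k = table.k
            for i in range(k):
                for j in range(i + 1, k):
                    tr_a.append(table.values[:, i])
                    tr_b.append(table.values[:, j])
                    tr_subj.append(np.asarray(table.row_ids))
        ba_results[(bio, "test-retest")] = bland_altman(
            np.concatenate(tr_a), np.concatenate(tr_b),
            subjects=np.concatenate(tr_subj) if repeated else None,
            repeated=repeated)
    return pd.DataFrame(rows), ba_results, descriptives
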