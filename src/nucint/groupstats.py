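"""Group-comparison and relative-quantification statistics.

Small-sample workflow used throughout the quantitative assays: a
Shapiro–Wilk normality gate, pairwise Student's t-tests with the usual
significance bands (*** p < 0.0001, ** p < 0.001, * p < 0.05, n.s.),
mean ± s.d. summaries, qPCR relative expression by the comparative-Ct
(2^-ΔΔCt) method against a reference transcript (Rp49 by convention in the
fly), and ChIP-qPCR enrichment expressed as percent input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

BAND_THRESHOLDS = ((1e-4, "***"), (1e-3, "**"), (0.05, "*"))


@dataclass(frozen=True)
class GroupSample:
    """A labelled group of replicate measurements."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {self.label!r}: values must be finite")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class NormalityResult:
    statistic: float  # Shapiro-Wilk W
    p_value: float
    passed: bool
    degenerate: bool = False  # zero-variance sample, W undefined


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    df: float
    significance_band: str
    normality_pass: tuple[bool, bool] | None = None


def significance_band(p: float) -> str:
    """Map a p-value to the figure-legend band: ***/**/*/ns."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    for threshold, band in BAND_THRESHOLDS:
        if p < threshold:
            return band
    return "ns"


def normality_gate(group: GroupSample, alpha: float = 0.05) -> NormalityResult:
    """Shapiro–Wilk test; the gate passes when p >= alpha.

    Requires 3 <= n; a zero-variance sample has no defined W and is reported
    as a failed, degenerate result rather than an exception.
    """
    values = np.asarray(group.values, dtype=float)
    if len(values) < 3:
        raise ValueError(f"insufficient sample: Shapiro-Wilk needs n >= 3, got {len(values)}")
    if np.ptp(values) == 0:
        return NormalityResult(float("nan"), float("nan"), passed=False, degenerate=True)
    w, p = stats.shapiro(values)
    return NormalityResult(float(w), float(p), passed=bool(p >= alpha))


def pairwise_t_test(
    a: GroupSample,
    b: GroupSample,
    two_sided: bool = True,
    equal_var: bool = True,
    normality_alpha: float = 0.05,
) -> TestResult:
    """Student's t-test between two groups (classic pooled-variance form).

    Two-sided and equal-variance by default; Welch's correction available via
    ``equal_var=False``.  Each group is also run through the Shapiro–Wilk
    gate (where n allows) and the outcome reported alongside — the gate
    informs interpretation but does not change the test.
    """
    x, y = (np.asarray(g.values, dtype=float) for g in (a, b))
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t-test needs n >= 2 per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and equal_var:
        raise ValueError("zero pooled variance: t statistic undefined")
    alternative = "two-sided" if two_sided else "greater"
    res = stats.ttest_ind(x, y, equal_var=equal_var, alternative=alternative)
    df = float(res.df)
    normality = None
    if len(x) >= 3 and len(y) >= 3:
        normality = (normality_gate(a, normality_alpha).passed,
                     normality_gate(b, normality_alpha).passed)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="student_t" if equal_var else "welch_t",
        df=df,
        significance_band=significance_band(float(res.pvalue)),
        normality_pass=normality,
    )


def summarize(group: GroupSample) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation, as plotted mean ± s.d."""
    values = np.asarray(group.values, dtype=float)
    if len(values) < 2:
        raise ValueError("sd needs n >= 2")
    return float(values.mean()), float(values.std(ddof=1))


# ---------------------------------------------------------------------------
# qPCR relative expression (comparative Ct)
# ---------------------------------------------------------------------------

def relative_expression(
    ct_table: pd.DataFrame,
    control_sample: str,
    reference_gene: str | None = None,
) -> pd.DataFrame:
    """Relative expression per sample by the 2^-ΔΔCt method.

    ``ct_table`` is tidy with columns ``sample, gene, role, ct`` (role is
    ``target`` or ``reference``); technical repetitions (duplicate rows per
    sample and gene) are averaged on the Ct scale first.  For each sample,
    ΔCt = Ct_target − Ct_reference, and the fold change is
    2^−(ΔCt_sample − ΔCt_control); the control sample's fold is exactly 1.

    Returns a DataFrame ``sample, target_gene, fold_change``.  A sample
    without a reference Ct (or the named ``reference_gene``) is an error.
    """
    required = {"sample", "gene", "role", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"ct_table must have columns {sorted(required)}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle numbers")
    mean_ct = (ct_table.groupby(["sample", "gene", "role"], as_index=False)["ct"]
               .mean())

    refs = mean_ct[mean_ct["role"] == "reference"]
    if reference_gene is not None:
        refs = refs[refs["gene"] == reference_gene]
    ref_by_sample = refs.set_index("sample")["ct"]

    targets = mean_ct[mean_ct["role"] == "target"]
    rows = []
    for (sample, gene), sub in targets.groupby(["sample", "gene"]):
        if sample not in ref_by_sample.index:
            raise ValueError(f"missing reference Ct for sample {sample!r}")
        rows.append((sample, gene, float(sub["ct"].iloc[0]) - float(ref_by_sample[sample])))
    dct = pd.DataFrame(rows, columns=["sample", "target_gene", "delta_ct"])

    out = []
    for gene, sub in dct.groupby("target_gene"):
        control = sub[sub["sample"] == control_sample]
        if control.empty:
            raise ValueError(f"control sample {control_sample!r} missing for {gene!r}")
        ddct = sub["delta_ct"] - float(control["delta_ct"].iloc[0])
        out.append(pd.DataFrame({
            "sample": sub["sample"],
            "target_gene": gene,
            "fold_change": np.power(2.0, -ddct),
        }))
    return pd.concat(out, ignore_index=True)


def chip_enrichment(
    ip_quantity: float,
    input_quantity: float,
    input_fraction_saved: float = 0.05,
) -> float:
    """ChIP-qPCR recovery as percent of input chromatin.

    The input aliquot represents ``input_fraction_saved`` of the chromatin
    (5% by default), so percent input =
    ``100 * ip / (input / input_fraction_saved)``.
    """
    if ip_quantity < 0:
        raise ValueError("ip_quantity must be non-negative")
    if input_quantity <= 0:
        raise ValueError("input_quantity must be positive")
    if not 0 < input_fraction_saved <= 1:
        raise ValueError("input_fraction_saved must be in (0, 1]")
    return 100.0 * ip_quantity / (input_quantity / input_fraction_saved)
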