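"""Per-region statistics comparing native-space with template-space processing.

For every subject and brain area, the template-space value is subtracted
from the native-space value (sign convention: native minus template).
Each region's differences across subjects are then tested with a
one-sample t-test against zero, thresholded at an uncorrected alpha of
0.05 by default; the mean difference per region is reported alongside
for visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import t as t_dist

from .region_extraction import RegionMatrix
from .volumes import ValidationError


@dataclass
class ComparisonResult:
    """Per-region difference statistics (native minus template)."""

    region_labels: list[int]
    region_names: list[str]
    mean_difference: np.ndarray
    t_statistic: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    degenerate: np.ndarray
    alpha: float
    n_subjects: int
    n_per_region: np.ndarray

    def to_tsv(self, path=None) -> str:
        lines = [
            f"# alpha: {self.alpha:g}",
            f"# n_subjects: {self.n_subjects}",
            "label\tname\tmean_diff\tt\tp\tsignificant\tn",
        ]
        for i in range(len(self.region_labels)):
            lines.append(
                "\t".join(
                    [
                        str(self.region_labels[i]),
                        self.region_names[i],
                        format(self.mean_difference[i], ".12g"),
                        format(self.t_statistic[i], ".12g"),
                        format(self.p_value[i], ".12g"),
                        str(int(self.significant[i])),
                        str(int(self.n_per_region[i])),
                    ]
                )
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def region_differences(S_native: RegionMatrix, S_template: RegionMatrix) -> RegionMatrix:
    """Element-wise native minus template; missing propagates."""
    if S_native.region_labels != S_template.region_labels:
        raise ValidationError("matrices differ in region ordering")
    if S_native.subject_ids != S_template.subject_ids:
        raise ValidationError("matrices differ in subject ordering")
    return RegionMatrix(
        S_native.values - S_template.values,
        list(S_native.region_labels),
        list(S_native.region_names),
        list(S_native.subject_ids),
        f"diff({S_native.statistic})",
    )


def ttest_per_region(
    D: RegionMatrix, alpha: float = 0.05, correction: str = "none"
) -> ComparisonResult:
    """One-sample t-test of each region's differences against zero.

    Two-sided, with p from Student's t on n−1 degrees of freedom, where
    n counts the region's non-missing subjects.  No multiple-testing
    correction is applied by default (uncorrected thresholding);
    ``correction`` may be ``"bonferroni"`` or ``"fdr_bh"``.

    Zero-variance regions: all-zero differences get t=0, p=1; constant
    nonzero differences are flagged degenerate (p set to 0, with a
    warning).
    """
    vals = D.values
    finite = np.isfinite(vals)
    n = finite.sum(axis=1)
    low = np.flatnonzero(n < 2)
    if low.size:
        names = [f"{D.region_labels[i]} ({D.region_names[i]})" for i in low[:5]]
        raise ValidationError(
            f"region(s) with fewer than 2 non-missing subjects: {', '.join(names)}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(vals, axis=1)
        sd = np.nanstd(vals, axis=1, ddof=1)
    zero_var = sd == 0.0
    degenerate = zero_var & (mean != 0.0)
    t_stat = np.zeros(len(mean))
    ok = ~zero_var
    t_stat[ok] = mean[ok] / (sd[ok] / np.sqrt(n[ok]))
    t_stat[degenerate] = np.sign(mean[degenerate]) * np.inf
    p = np.ones(len(mean))
    p[ok] = 2.0 * t_dist.sf(np.abs(t_stat[ok]), n[ok] - 1)
    p[degenerate] = 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} region(s) have constant nonzero differences; "
            "their p-values are degenerate (set to 0)",
            stacklevel=2,
        )
    if correction == "bonferroni":
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, alpha=alpha, method="bonferroni")[1]
    elif correction == "fdr_bh":
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, alpha=alpha, method="fdr_bh")[1]
    elif correction != "none":
        raise ValidationError(f"unknown correction {correction!r}")
    return ComparisonResult(
        region_labels=list(D.region_labels),
        region_names=list(D.region_names),
        mean_difference=mean,
        t_statistic=t_stat,
        p_value=p,
        significant=p < alpha,
        degenerate=degenerate,
        alpha=alpha,
        n_subjects=D.N,
        n_per_region=n,
    )
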