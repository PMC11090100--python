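"""Cohort demographics bookkeeping: per-site sex and age comparisons.

Sex balance between groups is tested with the Pearson chi-square on the 2x2
group-by-sex table, one degree of freedom, without continuity correction.
Age is compared with Welch's two-sample t test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["chisq_2x2", "demographics_table", "qc_bookkeeping"]


def chisq_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]], 1 df, no
    continuity correction.

    Rows are groups, columns sexes (e.g. a = SCZ males, b = SCZ females,
    c = HC males, d = HC females).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("zero margin: chi-square undefined")
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1]
                                       * margins[2] * margins[3])
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def _group_row(label, sub: pd.DataFrame) -> dict:
    scz = sub[sub["group"] == "SCZ"]
    hc = sub[sub["group"] == "HC"]
    if len(scz) == 0 or len(hc) == 0:
        raise ValueError(f"site {label!r} lacks one of the groups")
    m_scz = int((scz["sex"] == "M").sum())
    f_scz = int((scz["sex"] == "F").sum())
    m_hc = int((hc["sex"] == "M").sum())
    f_hc = int((hc["sex"] == "F").sum())
    chi2, chi2_p = chisq_2x2(m_scz, f_scz, m_hc, f_hc)
    t, t_p = stats.ttest_ind(scz["age"], hc["age"], equal_var=False)
    return {
        "site": label,
        "n_scz": len(scz), "n_hc": len(hc),
        "age_mean_scz": float(scz["age"].mean()),
        "age_sd_scz": float(scz["age"].std(ddof=1)),
        "age_mean_hc": float(hc["age"].mean()),
        "age_sd_hc": float(hc["age"].std(ddof=1)),
        "m_scz": m_scz, "f_scz": f_scz, "m_hc": m_hc, "f_hc": f_hc,
        "sex_chi2": chi2, "sex_p": chi2_p,
        "age_t": float(t), "age_p": float(t_p),
    }


def demographics_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per site plus a Total row, with group sizes, age mean (SD),
    sex counts, the sex chi-square and the Welch age comparison."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rows = [_group_row(site, sub) for site, sub in cohort.groupby("site_id")]
    rows.append(_group_row("Total", cohort))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class QCCounts:
    """Enrollment minus quality-control exclusions."""

    enrolled_scz: int
    enrolled_hc: int
    excluded_scz: int
    excluded_hc: int

    @property
    def analyzed_scz(self) -> int:
        return self.enrolled_scz - self.excluded_scz

    @property
    def analyzed_hc(self) -> int:
        return self.enrolled_hc - self.excluded_hc

    @property
    def analyzed_total(self) -> int:
        return self.analyzed_scz + self.analyzed_hc


def qc_bookkeeping(enrolled_scz: int, enrolled_hc: int,
                   excluded_scz: int, excluded_hc: int) -> QCCounts:
    """Sanity-checked subject-count bookkeeping after QC exclusions."""
    if min(enrolled_scz, enrolled_hc, excluded_scz, excluded_hc) < 0:
        raise ValueError("counts must be non-negative")
    if excluded_scz > enrolled_scz or excluded_hc > enrolled_hc:
        raise ValueError("cannot exclude more subjects than enrolled")
    return QCCounts(enrolled_scz, enrolled_hc, excluded_scz, excluded_hc)
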