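import math

import pytest

from hbmeta.dose_assignment import DoseRule, assign_doses_table
from hbmeta.effect_math import rr_from_counts
from hbmeta.study_table import ExposureCategory, StudyRecord, table1_fixture


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def dosed_table1(table1):
    return assign_doses_table(table1, DoseRule())


def categories_from_counts(cases, totals, ref_idx=0, doses=None):
    """Build exposure categories whose RRs/CIs come from known counts."""
    cats = []
    for i, (a, n) in enumerate(zip(cases, totals)):
        dose = doses[i] if doses else None
        if i == ref_idx:
            cats.append(ExposureCategory(rr=1.0, is_reference=True,
                                         assigned_dose=dose, cases=a, total=n))
        else:
            est = rr_from_counts(a, n, cases[ref_idx], totals[ref_idx])
            lo, hi = est.ci()
            cats.append(ExposureCategory(rr=est.rr, ci_lower=lo, ci_upper=hi,
                                         assigned_dose=dose, cases=a, total=n))
    return cats


@pytest.fixture
def count_categories():
    return categories_from_counts([10, 20, 40], [100, 100, 100])
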