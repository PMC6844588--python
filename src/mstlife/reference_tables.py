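"""Published descriptive counts for the CLHLS 2002-2014 elderly cohort.

These integers are inputs transcribed from the published descriptive table
of the analytic cohort (region x sex strata, characteristics at entry) and
from its enrollment flow.  They serve as fixed reference inputs for
arithmetic recomputation — sample-size reconstruction and percentage-of-
nonmissing summaries — exercising the same rounding conventions as
:func:`mstlife.cohort.percentage_of_nonmissing`.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .cohort import percentage_of_nonmissing

#: Subjects aged 65-95 interviewed at each enrollment wave.
WAVE_ENROLLMENT: Dict[str, int] = {
    "2002": 11784,
    "2005": 5095,
    "2008": 5883,
    "2011": 917,
}
#: Exclusions: dropped out before first follow-up; incomplete baseline
#: disability assessment.
EXCLUDED_NO_FOLLOWUP: int = 3981
EXCLUDED_INCOMPLETE_BASELINE: int = 79

#: Stratum sizes (region, sex) -> N.
STRATUM_N: Dict[Tuple[str, str], int] = {
    ("urban", "male"): 3838,
    ("urban", "female"): 3918,
    ("rural", "male"): 5866,
    ("rural", "female"): 5997,
}

#: Disability state at entry (no / mild / severe) per stratum.
ENTRY_STATE_COUNTS: Dict[Tuple[str, str], Tuple[int, int, int]] = {
    ("urban", "male"): (2145, 1064, 629),
    ("urban", "female"): (1574, 1464, 880),
    ("rural", "male"): (3169, 2042, 655),
    ("rural", "female"): (2260, 2702, 1035),
}

#: Subjects reporting regular physical exercise at entry, per stratum.
EXERCISE_COUNTS: Dict[Tuple[str, str], int] = {
    ("urban", "male"): 2028,
    ("urban", "female"): 1490,
    ("rural", "male"): 1600,
    ("rural", "female"): 1124,
}


def analytic_sample_size() -> int:
    """Cohort size after the enrollment flow: all enrolled, minus subjects
    lost before first follow-up, minus incomplete baseline assessments."""
    return (
        sum(WAVE_ENROLLMENT.values())
        - EXCLUDED_NO_FOLLOWUP
        - EXCLUDED_INCOMPLETE_BASELINE
    )


def entry_state_percentages(region: str, sex: str) -> Tuple[float, float, float]:
    """Entry-state percentages of nonmissing for one stratum, 1-decimal."""
    counts = ENTRY_STATE_COUNTS[(region, sex)]
    return tuple(percentage_of_nonmissing(counts))


def exercise_percentage_by_region(region: str) -> float:
    """Regular-exercise percentage pooled over sexes within a region,
    1-decimal, full stratum denominators."""
    num = sum(v for (r, _), v in EXERCISE_COUNTS.items() if r == region)
    den = sum(v for (r, _), v in STRATUM_N.items() if r == region)
    return round(100.0 * num / den, 1)
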