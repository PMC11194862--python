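"""Controlled vocabularies and date-arithmetic constants shared across modules."""

from __future__ import annotations

# The six disease-modifying treatments eligible as index therapy.
DMT6 = (
    "dimethyl fumarate",
    "fingolimod",
    "glatiramer acetate",
    "interferon beta1",
    "natalizumab",
    "teriflunomide",
)

NODMT = "NoDMT"
OTHERDMT = "OtherDMT"

# DMTs counted as second-line exposure.
SECOND_LINE = frozenset(
    {
        "alemtuzumab",
        "cyclophosphamide",
        "fingolimod",
        "mitoxantrone",
        "natalizumab",
        "ocrelizumab",
        "rituximab",
    }
)

AGE_LEVELS = ("30 or younger", "31 to 40", "41 to 50", "51 or older")
SEX_LEVELS = ("F", "M")
EDSS_LEVELS = ("1.5 or less", "2 to 2.5", "3 to 3.5", "4 to 10")
RELAPSE_DISTANCE_LEVELS = ("less than 0.25", "0.25 to 0.99", "1 to 2.99", "3 or more")
DMT_COUNT_LEVELS = ("0", "1", "2", "3 or more")
CURRENT_THERAPY_LEVELS = DMT6 + (NODMT,)
INDEX_THERAPY_LEVELS = DMT6

#: categorical factor -> ordered level tuple
FACTOR_LEVELS = {
    "age_cat": AGE_LEVELS,
    "sex": SEX_LEVELS,
    "edss_cat": EDSS_LEVELS,
    "relapse_distance_cat": RELAPSE_DISTANCE_LEVELS,
    "dmt_count_cat": DMT_COUNT_LEVELS,
    "current_therapy": CURRENT_THERAPY_LEVELS,
    "index_therapy": INDEX_THERAPY_LEVELS,
}

#: predictors entering the design as plain numeric columns
CONTINUOUS_PREDICTORS = ("relapse_count_prev_year", "onset_distance", "current_duration")

# Internal unit is days; months/years are fixed-length conversions.
DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375
THREE_MONTHS_DAYS = 3 * DAYS_PER_MONTH  # 91.3125
TWELVE_MONTHS_DAYS = 12 * DAYS_PER_MONTH  # 365.25
SIX_MONTHS_DAYS = 6 * DAYS_PER_MONTH
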