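"""Reference tallies from the original Chinese giant salamander survey
campaign, used as fixed inputs for the package's consistency checks.

These are the printed field-survey counts: the per-arm tallies of counties
with and without sighting reports, the respondent totals, and the national
county totals behind the headline percentages. They are inputs, not outputs:
the package recomputes the derived statistics (chi-squared, percentages)
from them.
"""

from __future__ import annotations

# counties with >=1 sighting report vs none, by selection arm
# rows: historical-record arm (43 of 48), model-selected arm (40 of 47)
COUNTY_REPORT_TABLE = [[43, 5], [40, 7]]

N_RESPONDENTS = 2812
N_REPORTED = 1299          # respondents reporting a sighting
N_DATED = 1146             # respondents providing a last-sighting date

N_COUNTIES_TOTAL = 2852            # Chinese counties assessed
N_COUNTIES_WITH_RECORDS = 145      # counties with historical gazetteer records
N_COUNTIES_HIGH_SUITABILITY = 156  # counties with >=50% predicted suitable habitat

POWER_EFFECT = 0.10   # probability difference the survey design should detect
POWER_TARGET = 0.80   # claimed detection probability at that effect

# surveyed counties per province (95 counties across 15 provinces or
# equivalent administrative units); 48 counties form the historical-record
# arm and 47 the model-selected arm
SURVEY_PROVINCE_COUNTY_COUNTS = {
    "Anhui": 6, "Chongqing": 3, "Fujian": 1, "Gansu": 4, "Guangdong": 1,
    "Guangxi": 10, "Guizhou": 32, "Henan": 3, "Hubei": 4, "Hunan": 12,
    "Jiangxi": 2, "Shaanxi": 3, "Sichuan": 9, "Yunnan": 1, "Zhejiang": 4,
}
N_HISTORICAL_ARM = 48
N_MODEL_ARM = 47
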