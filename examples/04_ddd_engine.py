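"""Convert heterogeneous sales records into DDD consumption rates.

Sales arrive as standard units (single doses with a product strength) for
early years and kilograms later; both convert through the versioned
ATC/DDD registry into defined daily doses, aggregate to country-year
totals and divide out to DDD per 1000 population per day.
"""

import numpy as np
import pandas as pd

from abxgeo import ddd

registry = ddd.ATCRegistry.load("2019")
records = pd.DataFrame([
    # 2 million amoxicillin doses of 500 mg each, retail sector, 2010
    {"country": "A", "year": 2010, "atc": "J01CA04", "route": "oral",
     "sector": "retail", "unit": "SU", "quantity": 2_000_000, "mg_per_su": 500},
    # 150 kg of ceftriaxone, hospital sector, 2016
    {"country": "A", "year": 2010, "atc": "J01DD04", "route": "parenteral",
     "sector": "hospital", "unit": "kg", "quantity": 150, "mg_per_su": np.nan},
    # a non-antibiotic code that the J01 filter removes
    {"country": "A", "year": 2010, "atc": "A07AA09", "route": "oral",
     "sector": "retail", "unit": "kg", "quantity": 10, "mg_per_su": np.nan},
])

j01, dropped = ddd.filter_j01(records)
print(f"dropped {dropped} non-J01 record(s)")
totals = ddd.country_year_totals(j01, registry)
row = totals.iloc[0]
print(f"total DDD: {row['ddd_total']:,.0f} "
      f"(hospital {row['ddd_hospital']:,.0f}, retail {row['ddd_retail']:,.0f})")
# 2e6 SU x 500 mg = 1000 kg amoxicillin / 1.5 g per DDD = 666,667 DDD;
# 150 kg ceftriaxone / 2 g per DDD = 75,000 DDD
rate = ddd.rate(row["ddd_total"], population=1_000_000)
print(f"rate for 1M population: {rate:.2f} DDD per 1000 per day")

# the 2019 index raised several DDD values: the same mass gives fewer DDD
old = ddd.ATCRegistry.load("pre-2019")
print(f"1000 kg amoxicillin: {ddd.kg_to_ddd(1000, 'J01CA04', 'oral', registry):,.0f} DDD "
      f"(2019 index) vs {ddd.kg_to_ddd(1000, 'J01CA04', 'oral', old):,.0f} (pre-2019)")
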