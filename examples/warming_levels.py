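"""Pool 30-year periods that match prescribed global warming levels.

A synthetic GMST ramp is converted to anomalies against the 1850-1900
baseline; every 30-year window whose mean anomaly is within 0.1 degC of a
level contributes its years to that level's pool.
"""

import numpy as np
import pandas as pd

from climenv import GWLSpec, find_gwl_windows, gmst_anomaly
from climenv.gwl import pooled_years

years = np.arange(1850, 2101)
rng = np.random.default_rng(11)
gmst = pd.Series(13.8 + 0.016 * (years - 1850) + rng.normal(0, 0.08, years.size),
                 index=years)

anom = gmst_anomaly(gmst, baseline=(1850, 1900))
spec = GWLSpec()  # 1.2 (ref), 1.5, 2.0, 2.5, 3.0 degC; 30-yr windows
windows = find_gwl_windows(anom, spec)

for level in spec.levels:
    pool = sorted(pooled_years(windows[level]))
    if pool:
        print(f"GWL {spec.label(level):>9}: {len(pool):3d} pooled years "
              f"({pool[0]}-{pool[-1]}), {len(windows[level])} matching windows")
    else:
        print(f"GWL {spec.label(level):>9}: never reached in this run")
print("Higher levels pool later periods; overlapping windows are merged so "
      "each calendar year counts once per run.")
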