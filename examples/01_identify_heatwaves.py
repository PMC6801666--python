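"""Identify heatwave days in a daily temperature series with the EHF index.

Simulates two years of daily temperatures for two regions (seasonal cycle,
autocorrelated noise, a few injected summer heat episodes), fits the
climatological thresholds, and classifies every day as none / low / severe /
extreme.
"""

import numpy as np

import heatcross as hc

cfg = hc.SyntheticConfig(seed=11, study_start="2014-01-01", study_end="2015-12-31")
temps, episodes = hc.simulate_temperature(cfg, np.random.default_rng(cfg.seed))

clim = hc.fit_climatology(temps)
series = hc.classify_severity(hc.compute_ehf_series(temps, clim), clim)
calendar = hc.heatwave_calendar(series)

for region, c in clim.items():
    # t95: the 95th percentile of daily mean temperature; ehf85: the severe
    # threshold (85th percentile of positive EHF); extreme is 3x that.
    print(f"{region}: t95 = {c.t95:.1f} C, severe >= {c.ehf85:.1f} C^2, "
          f"extreme >= {c.extreme_threshold:.1f} C^2")

print("\nDays at each severity (exposure = severe or extreme):")
print(hc.severity_day_counts(calendar).to_string(index=False))

print(f"\n{len(episodes)} heat episodes were injected; the severe/extreme days "
      "above should fall inside or just after them.")
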