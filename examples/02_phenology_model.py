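"""Predict wheat heading dates with the phenology model.

Two genetic parameters drive development: the phyllochron P (thermal
time per leaf) and the photoperiod sensitivity SLDL (extra leaves per
hour of daylength below saturation).  Short winter days delay heading
in sensitive genotypes.
"""

import datetime as dt

import numpy as np

from cgmtap import PhenologyParams, WeatherSeries, predict_heading

# a constant-temperature toy environment: 20 deg C days, 12 h daylength
sow = dt.date(2012, 10, 20)
weather = WeatherSeries("toy", sow, np.full(300, 20.0), np.full(300, 12.0))

insensitive = PhenologyParams(P=100, SLDL=0.0)
day, doy = predict_heading(insensitive, weather)
print(f"insensitive genotype: heading {day} days after sowing (day-of-year {doy})")

sensitive = PhenologyParams(P=100, SLDL=1.0)
day_s, _ = predict_heading(sensitive, weather)
print(f"photoperiod-sensitive genotype: heading {day_s} days after sowing")
print(f"-> the 12 h days cost it {day_s - day} extra days "
      "(3 extra leaves at 100 degCd each)")

# realistic seasonal weather at 47 N
t = 11 + 8 * np.sin(2 * np.pi * (np.arange(320) - 120) / 365)
real = WeatherSeries("field", sow, t, latitude=47.0)
for p in (80, 100, 120):
    d, _ = predict_heading(PhenologyParams(p, 0.8), real)
    print(f"P = {p:3d} degCd/leaf -> heading day {d} (later with slower leafing)")
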