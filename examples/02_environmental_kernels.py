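"""Daily weather to environment kernels: reaction norm and envirotyping.

Simulates daily weather for the six trial sites, derives thermal-time
covariates from the crop's cardinal temperatures, builds the two feature
tables (RN window means; ET quantile-bin frequencies) and the environment
relationship matrices E used by the GxE models.
"""

import numpy as np

import gxeblup as gx

design = gx.default_design()
weather = gx.simulate_weather(design, seed=2)
weather = gx.derive_thermal_covariates(weather)   # cardinal temps 3.2/10/30/52 C

windows = gx.build_windows("TDM3", 2016)
print(f"seasonal-yield windows: {windows.n_windows} "
      f"({windows.start} .. {windows.end}; final short window kept)")

harvest_years = {c.name: design.years for c in design.countries}
covs = ["tmean", "tmin", "tmax", "precipitation", "radiation", "thermal_time"]

rn = gx.rn_features(weather, windows, harvest_years, covs)
print(f"RN features: {rn.shape[0]} environments x {rn.shape[1]} "
      "covariate-window means")

et = gx.et_features(weather, windows, harvest_years, ["tmean", "thermal_time"])
sums = et.to_numpy().reshape(len(et), -1, 5).sum(axis=2)
print(f"ET features: {et.shape[1]} bin frequencies; "
      f"max |sum - 1| per covariate-window = {np.abs(sums - 1).max():.2e}")

E_rn = gx.env_kernel(rn)
E_et = gx.env_kernel(et)
for name, E in (("RN", E_rn), ("ET", E_et)):
    E.validate()
    print(f"E ({name}): trace {np.trace(E.values):.3f} over {E.n} environments")

# same-country environments should be most alike: compare within- vs
# between-country mean kernel entries
labels = np.array([e.rsplit("-", 1)[0] for e in E_rn.labels])
same = (labels[:, None] == labels[None, :]) & ~np.eye(12, dtype=bool)
print(f"mean E_RN entry, same country {E_rn.values[same].mean():.3f} vs "
      f"different {E_rn.values[~same & ~np.eye(12, dtype=bool)].mean():.3f} "
      "(site climate persists across years)")
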