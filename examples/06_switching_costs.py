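"""How switching frictions shrink optimal reallocation.

Charges a per-acre cost on acreage moved beyond a crop's baseline area
and sweeps it upward: reallocated acres and the net objective fall
monotonically, and at prohibitive cost the allocation collapses onto the
status quo (with unprofitable acres left fallow).
"""

import numpy as np
import pandas as pd

from cropshift import allocation, hier, synth

crops = ("corn", "soybeans", "wheat")
cfg = synth.GeneratorConfig(crops=crops, mode="faithful")
data = synth.simulate(n_counties=30, n_years=18, seed=21, config=cfg)

draws = {}
for crop in crops:
    model = hier.build_model(data.panel_result.panel, data.covariates, hier.ModelSpec(crop=crop))
    draws[crop] = hier.fit(model, chains=2, warmup=250, draws=300, seed=4)

# calibrated posterior-mean profit surface at baseline climate
counties, crop_arr, (prices, costs, base) = allocation._econ_matrices(
    data.economics, ["price", "cost", "baseline_area"]
)
cov = data.covariates.set_index("county_id").loc[counties].reset_index()
clim = data.panel_result.climatology.set_index(["county_id", "crop"])
Y = np.empty((len(counties), len(crop_arr)))
for c, crop in enumerate(crop_arr):
    th = hier.predict_coefficients(draws[crop], cov, seed=0).theta.mean(axis=0)
    x = clim.loc[[(cid, crop) for cid in counties], ["t", "cdi", "gdd", "edd"]].to_numpy(float)
    Y[:, c] = np.exp(th[:, 0] + np.einsum("ij,ij->i", th[:, 1:], x))
ydf = pd.DataFrame({
    "county_id": np.repeat(counties, len(crop_arr)),
    "crop": np.tile(crop_arr, len(counties)),
    "yield": Y.reshape(-1),
})
econ_cal = allocation.calibrate_hidden_costs(data.economics, ydf)
_, _, (prices, costs, base) = allocation._econ_matrices(econ_cal, ["price", "cost", "baseline_area"])
surf = allocation.ProfitSurface(counties=counties, crops=crop_arr, yields=Y,
                                prices=prices, costs=costs)

sweep = allocation.sweep_switching_costs(surf, base, [0, 30, 60, 120, 180, 300, 600, 2000])
print(sweep.round(1).to_string(index=False))
r0 = sweep["reallocated_acres"].iloc[0]
half_cost = float(np.interp(-0.5 * r0, -sweep["reallocated_acres"], sweep["switching_cost"]))
print(f"\nswitching cost that halves reallocated acreage: ~${half_cost:.0f}/acre")
print("as the cost rises the optimizer keeps crops in place; in the limit the"
      " allocation equals the baseline pattern and gains from reallocation vanish")
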