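"""Generate a complete synthetic study: counties, yields, economics.

The generator draws county covariates, realizes county-level yield
sensitivities from the covariate-driven hierarchical model, simulates a
county x year x crop panel of log-yields, and builds an economics table
in which a designated "observed" crop leads each county.
"""

from cropshift import synth

cfg = synth.GeneratorConfig(crops=("corn", "soybeans", "wheat"), mode="faithful")
data = synth.simulate(n_counties=25, n_years=15, seed=42, config=cfg)

print("county covariates:")
print(data.covariates.head(3).round(2).to_string(index=False))
print("\nyield panel (standardized predictors):")
print(data.panel_result.panel.head(5).round(3).to_string(index=False))
print("\neconomics table:")
print(data.economics.head(6).round(2).to_string(index=False))

t = data.truth.crops["corn"]
print(f"\ntrue corn EDD effect at average covariates: {t.hyper.a[4]:+.3f} log-yield per SD")
print(f"between-county SD of the EDD effect:        {t.hyper.sigma_beta[3]:.3f}")
print("(one SD of extreme degree-days costs the average county "
      f"{-100 * t.hyper.a[4]:.0f}% of corn yield)")
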