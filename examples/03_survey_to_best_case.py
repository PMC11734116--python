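"""Turn a (synthetic) before/after abundance survey into a best-case beta.

Emulates the empirical route into the model: overdispersed core counts from
control and impacted sites, bootstrap resampling of the relative decrease in
abundance, and a method-of-moments beta fit.  The fitted distribution is what
an elicitation spec uses as its best case.
"""

import numpy as np

import seabed_era as se

spec = se.SurveySpec(
    n_cores_control=200, n_cores_impact=200,
    mean_density={"macroinfauna": 50.0, "meiofauna": 300.0},
    dispersion=5.0,
    true_decrease={"macroinfauna": 0.4, "meiofauna": 0.15},
    seed=1,
)
survey = se.simulate_survey(spec)
print(f"simulated {len(survey)} core counts "
      f"({spec.n_cores_control} control + {spec.n_cores_impact} impact per group)")

samples = se.decrease_samples(survey, n_boot=1000, seed=1)
for group, dec in samples.items():
    fit = se.fit_beta_moments(dec)
    truth = spec.true_decrease[group]
    print(f"{group}: fitted Beta({fit.alpha:.1f}, {fit.beta:.1f}), "
          f"mean decrease {fit.mean:.3f} (true {truth})")

# The bootstrap spread reflects core-to-core patchiness (negative-binomial
# dispersion); the fitted mean recovers the simulated decrease to within
# sampling error of the survey design.
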