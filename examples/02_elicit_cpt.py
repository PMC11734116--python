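"""Generate a full CPT from best/worst-case expert input.

Instead of eliciting one probability column per parent-state combination
(3 x 3 x 2 = 18 columns here), the expert supplies two beta distributions --
the response when every stressor is at its most favorable state (best case)
and at its least favorable state (worst case) -- plus a weight per stressor.
All other columns are interpolated.
"""

import numpy as np

import seabed_era as se

spec = se.ElicitationSpec(
    child="decrease_in_abundance",
    best=se.BetaSpec(1.0, 9.0),    # mean 0.10: little decrease
    worst=se.BetaSpec(9.0, 2.0),   # mean 0.82: severe decrease
    influences=(
        se.ParentInfluence("suspended_sediment", weight=0.5, scores=(0.0, 0.5, 1.0)),
        se.ParentInfluence("deposition", weight=0.4, scores=(0.0, 0.5, 1.0)),
        se.ParentInfluence("contaminants", weight=0.1, scores=(0.0, 1.0)),
    ),
)
cpt = se.build_cpt_from_elicitation(spec)
print(f"CPT: {cpt.table.shape[0]} columns over bins {spec.bins.labels}")

lam = se.relevance_index(spec, {"suspended_sediment": 1, "deposition": 2, "contaminants": 0})
print(f"relevance index for (moderate SSC, high deposition, no contaminants): {lam:.3f}")

interp = se.interpolate_beta(spec.best, spec.worst, lam)
print(f"interpolated response: Beta({interp.alpha:.2f}, {interp.beta:.2f}), "
      f"mean decrease {interp.mean:.2f}")

for label, row in (("best case ", 0), ("above mix ", 1 * 3 * 2 + 2 * 2 + 0),
                   ("worst case", cpt.table.shape[0] - 1)):
    probs = ", ".join(f"{p:.3f}" for p in cpt.table[row])
    print(f"{label} column: [{probs}]")

# The relevance index positions each parent configuration between the two
# elicited extremes; the binned beta gives the probability per decrease bin.
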