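"""Build a small discrete Bayesian network by hand and query it exactly.

A two-node chain: disturbance level (root) and habitat damage (child).
Shows the three core operations -- joint probability, marginal query, and
conditioning on evidence -- and cross-checks them against brute-force
enumeration of the joint table.
"""

import numpy as np

import seabed_era as se

net = se.Network(
    variables={
        "disturbance": se.Variable("disturbance", ("low", "high")),
        "damage": se.Variable("damage", ("minor", "severe")),
    },
    cpts={
        "disturbance": se.Cpt("disturbance", (), np.array([[0.7, 0.3]])),
        "damage": se.Cpt("damage", ("disturbance",),
                         np.array([[0.9, 0.1],      # low disturbance
                                   [0.2, 0.8]])),   # high disturbance
    },
)
assert se.validate_network(net) == []

p_joint = se.joint_probability(net, {"disturbance": "high", "damage": "severe"})
print(f"P(high disturbance AND severe damage) = {p_joint:.3f}")

marginal = se.query(net, ["damage"], {})["damage"]
print(f"P(damage) = minor {marginal[0]:.3f} / severe {marginal[1]:.3f}")

posterior = se.query(net, ["disturbance"], {"damage": "severe"})["disturbance"]
print(f"P(disturbance | severe damage) = low {posterior[0]:.3f} / high {posterior[1]:.3f}")

joint = se.enumerate_joint(net, order=["disturbance", "damage"])
print(f"enumeration cross-check: P(severe) = {joint.marginal('damage')[1]:.3f}")

# The marginal mixes the two CPT rows by the prior; observing severe damage
# raises the probability that disturbance was high from 0.30 to ~0.77.
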