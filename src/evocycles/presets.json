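{
  "fig2a": {
    "variant": "seasonal",
    "epi": {"a0": 10.0, "q0": 0.5, "b": 1.0, "alpha": 1.0, "gamma": 1.0, "beta": 0.2, "amp": 0.5},
    "tradeoff": null,
    "trait_range": [0.05, 0.5],
    "sweep": null,
    "note": "Seasonally varying competition, resident dynamics only (a = 10, beta = 0.2)."
  },
  "fig2b": {
    "variant": "seasonal",
    "epi": {"a0": 10.0, "q0": 0.5, "b": 1.0, "alpha": 1.0, "gamma": 1.0, "beta": 0.2, "amp": 0.5},
    "tradeoff": {"a_ref": 10.0, "beta_ref": 0.2, "tau1": 1.58, "tau2": -3.0},
    "trait_range": [0.05, 0.5],
    "sweep": null,
    "note": "Seasonal competition with decelerating trade-off curvature (tau2 = -3): CSS."
  },
  "fig2c": {
    "variant": "seasonal",
    "epi": {"a0": 10.0, "q0": 0.5, "b": 1.0, "alpha": 1.0, "gamma": 1.0, "beta": 0.2, "amp": 0.5},
    "tradeoff": {"a_ref": 10.0, "beta_ref": 0.2, "tau1": 1.58, "tau2": 3.0},
    "trait_range": [0.05, 0.5],
    "sweep": null,
    "note": "Seasonal competition with accelerating trade-off curvature (tau2 = +3): branching point."
  },
  "fig3a": {
    "variant": "seasonal",
    "epi": {"a0": 10.0, "q0": 0.5, "b": 1.0, "alpha": 1.0, "gamma": 1.0, "beta": 0.2, "amp": 0.5},
    "tradeoff": {"a_ref": 10.0, "beta_ref": 0.2, "tau1": 1.58, "tau2": -3.0},
    "trait_range": [0.05, 0.5],
    "sweep": {"parameter": "amp", "values": [0.0, 0.3, 0.6, 0.9]},
    "note": "CSS location vs forcing amplitude; compare q0 = 0.1 against q0 = 0.5."
  },
  "fig3b": {
    "variant": "seasonal",
    "epi": {"a0": 10.0, "q0": 0.5, "b": 1.0, "alpha": 1.0, "gamma": 1.0, "beta": 0.2, "amp": 0.5},
    "tradeoff": {"a_ref": 10.0, "beta_ref": 0.2, "tau1": 1.58, "tau2": -3.0},
    "trait_range": [0.05, 0.5],
    "sweep": {"parameter": "alpha", "values": [0.5, 1.0, 1.5, 2.0]},
    "note": "CSS location vs virulence at several recovery rates."
  },
  "fig4": {
    "variant": "free_living",
    "epi": {"a0": 10.0, "q0": 0.1, "b": 1.0, "alpha": 1.0, "gamma": 0.1, "beta": 0.1, "amp": 0.0, "theta": 5.0, "decay": 0.1},
    "tradeoff": {"a_ref": 10.0, "beta_ref": 0.1, "tau1": 75.0, "tau2": -400.0},
    "trait_range": [0.02, 0.2],
    "sweep": null,
    "note": "Free-living parasite stages: intrinsic limit cycle of period ~10.13 at beta = 0.1."
  },
  "fig5a": {
    "variant": "free_living",
    "epi": {"a0": 10.0, "q0": 0.1, "b": 1.0, "alpha": 1.0, "gamma": 0.1, "beta": 0.1, "amp": 0.0, "theta": 5.0, "decay": 0.1},
    "tradeoff": {"a_ref": 10.0, "beta_ref": 0.1, "tau1": 75.0, "tau2": -400.0},
    "trait_range": [0.02, 0.2],
    "sweep": {"parameter": "q0", "values": [0.1, 0.2, 0.3, 0.4, 0.5]},
    "note": "CSS location vs competition, spanning the cycle/equilibrium boundary."
  },
  "fig5b": {
    "variant": "free_living",
    "epi": {"a0": 10.0, "q0": 0.1, "b": 1.0, "alpha": 1.0, "gamma": 0.1, "beta": 0.1, "amp": 0.0, "theta": 5.0, "decay": 0.1},
    "tradeoff": {"a_ref": 10.0, "beta_ref": 0.1, "tau1": 75.0, "tau2": -400.0},
    "trait_range": [0.02, 0.2],
    "sweep": {"parameter": "theta", "values": [1.0, 2.0, 3.0, 4.0, 5.0]},
    "note": "CSS location vs propagule production, spanning the equilibrium/cycle boundary."
  }
}
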