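{
  "mayo": {
    "name": "mayo",
    "source": "Swensen SJ et al. The probability of malignancy in solitary pulmonary nodules. Arch Intern Med 1997;157(8):849-855.",
    "link": "logistic",
    "intercept": -6.8272,
    "terms": [
      {"field": "age", "coef": 0.0391, "transform": {"type": "identity"}},
      {"field": "smoker", "coef": 0.7917, "transform": {"type": "identity"}},
      {"field": "previous_extrathoracic_cancer", "coef": 1.3388, "transform": {"type": "identity"}},
      {"field": "nodule_size", "coef": 0.1274, "transform": {"type": "identity"}},
      {"field": "spiculation", "coef": 1.0407, "transform": {"type": "identity"}},
      {"field": "upper_lobe", "coef": 0.7838, "transform": {"type": "identity"}}
    ]
  },
  "brock": {
    "name": "brock",
    "source": "McWilliams A et al. Probability of cancer in pulmonary nodules detected on first screening CT. N Engl J Med 2013;369(10):910-919. Full model (2b) with spiculation.",
    "link": "logistic",
    "intercept": -6.7892,
    "terms": [
      {"field": "age", "coef": 0.0287, "transform": {"type": "center", "value": 62.0}},
      {"field": "sex", "coef": 0.6011, "transform": {"type": "identity"}, "note": "sex = 1 for female"},
      {"field": "family_history", "coef": 0.2961, "transform": {"type": "identity"}},
      {"field": "emphysema", "coef": 0.2953, "transform": {"type": "identity"}},
      {"field": "nodule_size", "coef": -5.3854, "transform": {"type": "inverse_sqrt_cm_centered", "value": 1.58113883}},
      {"field": "nodule_count", "coef": -0.0824, "transform": {"type": "center", "value": 4.0}},
      {"field": "upper_lobe", "coef": 0.6581, "transform": {"type": "identity"}},
      {"field": "spiculation", "coef": 0.7729, "transform": {"type": "identity"}},
      {"field": "nodule_type", "coef": 0.377, "transform": {"type": "equals", "value": "part-solid"}},
      {"field": "nodule_type", "coef": -0.1276, "transform": {"type": "equals", "value": "non-solid"}}
    ]
  }
}
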