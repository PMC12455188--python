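# Published decision rules for the three-step sow-interaction method.
#
# Each rule set is a first-match decision list: branches are evaluated
# in order, every branch is a conjunction of threshold conditions, and
# a feature vector that satisfies no branch receives the default label.
# Comparators are exactly as printed ("strict as printed"): a value
# equal to a threshold fails a strict comparison and falls through.
#
# Distances and distance evolutions in meters; speeds in m/s; posture
# proportions as fractions of images.
version: 1
rule_sets:
  - step: presence
    period: before
    default: no_interaction
    branches:
      - label: interaction
        when:
          - {feature: d_evolution_nose1_nose2, op: "<", value: -0.2}
      - label: interaction
        when:
          - {feature: avg_d_nose1_nose2, op: "<", value: 0.87}
          - {feature: prop_any_standing, op: ">", value: 0.5}
      - label: interaction
        when:
          - {feature: avg_d_nose1_nose2, op: ">=", value: 0.87}
          - {feature: d_evolution_nose2_tail1, op: "<", value: -0.3}

  - step: presence
    period: after
    default: no_interaction
    branches:
      - label: interaction
        when:
          - {feature: d_evolution_nose1_nose2, op: ">", value: 0.13}
          - {feature: avg_d_nose1_nose2, op: "<", value: 2.5}
      - label: interaction
        when:
          - {feature: d_evolution_nose1_nose2, op: ">", value: 1.1}

  - step: valence
    period: before
    default: positive
    branches:
      - label: negative
        when:
          - {feature: speed_nose1_nose2, op: "<", value: 0.22}
          - {feature: prop_both_lying, op: "<", value: 0.5}
      - label: negative
        when:
          - {feature: speed_nose1_nose2, op: ">=", value: 0.22}
          - {feature: d_travelled_sow2, op: ">", value: 1.1}

  - step: valence
    period: during
    default: positive
    branches:
      - label: negative
        when:
          - {feature: d_travelled_sow1, op: ">", value: 0.47}
      - label: negative
        when:
          - {feature: speed_nose1_tail2, op: ">", value: 0.069}
      - label: negative
        when:
          - {feature: speed_nose1_nose2, op: ">", value: 0.3}

  - step: valence
    period: after
    default: positive
    branches:
      - label: negative
        when:
          - {feature: speed_nose1_nose2, op: ">", value: 0.42}
          - {feature: d_travelled_sow2, op: ">", value: 0.1}
      - label: negative
        when:
          - {feature: speed_nose1_nose2, op: "<", value: 0.011}
          - {feature: d_travelled_sow2, op: ">", value: 0.4}
      - label: negative
        when:
          - {feature: speed_nose1_nose2, op: ">=", value: 0.011}
          - {feature: speed_nose1_nose2, op: "<=", value: 0.42}
          - {feature: d_travelled_sow2, op: ">", value: 1.3}

  - step: orientation
    period: before
    default: nose_tail
    branches:
      - label: nose_nose
        when:
          - {feature: avg_d_nose1_nose2, op: "<", value: 1.9}
          - {feature: d_evolution_nose1_nose2, op: "<", value: -0.034}
      - label: nose_neck
        when:
          - {feature: avg_d_nose1_nose2, op: "<", value: 1.9}
          - {feature: avg_d_nose2_tail1, op: ">", value: 1.8}
      - label: nose_tail
        when:
          - {feature: avg_d_nose1_nose2, op: "<", value: 1.9}
      - label: nose_neck
        when:
          - {feature: avg_d_nose1_nose2, op: "<=", value: 2.2}
      # default: AvgD_nose1_nose2 above 2.2 m -> nose_tail

  - step: orientation
    period: during
    default: nose_tail
    branches:
      - label: nose_nose
        when:
          - {feature: avg_d_nose1_nose2, op: "<", value: 0.75}
      - label: nose_neck
        when:
          - {feature: avg_d_nose1_nose2, op: "<=", value: 1.7}
      # default: above 1.7 m -> nose_tail (disambiguated partition)

  - step: orientation
    period: after
    default: nose_tail
    branches:
      - label: nose_tail
        when:
          - {feature: avg_d_nose1_nose2, op: "<", value: 1.8}
          - {feature: avg_d_nose2_tail1, op: "<=", value: 1.3}
      - label: nose_nose
        when:
          - {feature: avg_d_nose1_nose2, op: "<", value: 1.8}
          - {feature: avg_d_nose1_tail2, op: ">", value: 2.4}
          - {feature: avg_d_nose2_tail1, op: ">", value: 1.3}
      - label: nose_neck
        when:
          - {feature: avg_d_nose1_nose2, op: "<", value: 1.8}
          - {feature: avg_d_nose1_tail2, op: "<=", value: 2.4}
          - {feature: avg_d_nose2_tail1, op: ">", value: 1.3}
      - label: nose_tail
        when:
          - {feature: avg_d_nose1_nose2, op: "<", value: 1.8}
          - {feature: d_evolution_nose1_nose2, op: "<=", value: 0.77}
          - {feature: d_evolution_nose2_tail1, op: ">", value: 0.11}
      - label: nose_nose
        when:
          - {feature: avg_d_nose1_nose2, op: ">=", value: 1.8}
          - {feature: avg_d_nose1_nose2, op: "<=", value: 3.2}
          - {feature: d_evolution_nose1_nose2, op: ">", value: 0.77}
      - label: nose_neck
        when:
          - {feature: avg_d_nose1_nose2, op: ">", value: 3.2}
          - {feature: d_evolution_nose1_nose2, op: ">", value: 0.77}
      - label: nose_neck
        when:
          - {feature: avg_d_nose1_nose2, op: ">", value: 1.8}
          - {feature: d_evolution_nose1_nose2, op: "<=", value: 0.77}
          - {feature: d_evolution_nose2_tail1, op: "<=", value: 0.11}
      # remaining region (far apart, little nose-nose divergence,
      # growing nose2-tail1 distance) -> nose_tail by symmetry with
      # the close-range subtree
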