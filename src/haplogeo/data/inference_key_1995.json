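{
  "name": "nested-clade-inference-key-1995",
  "description": "Decision table for interpreting nested clade Dc/Dn significance patterns, encoded with computable predicates. Questions about sampling adequacy are answered affirmatively; geographic-overlap questions are operationalized as shared-population checks and 'deep divergence' as inter-clade mutational steps exceeding twice the within-clade mean.",
  "start": "1",
  "steps": {
    "1": {
      "question": "Are there any significant Dc, Dn, interior-tip or contingency values within the nested clade?",
      "predicate": "any_significant",
      "yes": "2",
      "no": "conclusion:inconclusive"
    },
    "2": {
      "question": "Are tip-clade Dc values significantly small, or interior-clade Dc values significantly large?",
      "predicate": "tip_dc_small_or_interior_dc_large",
      "yes": "3",
      "no": "11",
      "na_predicate": "no_tip_interior_distinction",
      "na": "conclusion:inconclusive"
    },
    "3": {
      "question": "Are tip Dn values significantly large, interior Dn values significantly small, or the interior-tip Dn contrast significantly small (restricted clades displaced from the nesting center)?",
      "predicate": "dn_displacement",
      "yes": "4",
      "no": "5"
    },
    "4": {
      "question": "Does some member clade occupy populations fully disjoint from the other member clades?",
      "predicate": "some_member_disjoint",
      "yes": "9",
      "no": "conclusion:restricted gene flow with isolation by distance"
    },
    "5": {
      "question": "Does some member clade occupy populations fully disjoint from the other member clades?",
      "predicate": "some_member_disjoint",
      "yes": "15",
      "no": "conclusion:restricted gene flow with isolation by distance"
    },
    "9": {
      "question": "Are all member clades mutually disjoint in their population ranges?",
      "predicate": "all_members_disjoint",
      "yes": "conclusion:past fragmentation",
      "no": "conclusion:restricted gene flow with some long-distance dispersal"
    },
    "11": {
      "question": "Are interior-clade Dc values significantly small, or tip-clade Dc values significantly large (range-expansion reversal)?",
      "predicate": "interior_dc_small_or_tip_dc_large",
      "yes": "12",
      "no": "conclusion:inconclusive"
    },
    "12": {
      "question": "Are the tip clades disjoint from the interior clades' populations?",
      "predicate": "tips_disjoint_from_interiors",
      "yes": "conclusion:long-distance colonization",
      "no": "conclusion:contiguous range expansion"
    },
    "15": {
      "question": "Is the divergence between member clades deep (mean mutational steps between clades more than twice the within-clade mean)?",
      "predicate": "deep_divergence",
      "yes": "conclusion:past fragmentation",
      "no": "conclusion:long-distance colonization"
    }
  }
}
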