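{
  "comment": "ACMG/AMP 2015 evidence-combining rules over counts of evidence items by strength. A rule fires when, for every strength listed, the count of evidence items at that strength (in the rule's direction) is >= the stated minimum. Rules are evaluated top to bottom within each verdict block; pathogenic blocks before likely_pathogenic, benign before likely_benign. A simultaneous pathogenic-direction and benign-direction match yields uncertain_significance (conflict).",
  "pathogenic": [
    {"id": "P-i-a", "desc": "1 very strong + >=1 strong", "min_counts": {"very_strong": 1, "strong": 1}},
    {"id": "P-i-b", "desc": "1 very strong + >=2 moderate", "min_counts": {"very_strong": 1, "moderate": 2}},
    {"id": "P-i-c", "desc": "1 very strong + 1 moderate + 1 supporting", "min_counts": {"very_strong": 1, "moderate": 1, "supporting": 1}},
    {"id": "P-i-d", "desc": "1 very strong + >=2 supporting", "min_counts": {"very_strong": 1, "supporting": 2}},
    {"id": "P-ii", "desc": ">=2 strong", "min_counts": {"strong": 2}},
    {"id": "P-iii-a", "desc": "1 strong + >=3 moderate", "min_counts": {"strong": 1, "moderate": 3}},
    {"id": "P-iii-b", "desc": "1 strong + 2 moderate + >=2 supporting", "min_counts": {"strong": 1, "moderate": 2, "supporting": 2}},
    {"id": "P-iii-c", "desc": "1 strong + 1 moderate + >=4 supporting", "min_counts": {"strong": 1, "moderate": 1, "supporting": 4}}
  ],
  "likely_pathogenic": [
    {"id": "LP-i", "desc": "1 very strong + 1 moderate", "min_counts": {"very_strong": 1, "moderate": 1}},
    {"id": "LP-ii", "desc": "1 strong + 1-2 moderate", "min_counts": {"strong": 1, "moderate": 1}},
    {"id": "LP-iii", "desc": "1 strong + >=2 supporting", "min_counts": {"strong": 1, "supporting": 2}},
    {"id": "LP-iv", "desc": ">=3 moderate", "min_counts": {"moderate": 3}},
    {"id": "LP-v", "desc": "2 moderate + >=2 supporting", "min_counts": {"moderate": 2, "supporting": 2}},
    {"id": "LP-vi", "desc": "1 moderate + >=4 supporting", "min_counts": {"moderate": 1, "supporting": 4}}
  ],
  "benign": [
    {"id": "B-i", "desc": "1 stand-alone (BA1)", "min_counts": {"stand_alone": 1}},
    {"id": "B-ii", "desc": ">=2 strong benign", "min_counts": {"strong": 2}}
  ],
  "likely_benign": [
    {"id": "LB-i", "desc": "1 strong + 1 supporting", "min_counts": {"strong": 1, "supporting": 1}},
    {"id": "LB-ii", "desc": ">=2 supporting", "min_counts": {"supporting": 2}}
  ]
}
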