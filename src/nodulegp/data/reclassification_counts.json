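{
  "description": "Published 3x3 risk-group migration counts for a 450-subject NLST screening test cohort (53 biopsy-proven lung cancers, 397 negatives). Rows: initial risk group (low/medium/high) assigned from real nodule images by the named rule; columns: new risk group assigned by a lung-cancer risk prediction model reading GP-nodules (follow-up nodule images predicted from the baseline scan). Counts are split by outcome (event = cancer).",
  "n_event": 53,
  "n_nonevent": 397,
  "blocks": {
    "lung_rads": {
      "initial_rule": "Lung-RADS category at baseline (<3 low, =3 medium, >3 high)",
      "event": [[2, 5, 5], [0, 11, 4], [1, 5, 20]],
      "nonevent": [[89, 46, 9], [67, 67, 2], [8, 76, 33]]
    },
    "brock": {
      "initial_rule": "Brock model score at baseline (<0.0117 low, [0.0117, 0.10] medium, >0.10 high)",
      "event": [[1, 4, 0], [2, 14, 11], [0, 3, 18]],
      "nonevent": [[105, 57, 0], [54, 110, 19], [5, 22, 25]]
    },
    "lcrp_baseline": {
      "initial_rule": "risk model score on real baseline nodules (<0.45 low, [0.45, 0.81] medium, >0.81 high)",
      "event": [[3, 2, 0], [0, 19, 10], [0, 0, 19]],
      "nonevent": [[136, 22, 0], [28, 165, 20], [0, 2, 24]]
    },
    "lcrp_followup": {
      "initial_rule": "risk model score on real 1-year follow-up nodules (<0.45 low, [0.45, 0.81] medium, >0.81 high)",
      "event": [[2, 1, 0], [1, 14, 8], [0, 6, 21]],
      "nonevent": [[123, 32, 0], [41, 149, 18], [0, 8, 26]]
    }
  }
}
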