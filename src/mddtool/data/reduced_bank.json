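{
  "bank_id": "dsm5-mdd-reduced",
  "version": "1.0",
  "entry": "a1",
  "questions": [
    {
      "id": "a1",
      "text": "Over the last two weeks, have you felt sad, down or depressed most of the day, nearly every day?",
      "criterion": "A1",
      "response_kind": "binary",
      "branch_rules": {"yes": "a2", "no": "a2"}
    },
    {
      "id": "a2",
      "text": "Over the same period, have you lost interest or pleasure in almost all of your usual activities?",
      "criterion": "A2",
      "response_kind": "binary",
      "branch_rules": {"yes": "a3", "no": "a3"}
    },
    {
      "id": "a3",
      "text": "Has your appetite or weight changed noticeably (decrease or increase) without trying?",
      "criterion": "A3",
      "response_kind": "binary",
      "branch_rules": {"yes": "a4", "no": "a4"}
    },
    {
      "id": "a4",
      "text": "Have you had trouble sleeping, or been sleeping much more than usual, nearly every day?",
      "criterion": "A4",
      "response_kind": "binary",
      "branch_rules": {"yes": "a5", "no": "a5"}
    },
    {
      "id": "a5",
      "text": "Have you been moving or speaking so slowly, or been so restless, that other people could have noticed?",
      "criterion": "A5",
      "response_kind": "binary",
      "branch_rules": {"yes": "a6", "no": "a6"}
    },
    {
      "id": "a6",
      "text": "Have you felt tired or without energy nearly every day?",
      "criterion": "A6",
      "response_kind": "binary",
      "branch_rules": {"yes": "a7", "no": "a7"}
    },
    {
      "id": "a7",
      "text": "Have you felt worthless, or excessively or inappropriately guilty, nearly every day?",
      "criterion": "A7",
      "response_kind": "binary",
      "branch_rules": {"yes": "a8", "no": "a8"}
    },
    {
      "id": "a8",
      "text": "Have you had trouble thinking, concentrating or making decisions nearly every day?",
      "criterion": "A8",
      "response_kind": "binary",
      "branch_rules": {"yes": "a9", "no": "a9"}
    },
    {
      "id": "a9",
      "text": "Have you had recurrent thoughts of death, or thoughts of harming yourself?",
      "criterion": "A9",
      "response_kind": "binary",
      "branch_rules": {"yes": "dur", "no": "dur"}
    },
    {
      "id": "dur",
      "text": "Have these difficulties been present together during the same two-week period?",
      "criterion": "DUR",
      "response_kind": "binary",
      "branch_rules": {"yes": "imp", "no": "imp"}
    },
    {
      "id": "imp",
      "text": "Do these difficulties cause you significant distress, or interfere with your work, social life or daily activities?",
      "criterion": "B",
      "response_kind": "binary",
      "branch_rules": {"yes": "END", "no": "END"}
    }
  ]
}
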