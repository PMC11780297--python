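# Scale definitions used by the scoring engine. These are package fixtures:
# item counts follow the published instrument structures (SCHFI v7.2 subscale
# sizes, 10-item self-efficacy scale, 12-item belief scales), but per-item
# response metadata is declared here, not copied from the licensed instruments.
# The benefit/barrier split of each 12-item belief scale (7 benefit, 5 barrier)
# is a declared fixture default; the published split is not public.
schfi_maintenance:
  standardize: true
  threshold_insufficient: 70
  mcid: 8
  items: &likert10
    - {item_id: q01}
    - {item_id: q02}
    - {item_id: q03}
    - {item_id: q04}
    - {item_id: q05}
    - {item_id: q06}
    - {item_id: q07}
    - {item_id: q08}
    - {item_id: q09}
    - {item_id: q10}
schfi_symptom_perception:
  standardize: true
  threshold_insufficient: 70
  mcid: 8
  items:
    - {item_id: q01}
    - {item_id: q02}
    - {item_id: q03}
    - {item_id: q04}
    - {item_id: q05}
    - {item_id: q06}
    - {item_id: q07}
    - {item_id: q08}
    - {item_id: q09}
schfi_management:
  standardize: true
  threshold_insufficient: 70
  mcid: 8
  items: *likert10
scse:
  standardize: true
  threshold_insufficient: 70
  mcid: 8
  items: *likert10
benefits_medication:
  standardize: false
  items: &benefit7
    - {item_id: b1}
    - {item_id: b2}
    - {item_id: b3}
    - {item_id: b4}
    - {item_id: b5}
    - {item_id: b6}
    - {item_id: b7}
barriers_medication:
  standardize: false
  items: &barrier5
    - {item_id: r1}
    - {item_id: r2}
    - {item_id: r3}
    - {item_id: r4}
    - {item_id: r5}
benefits_diet:
  standardize: false
  items: *benefit7
barriers_diet:
  standardize: false
  items: *barrier5
benefits_selfmonitoring:
  standardize: false
  items: *benefit7
barriers_selfmonitoring:
  standardize: false
  items: *barrier5
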