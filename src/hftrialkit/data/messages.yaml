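# Tailoring rules and message bank. The six rules and their example messages
# are the published samples of the decision algorithm; the rest of the bank is
# a placeholder general-education pool (the full proprietary bank is not
# public). Everything here is editable fixture data.
rules:
  - rule_id: med_benefit_waterpills
    target: medication
    item_id: benefits_medication:b1
    rule_kind: benefit
    threshold: 3
    message_ids: [msg_med_benefit_1]
  - rule_id: med_barrier_away_from_home
    target: medication
    item_id: barriers_medication:r1
    rule_kind: barrier
    threshold: 3
    message_ids: [msg_med_barrier_1]
  - rule_id: diet_barrier_taste
    target: diet
    item_id: barriers_diet:r1
    rule_kind: barrier
    threshold: 3
    message_ids: [msg_diet_barrier_1]
  - rule_id: selfmon_barrier_weighing
    target: self_monitoring
    item_id: barriers_selfmonitoring:r1
    rule_kind: barrier
    threshold: 3
    message_ids: [msg_selfmon_barrier_1]
  - rule_id: efficacy_stability
    target: self_efficacy
    item_id: scse:q01
    rule_kind: efficacy
    threshold: 3
    message_ids: [msg_efficacy_1, msg_efficacy_2]
  - rule_id: knowledge_shortness_of_breath
    target: knowledge
    item_id: dhfks:k01
    rule_kind: knowledge
    correct_option: call_doctor_or_nurse
    message_ids: [msg_knowledge_1]

messages:
  msg_med_benefit_1: >-
    Taking water pills as prescribed can help remove extra water from the body
    and lessen the risk of getting hospitalized
  msg_med_barrier_1: >-
    If taking water pills makes it hard to go away from home, one option is to
    take it several hours before you plan to go out or wait until after you
    return home to take it.
  msg_diet_barrier_1: >-
    You can flavor your food without using salt. You can use seasonings like
    pepper, lemon juice, garlic, onion powder, and basil.
  msg_selfmon_barrier_1: >-
    Although weighing yourself daily might be unpleasant, it is important to do
    so because it can help you identify fluid buildup in your body.
  msg_efficacy_1: >-
    Following your doctor's advice and taking your medications as directed are
    important steps to managing your condition.
  msg_efficacy_2: >-
    Tell your doctor right away if you gain 3 or more pounds in a day or feel
    swelling in your feet, ankles, and other parts of your body or if it is
    hard to breathe.
  msg_knowledge_1: >-
    Call your health care provider if you feel any of the following: shortness
    of breath when lying flat or standing and swelling in your legs or stomach.
  msg_general_1: >-
    Weigh yourself every morning after using the bathroom and before breakfast,
    and write the number down or let your scale record it.
  msg_general_2: >-
    A low-sodium diet helps your body hold less fluid. Aim for 2000 to 3000 mg
    of sodium per day.
  msg_general_3: >-
    Try to be active most days of the week. Even short walks add up toward 20
    to 30 minutes of moderate activity a day.
  msg_general_4: >-
    Take your blood pressure at the same time each day so the readings are easy
    to compare.

general_pool: [msg_general_1, msg_general_2, msg_general_3, msg_general_4]
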