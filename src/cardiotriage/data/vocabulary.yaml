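# Default closed vocabularies for symptom triage.
# Codes are canonical (lowercase, underscore-joined). Deployments may override
# this file; the region set must keep at least one code per required group
# (chest, jaw, shoulder, back, arm, axilla).
qualities:
  - dull
  - heavy
  - tight
  - pressure
  - sharp
  - burning

associated_symptoms:
  - shortness_of_breath
  - palpitations
  - racing_heart
  - lightheaded
  - faint
  - dizzy

body_regions:
  - {code: chest_center, side: front, label: "Centre of chest"}
  - {code: chest_left, side: front, label: "Left chest"}
  - {code: chest_right, side: front, label: "Right chest"}
  - {code: jaw, side: front, label: "Jaw"}
  - {code: neck, side: front, label: "Neck / throat"}
  - {code: shoulder_left, side: front, label: "Left shoulder"}
  - {code: shoulder_right, side: front, label: "Right shoulder"}
  - {code: arm_left, side: front, label: "Left arm"}
  - {code: arm_right, side: front, label: "Right arm"}
  - {code: axilla_left, side: front, label: "Left axilla (armpit)"}
  - {code: axilla_right, side: front, label: "Right axilla (armpit)"}
  - {code: abdomen_upper, side: front, label: "Upper abdomen"}
  - {code: back_upper, side: back, label: "Upper back"}
  - {code: back_mid, side: back, label: "Mid back / between shoulder blades"}
  - {code: back_lower, side: back, label: "Lower back"}
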