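[
 {
  "label_1": "High_N",
  "label_2": "High_N",
  "wrist_extension": "High",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": false
 },
 {
  "label_1": "High_N",
  "label_2": "Low_N",
  "wrist_extension": "Med",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": false
 },
 {
  "label_1": "High_N",
  "label_2": "Off",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": false
 },
 {
  "label_1": "High_N",
  "label_2": "Low",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "High_N",
  "label_2": "Med",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "High_N",
  "label_2": "High",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "Low_N",
  "label_2": "High_N",
  "wrist_extension": "Med",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": false
 },
 {
  "label_1": "Low_N",
  "label_2": "Low_N",
  "wrist_extension": "Med",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Med",
  "inferred": false
 },
 {
  "label_1": "Low_N",
  "label_2": "Off",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Med",
  "inferred": false
 },
 {
  "label_1": "Low_N",
  "label_2": "Low",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "Low_N",
  "label_2": "Med",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "Low_N",
  "label_2": "High",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "Off",
  "label_2": "High_N",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": false
 },
 {
  "label_1": "Off",
  "label_2": "Low_N",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Med",
  "inferred": false
 },
 {
  "label_1": "Off",
  "label_2": "Off",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "High",
  "inferred": false
 },
 {
  "label_1": "Off",
  "label_2": "Low",
  "wrist_extension": "Low",
  "ulnar_deviation": "High",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Med",
  "inferred": true
 },
 {
  "label_1": "Off",
  "label_2": "Med",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "Off",
  "label_2": "High",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "Low",
  "label_2": "High_N",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "Low",
  "label_2": "Low_N",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "Low",
  "label_2": "Off",
  "wrist_extension": "Low",
  "ulnar_deviation": "High",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Med",
  "inferred": false
 },
 {
  "label_1": "Low",
  "label_2": "Low",
  "wrist_extension": "Low",
  "ulnar_deviation": "Med",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Med",
  "inferred": false
 },
 {
  "label_1": "Low",
  "label_2": "Med",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": false
 },
 {
  "label_1": "Low",
  "label_2": "High",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "Med",
  "label_2": "High_N",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "Med",
  "label_2": "Low_N",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "Med",
  "label_2": "Off",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "Med",
  "label_2": "Low",
  "wrist_extension": "Low",
  "ulnar_deviation": "Med",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": false
 },
 {
  "label_1": "Med",
  "label_2": "Med",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Med",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": false
 },
 {
  "label_1": "Med",
  "label_2": "High",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "High",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": false
 },
 {
  "label_1": "High",
  "label_2": "High_N",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "High",
  "label_2": "Low_N",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "High",
  "label_2": "Off",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": true
 },
 {
  "label_1": "High",
  "label_2": "Low",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "Low",
  "off_state": "Low",
  "inferred": false
 },
 {
  "label_1": "High",
  "label_2": "Med",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Med",
  "wrist_flexion": "Med",
  "off_state": "Low",
  "inferred": false
 },
 {
  "label_1": "High",
  "label_2": "High",
  "wrist_extension": "Low",
  "ulnar_deviation": "Low",
  "finger_flexion": "Low",
  "wrist_flexion": "High",
  "off_state": "Low",
  "inferred": false
 }
]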