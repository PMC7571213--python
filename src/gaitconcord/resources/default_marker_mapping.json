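{
  "pelvis": ["RPSI", "LPSI"],
  "sternum": ["STRN"],
  "ankle_left": ["LANK"],
  "ankle_right": ["RANK"],
  "heel_left": ["LHEE"],
  "heel_right": ["RHEE"],
  "foot_left": ["LTOE"],
  "foot_right": ["RTOE"]
}
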