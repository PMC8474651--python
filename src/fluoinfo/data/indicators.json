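[
  {"name": "gCaMP6f",       "height": 0.190, "rise": 0.042, "fall": 0.142},
  {"name": "jRGECO1a",      "height": 0.164, "rise": 0.041, "fall": 0.207},
  {"name": "gCaMP7f",       "height": 0.560, "rise": 0.063, "fall": 0.276},
  {"name": "gCaMP6s",       "height": 0.230, "rise": 0.179, "fall": 0.550},
  {"name": "iGluSnfR-A184S","height": 0.300, "rise": 0.022, "fall": 0.106}
]
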