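{
  "efficacy": [
    {"concept": "effectiveness", "score": 1000, "types": ["Qualitative Concept"]},
    {"concept": "Efficacy Study", "score": 1000, "types": ["Research Activity"]}
  ],
  "safety": [
    {"concept": "safety", "score": 1000, "types": ["Human-caused Phenomenon or Process"]},
    {"concept": "safety study", "score": 1000, "types": ["Research Activity"]}
  ]
}
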