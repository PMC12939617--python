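{
  "broad": {
    "name": "broad",
    "pts": {
      "10069649": "Atopic cataract",
      "10007739": "Cataract",
      "10007748": "Cataract cortical",
      "10007759": "Cataract nuclear",
      "10044135": "Toxic cataract",
      "10024214": "Lenticular opacities"
    }
  },
  "narrow": {
    "name": "narrow",
    "pts": {
      "10007739": "Cataract"
    }
  }
}
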