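{
  "t2d": {"name": "Type 2 Diabetes", "altr": 0.25, "heritability": 0.64},
  "crohns": {"name": "Crohn's Disease", "altr": 0.0056, "heritability": 0.80},
  "ra": {"name": "Rheumatoid Arthritis", "altr": 0.0154, "heritability": 0.53}
}
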