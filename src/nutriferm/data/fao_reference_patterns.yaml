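# FAO (2013) amino-acid scoring patterns, mg per g of reference protein.
# Scoring units: His, Ile, Leu, Lys, SAA (Met+Cys), AAA (Phe+Tyr), Thr,
# Trp, Val. Editable: replace with updated requirements if needed.
infant:
  His: 21
  Ile: 55
  Leu: 96
  Lys: 69
  SAA: 33
  AAA: 94
  Thr: 44
  Trp: 17
  Val: 55
child_6mo_3y:
  His: 20
  Ile: 32
  Leu: 66
  Lys: 57
  SAA: 27
  AAA: 52
  Thr: 31
  Trp: 8.5
  Val: 43
older_child_adolescent_adult:
  His: 16
  Ile: 30
  Leu: 61
  Lys: 48
  SAA: 23
  AAA: 41
  Thr: 25
  Trp: 6.6
  Val: 40
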