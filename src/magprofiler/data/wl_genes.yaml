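# Editable gene list defining the Wood-Ljungdahl (reductive acetyl-CoA)
# pathway for wl_count, plus marker genes used as supporting evidence.
# KEGG ortholog ids; edit to match the annotation vocabulary in use.
wl_pathway:
  - K00122   # fdhA, formate dehydrogenase alpha subunit
  - K22015   # fdhF, formate dehydrogenase H
  - K01938   # fhs, formate--tetrahydrofolate ligase
  - K01491   # folD, methylenetetrahydrofolate dehydrogenase/cyclohydrolase
  - K00297   # metF, methylenetetrahydrofolate reductase
  - K15023   # acsE, methyltetrahydrofolate:corrinoid methyltransferase
  - K00198   # cooS, anaerobic carbon-monoxide dehydrogenase
  - K14138   # acsB, acetyl-CoA synthase
  - K00197   # acsC, corrinoid iron-sulfur protein large subunit
  - K00194   # acsD, corrinoid iron-sulfur protein small subunit
markers:
  fhs: K01938
  folD: K01491
  fdhA: K00122
  fdhF: K22015
menaquinone_biosynthesis:
  - K02548   # menA
  - K00661   # menB-related
  - K01911   # menE
  - K02551   # menD
  - K02552   # menF
wl_nearly_complete_threshold: 8
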