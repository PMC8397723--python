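# Default butyrate-production pathway definitions.
#
# Four routes converge on butyryl-CoA: the acetyl-CoA pathway (the dominant
# route in gut Clostridiales, terminal step either butyryl-CoA:acetate
# CoA-transferase `but` — which consumes luminal acetate — or butyrate kinase
# `buk`), and the glutarate, 4-aminobutyrate/succinate and lysine pathways.
# Gene tokens follow the common catalogue naming; edit core_genes /
# terminal_genes to match the annotation columns of your own hit tables.
# required_core_fraction defaults to 1.0 (all core genes required).
pathways:
  - name: acetyl-CoA
    core_genes: [thl, bhbd, cro, bcd]
    terminal_genes: [but, buk]
    required_core_fraction: 1.0
  - name: glutarate
    core_genes: [gctA, gctB, hgCoAdA, hgCoAdB, hgCoAdC, gcdA, gcdB]
    terminal_genes: [but, buk]
    required_core_fraction: 1.0
  - name: 4-aminobutyrate
    core_genes: [abfH, abfD, isom]
    terminal_genes: [4hbt, but, buk]
    required_core_fraction: 1.0
  - name: lysine
    core_genes: [kamA, kamD, kamE, kdd, kce, kal]
    terminal_genes: [atoA, atoD, but, buk]
    required_core_fraction: 1.0
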