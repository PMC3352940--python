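# Taxa documented to bear a hemicaudotheca (caudal prezygapophyses elongated
# but extending little more than one centrum length).  Kept separate from the
# main tail table, which does not include rows for these taxa.
taxon
Utahraptor ostrommaysorum
Achillobator giganticus
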