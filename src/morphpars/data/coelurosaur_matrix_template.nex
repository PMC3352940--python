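#NEXUS
[ Template for the coelurosaurian phylogenetic data matrix.
  The published matrix is distributed as supplementary material to the
  source study and is not redistributable here; transcribe it into this
  file (or any file passed to load_study_matrix) using the dialect below.
  The matrix has >= 307 characters per taxon, including the two added
  pelvic-girdle characters (301 and 307).  '?' = missing, '-' =
  inapplicable (scored as missing by default), '{01}' or '(01)' =
  polymorphic/ambiguous. ]
BEGIN DATA;
DIMENSIONS NTAX=2 NCHAR=4;
FORMAT DATATYPE=STANDARD SYMBOLS="0123" MISSING=? GAP=-;
MATRIX
Example_taxon_A  01?{01}
Example_taxon_B  0-10
;
END;
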