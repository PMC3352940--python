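# Caudal-skeleton data for coelurosaurian theropods (published comparative table).
# NC = number of caudal vertebrae ("(+k)" = estimated additional beyond preserved);
# TP = distalmost caudal with a distinct transverse process; E = cranialmost caudal
# with sudden marked centrum elongation; PZ = cranialmost caudal contributing to the
# caudotheca; C = cranialmost caudal contacted by the caudotheca; 2x = mid-caudal
# centra at least twice as long as proximal ones; TrPt = abrupt transition point.
# "-" = inapplicable, "?" = unknown.
taxon	group	NC	TP	E	PZ	C	2x	TrPt
Gorgosaurus libratus	Tyrannosauridae	31 (+4)	13	-	-	-	No	No
Tyrannosaurus rex	Tyrannosauridae	>34	16	-	-	-	No	No
Huaxiagnathus orientalis	Compsognathidae	>25	17	-	-	-	No	No
Sinocalliopteryx gigas	Compsognathidae	49	16	-	-	-	No	No
Sinosauropteryx prima	Compsognathidae	>64	17	-	-	-	No	No
Gallimimus bullatus	Ornithomimosauria	36-39	14	-	-	-	No	Yes
Harpymimus okladnikovi	Ornithomimosauria	>34	12	-	-	-	No	Yes
Shenzhousaurus orientalis	Ornithomimosauria	>16	11	-	-	-	No	Yes
Alxasaurus elesitaiensis	Therizinosauroidea	>19	13	-	-	-	No	No
Beipiaosaurus inexpectus	Therizinosauroidea	30	?	-	-	-	No	No
Neimongosaurus yangi	Therizinosauroidea	22 (+3 to 8)	>12	-	-	-	No	No
Nothronychus graffami	Therizinosauroidea	23 (+3)	12	-	-	-	No	No
Caudipteryx sp.	Oviraptorosauria	9	-	-	-	-	No	No
Khaan mckennai	Oviraptorosauria	26 (+2)	21	-	-	-	No	No
Nomingia gobiensis	Oviraptorosauria	24	18	-	-	-	No	No
Archaeopteryx sp.	Avialae	22	5	6	-	-	Yes	Yes
Epidendrosaurus ningchengensis	Avialae	22 (+5?)	2	?	-	-	Yes	Yes
Jeholornis prima	Avialae	24-27	2	3	-	-	Yes	Yes
Anchiornis huxleyi	Troodontidae	20 (+6?)	3	5	-	-	Yes	Yes
Sinornithoides dongi	Troodontidae	27	9	9	-	-	Yes	Yes
Buitreraptor gonzalezorum	Unenlagiinae	>14	5	8	-	-	Yes	Yes
Rahonavis ostromi	Unenlagiinae	>13	6	6	-	-	Yes	Yes
Cryptovolans pauli	Microraptoria	28-20	?	5	?	4	Yes	Yes
Microraptor gui	Microraptoria	approx. 26	?	4-6	?	?	Yes	Yes
Microraptor zhaoianus	Microraptoria	24-26	6	6	6	3	Yes	Yes
Tianyraptor ostromi	Microraptoria	>25	?	7	?	3	Yes	Yes
Bambiraptor feinbergorum	Eudromaeosauria	>23	6	10	9	6	Yes	Yes
Deinonychus antirrhopus	Eudromaeosauria	36 (+4)	10	9	>10	8	No	Yes
Tsaagan sp.	Eudromaeosauria	>20	>12	>8	>10	6	No	Yes
Velociraptor mongoliensis	Eudromaeosauria	approx. 30	11	6	10	6	No	Yes
UMNH VP 20209	Eudromaeosauria	?	?	?	>8	>7	?	?
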