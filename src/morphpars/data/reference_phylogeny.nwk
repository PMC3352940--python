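((Gorgosaurus_libratus,Tyrannosaurus_rex),((Huaxiagnathus_orientalis,Sinocalliopteryx_gigas,Sinosauropteryx_prima),((Gallimimus_bullatus,Harpymimus_okladnikovi,Shenzhousaurus_orientalis),((Alxasaurus_elesitaiensis,Beipiaosaurus_inexpectus,Neimongosaurus_yangi,Nothronychus_graffami),((Caudipteryx_sp.,Khaan_mckennai,Nomingia_gobiensis),((Archaeopteryx_sp.,Epidendrosaurus_ningchengensis,Jeholornis_prima),((Anchiornis_huxleyi,Sinornithoides_dongi),((Buitreraptor_gonzalezorum,Rahonavis_ostromi),((Cryptovolans_pauli,Microraptor_gui,Microraptor_zhaoianus,Tianyraptor_ostromi),(Bambiraptor_feinbergorum,((Tsaagan_sp.,Velociraptor_mongoliensis),(Deinonychus_antirrhopus,(Achillobator_giganticus,Utahraptor_ostrommaysorum)))))))))))));
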