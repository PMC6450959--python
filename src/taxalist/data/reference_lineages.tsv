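# Packaged reference lineages (taxid<TAB>root;...;leaf), NCBI-style taxon ids.
# The human path carries 32 edges: the NCBI lineage plus one synthetic
# tribe-level node (9999001) below Homininae; all clade splits are preserved
# (goldfish diverges after Euteleostomi -> ST 13; mouse/rat after
# Euarchontoglires -> ST 22).
9606	1;131567;2759;33154;33208;6072;33213;33511;7711;89593;7742;7776;117570;117571;8287;1338369;32523;32524;40674;32525;9347;1437010;314146;9443;376913;314293;9526;314295;9604;207598;9999001;9605;9606
7957	1;131567;2759;33154;33208;6072;33213;33511;7711;89593;7742;7776;117570;117571;7898;186623;41665;32443;32519;7952;7953;7956;7957
10090	1;131567;2759;33154;33208;6072;33213;33511;7711;89593;7742;7776;117570;117571;8287;1338369;32523;32524;40674;32525;9347;1437010;314146;314147;9989;1963758;337687;10066;39107;10088;10090
10116	1;131567;2759;33154;33208;6072;33213;33511;7711;89593;7742;7776;117570;117571;8287;1338369;32523;32524;40674;32525;9347;1437010;314146;314147;9989;1963758;337687;10066;39107;10114;10116
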