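species,aa,mg_per_g_protein
bovine,ILE,30.1
bovine,LEU,52.4
bovine,VAL,34.6
bovine,HIS,12.2
bovine,LYS,23.8
bovine,MET,12.0
bovine,PHE,26.2
bovine,THR,22.0
bovine,TRP,14.4
bovine,ALA,17.0
bovine,ARG,17.8
bovine,ASX,36.6
bovine,CYS,6.5
bovine,GLX,127.3
bovine,SER,27.9
bovine,TYR,25.5
caprine,ILE,31.3
caprine,LEU,56.5
caprine,VAL,41.6
caprine,HIS,13.2
caprine,LYS,25.2
caprine,MET,11.7
caprine,PHE,28.7
caprine,THR,27.7
caprine,TRP,14.8
caprine,ALA,16.8
caprine,ARG,16.5
caprine,ASX,37.1
caprine,CYS,7.5
caprine,GLX,132.7
caprine,SER,27.8
caprine,TYR,23.0
ovine,ILE,37.0
ovine,LEU,74.1
ovine,VAL,42.9
ovine,HIS,18.9
ovine,LYS,42.1
ovine,MET,18.2
ovine,PHE,34.5
ovine,THR,31.7
ovine,TRP,15.0
ovine,ALA,27.7
ovine,ARG,25.6
ovine,ASX,58.3
ovine,CYS,7.1
ovine,GLX,172.4
ovine,SER,39.4
ovine,TYR,35.5
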