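species,aa,retention_ratio
bovine,ILE,0.61
bovine,LEU,0.64
bovine,VAL,0.66
bovine,HIS,0.77
bovine,LYS,1.11
bovine,MET,0.85
bovine,PHE,0.69
bovine,THR,0.64
bovine,ALA,0.60
bovine,ARG,0.77
bovine,ASX,0.71
bovine,GLX,0.70
bovine,SER,0.71
bovine,TYR,0.77
caprine,ILE,0.42
caprine,LEU,0.46
caprine,VAL,0.47
caprine,HIS,0.55
caprine,LYS,0.78
caprine,MET,0.68
caprine,PHE,0.49
caprine,THR,0.47
caprine,ALA,0.37
caprine,ARG,0.53
caprine,ASX,0.48
caprine,GLX,0.52
caprine,SER,0.50
caprine,TYR,0.51
ovine,ILE,0.37
ovine,LEU,0.35
ovine,VAL,0.41
ovine,HIS,0.36
ovine,LYS,0.47
ovine,MET,0.44
ovine,PHE,0.39
ovine,THR,0.35
ovine,ALA,0.30
ovine,ARG,0.38
ovine,ASX,0.34
ovine,GLX,0.39
ovine,SER,0.37
ovine,TYR,0.59
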