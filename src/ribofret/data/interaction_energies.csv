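compound,component,energy_kcal_mol
C45,PVF,-5.86
C45,Cyto,-5.45
C45,Gua,-8.42
C45,PVF-Cyto-Gua,-19.26
CL,PVF,-18.07
CL,Cyto,-5.17
CL,Gua,-8.68
CL,PVF-Cyto-Gua,-31.49
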