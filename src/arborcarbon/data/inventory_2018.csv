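# Stock volume and area of the 19 dominant arbor tree species, ninth China
# forest resources inventory (statistical year 2018). Areas split by forest
# use class. Units: volume Mm3, areas Mha.
species,volume_Mm3,area_public_welfare_Mha,area_commercial_Mha
Broad-leaved mixed forest,4390.4,24.6,19.9
Quercus,1386.6,9.9,5.4
Fir,1325.0,2.9,0.7
Coniferous and broad-leaved mixed forest,1241.5,7.6,6.6
Larch,1123.0,7.7,3.2
Spruce,972.7,3.7,0.7
Birch,922.9,7.5,2.9
Chinese fir,852.0,4.9,6.5
Masson pine,626.1,3.7,4.3
Poplar,612.4,5.2,3.1
Coniferous mixed forests,574.7,3.0,2.8
Pinus yunnanensis,501.0,2.4,1.9
Pinus densata,332.4,1.2,0.3
Soft broad-leaved forest,302.6,2.8,1.5
Cypress,232.0,2.5,1.2
Eucalyptus,215.6,1.8,3.6
Hardwood broad-leaved forest,154.0,1.7,1.1
Pinus tabulaeformis,145.1,1.8,0.6
Pinus kesiya,61.6,0.3,0.3
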