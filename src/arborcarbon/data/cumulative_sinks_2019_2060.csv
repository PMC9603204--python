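# Published cumulative vegetation carbon sink by dominant species of China's
# existing arbor forests, 2019-2060, MtC, split by forest use class.
species,public_welfare_MtC,commercial_MtC,total_MtC
Broad-leaved mixed forest,2012.7,433,2445.8
Quercus,357.9,113.4,471.4
Fir,55.5,-3.9,51.6
Coniferous and broad-leaved mixed forest,163.4,67,230.5
Larch,348.2,46.4,394.5
Spruce,87.5,4.6,92.1
Birch,38,43.6,81.5
Chinese fir,341.4,163.5,504.8
Masson pine,203.3,102.2,305.5
Poplar,330.2,43,373.2
Coniferous mixed forests,44.9,28.5,73.4
Pinus yunnanensis,27.2,10,37.2
Pinus densata,38.8,2.4,41.2
Soft broad-leaved forest,403.5,48.5,452
Cypress,272,72.5,344.5
Eucalyptus,93.5,244.9,338.4
Hardwood broad-leaved forest,346.2,67.4,413.6
Pinus tabulaeformis,48.8,8.6,57.5
Pinus kesiya,2.6,3.5,6.1
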