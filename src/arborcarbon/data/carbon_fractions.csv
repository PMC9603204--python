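# Organ carbon contents (percent of dry mass) by tree species. Rows sharing
# one measurement are grouped in a single comma-separated species field, as
# published; the loader expands groups so every species gets its own record.
species,stem_pct,root_pct,foliage_pct,branch_pct
Quercus,44.34,42.26,45.86,44.73
"Spruce, Fir",47.54,48.54,50.67,49.35
Coniferous and broad-leaved mixed forest,48.12,48.03,47.22,47.6
Larch,47.52,47.02,47.09,47.77
Birch,45.61,45.19,47.55,47.98
Chinese fir,47.71,43.17,47.95,46.52
Masson pine,47.91,45.96,49.8,48.32
Poplar,46.09,43.76,44.8,46.13
"Pinus kesiya, Pinus densata, Coniferous mixed forests",47.32,47.27,49.28,48.78
Pinus yunnanensis,47.91,45.96,49.8,48.32
Soft broad-leaved forest,45.21,43.5,44.55,44.38
Cypress,48.33,46.13,50.53,48.31
Eucalyptus,45.5,45.23,46.18,45.3
"Broad-leaved mixed forest, Hardwood broad-leaved forest",45.36,43.68,45.61,45.39
Pinus tabulaeformis,47.36,45.92,49.68,48.3
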