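# Published national scenario summary for China's total arbor forests
# (existing plus new afforestation), at benchmark years. scenario denotes the
# use class assigned to all newly planted forests. sink is the annual
# vegetation carbon sink of the benchmark year (undefined for 2018).
scenario,year,area_Mha,stock_MtC,sink_MtC_per_a,density_MgC_per_ha
public_welfare,2018,179.9,7344.8,,40.8
public_welfare,2020,183.3,7894.4,274.5,43.1
public_welfare,2030,200.5,10480.9,249.4,52.3
public_welfare,2040,224.1,12871.4,268.3,57.4
public_welfare,2050,254.2,15510.0,272.3,61.0
public_welfare,2060,254.2,18219.1,279.4,71.7
commercial,2018,179.9,7344.8,,40.8
commercial,2020,183.3,7894.4,274.5,43.1
commercial,2030,200.5,10463.3,244.2,52.2
commercial,2040,224.1,12757.3,251.0,56.9
commercial,2050,254.2,15169.9,241.4,59.7
commercial,2060,254.2,17430.7,211.1,68.6
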