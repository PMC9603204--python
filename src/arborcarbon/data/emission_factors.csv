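# Greenhouse-gas emission factors by fuel and combustion technology,
# g of gas emitted per kg of fuel burned.
fuel,technology,CO2,CH4,N2O,CO,TNMOC
Coal,Anthracite stoves,2876.26,8.78,0.04,58.49,5.82
Forestry bioenergy,Traditional cookstoves,0,9.4,0.08,64.7,9.65
Forestry bioenergy,Improved stoves,0,7.92,0.06,69.5,6.84
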