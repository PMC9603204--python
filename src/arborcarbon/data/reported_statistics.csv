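# Published headline statistics of the national arbor-forest carbon
# accounting study these analyses cross-check. All stocks/sinks are
# vegetation carbon. Units are embedded in the names.
name,value
stock_19_species_2018_MtC,6876.9
stock_19_species_2060_MtC,13591.6
stock_growth_pct,97.6
mean_annual_growth_rate_pct,1.64
stock_existing_2018_MtC,7344.8
stock_existing_2030_MtC,10267.4
stock_existing_2060_MtC,14516.4
stock_existing_pwf_2018_MtC,5004.8
stock_existing_com_2018_MtC,2340.0
stock_existing_pwf_2060_MtC,10575.3
stock_existing_com_2060_MtC,3941.7
share_pwf_2018_pct,68.1
com_growth_2018_2060_pct,68.4
cumulative_sink_existing_MtC,7171.5
mean_annual_sink_existing_MtC_per_a,170.8
mean_annual_sink_existing_pwf_MtC_per_a,132.6
mean_annual_sink_existing_com_MtC_per_a,38.1
density_existing_2018_MgC_per_ha,40.8
density_existing_2060_MgC_per_ha,80.7
arbor_area_2018_Mha,179.9
forest_area_2018_Mha,220.5
forest_coverage_2018_pct,22.96
forest_coverage_2035_pct,26.0
forest_coverage_2050_pct,30.7
forest_area_2035_Mha,249.6
forest_area_2050_Mha,294.8
arbor_area_2050_Mha,254.2
afforestation_rate_2019_2035_Mha,1.7
afforestation_rate_2036_2050_Mha,3.0
cum_mitigation_existing_traditional_MtC,1516.0
cum_mitigation_existing_improved_MtC,2911.2
avg_mitigation_existing_traditional_MtC_per_a,36.1
avg_mitigation_existing_improved_MtC_per_a,69.3
cum_sink_existing_plus_traditional_MtC,8687.6
avg_sink_existing_plus_traditional_MtC_per_a,206.8
pct_gain_traditional,21.1
cum_sink_existing_plus_improved_MtC,10082.7
avg_sink_existing_plus_improved_MtC_per_a,240.1
pct_gain_improved,40.6
cum_sink_new_pwf_MtC,3702.8
cum_sink_new_com_MtC,2914.3
cum_mitigation_new_traditional_MtC,352.3
avg_mitigation_new_traditional_MtC_per_a,8.4
cum_mitigation_new_improved_MtC,690.3
avg_mitigation_new_improved_MtC_per_a,16.4
cum_sink_new_com_plus_traditional_MtC,3266.7
cum_sink_new_com_plus_improved_MtC,3604.7
cum_sink_total_pwf_scenario_MtC,10874.3
avg_sink_total_pwf_scenario_MtC_per_a,258.9
cum_sink_total_com_scenario_MtC,10085.9
avg_sink_total_com_scenario_MtC_per_a,240.1
cum_best_scenario_MtC,13785.5
avg_best_scenario_MtC_per_a,328.2
table1_total_volume_Mm3,15971.5
table1_total_area_Mha,161.8
table1_area_share_pct,89.9
table4_total_pwf_MtC,5215.6
table4_total_com_MtC,1499.1
table4_total_MtC,6714.7
density_2018_min_MgC_per_ha,28.4
density_2018_max_MgC_per_ha,144.3
density_2060_min_MgC_per_ha,44.6
density_2060_max_MgC_per_ha,212.2
young_middle_share_pct,63.9
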