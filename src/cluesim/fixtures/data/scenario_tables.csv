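# Published 2025 class-area demands (ha) and 2017-2025 dynamic-change summary
# for the Weishan mining-area calibration, by policy scenario.
# area_2025_ha: projected demand endpoint; area_change_ha: signed change over
# the simulation horizon; single_dynamics_pct: printed annualised rate (%/yr).
scenario,class_code,class_name,area_2025_ha,area_change_ha,single_dynamics_pct
natural,1,farmland,25907.39,-2801.25,-1.95
natural,2,other agricultural land,41817.72,5515.83,3.04
natural,3,urban and rural construction land,6642.71,-3168.18,-6.46
natural,4,subsided seeper area,1119.64,-65.61,-1.12
natural,5,water area,39199.37,7817.13,4.98
natural,6,tidal wetland,2995.01,-7302.15,-14.2
ecological,1,farmland,24535.92,-4172.49,-2.91
ecological,2,other agricultural land,42839.93,6548.31,3.61
ecological,3,urban and rural construction land,6385.32,-3434.58,-7.01
ecological,4,subsided seeper area,1020.68,-166.05,-2.84
ecological,5,water area,39362.02,7978.77,5.08
ecological,6,tidal wetland,3537.96,-6758.19,-13.14
farmland,1,farmland,28074.34,-629.73,-0.44
farmland,2,other agricultural land,40163.25,3867.03,2.13
farmland,3,urban and rural construction land,6449.67,-3370.5,-6.88
farmland,4,subsided seeper area,1099.93,-85.05,-1.46
farmland,5,water area,38918.11,7528.41,4.79
farmland,6,tidal wetland,2976.55,-7314.39,-14.23
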