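# Published conversion elasticities (ELAS) per class and policy scenario
# for the Weishan mining-area calibration. Higher = more resistant to
# conversion away from currently occupied cells.
scenario,class_code,class_name,elas
natural,1,farmland,0.7
natural,2,other agricultural land,0.5
natural,3,urban and rural construction land,0.9
natural,4,subsided seeper area,0.6
natural,5,water area,0.6
natural,6,tidal wetland,0.55
ecological,1,farmland,0.7
ecological,2,other agricultural land,0.6
ecological,3,urban and rural construction land,0.9
ecological,4,subsided seeper area,0.5
ecological,5,water area,0.7
ecological,6,tidal wetland,0.6
farmland,1,farmland,0.8
farmland,2,other agricultural land,0.5
farmland,3,urban and rural construction land,0.9
farmland,4,subsided seeper area,0.6
farmland,5,water area,0.6
farmland,6,tidal wetland,0.5
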