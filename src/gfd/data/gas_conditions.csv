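label,q_CO,q_CO2,q_H2,q_Acet,q_EtOH,q_BDO,mu
"Syngas, LBC",-18.8,5.65,-12.6,6.35,1.2,0,0.04
"Syngas, MBC",-24.6,8.7,-12.5,5.2,2.5,0.01,0.04
"Syngas, HBC",-30.6,12.55,-11.9,4.05,3.75,0.09,0.04
"Syngas, LBC (b)","-18,792","5,625","-12,583","6,333",1.25,0,0.04
"High-H2 CO, LBC","-20,042","2,125","-33,042","1,083","9,042",0,0.04
"CO, HBC",-31,21,0.5,3.3,2.5,0.03,0.04
"Syngas, HBC (b)",-30,12,-11,4,3.75,0.06,0.04
"High-H2 CO, HBC",-20,4,-29,1.9,7.88,0,0.04
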