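noodle_type,flavor,form,brand,capsaicin,capsaicin_sd,dihydrocapsaicin,dihydrocapsaicin_sd,total,total_sd,packet_g,per_packet,per_packet_sd
regular,mild,powder,NS NGR mild,3.80,0.44,1.57,0.38,5.37,0.7,10.6,0.57,0.07
regular,mild,powder,SY SGK,2.79,0.66,2.36,0.09,5.15,0.57,12.0,0.62,0.07
regular,mild,powder,OTG Jin mild,4.11,0.33,1.81,0.12,5.92,0.34,11.1,0.66,0.04
regular,mild,liquid,OTG BBM,2.04,0.09,0.51,0.54,2.55,0.45,28.8,0.73,0.13
regular,mild,powder,SY SY,3.32,0.45,3.43,0.29,6.75,0.17,12.2,0.82,0.02
regular,mild,powder,NS AS,4.27,0.24,2.20,0.06,6.47,0.19,12.2,0.79,0.02
regular,hot,powder,SY MPM,5.23,0.85,2.89,0.32,8.12,0.76,12.3,1.00,0.09
regular,hot,powder,SY MSN,5.20,0.45,3.63,0.05,8.83,0.46,12.8,1.13,0.06
regular,hot,liquid,PD BBM,3.26,0.33,0.78,0.56,4.04,0.88,28.4,1.15,0.25
regular,hot,powder,NS NGR hot,10.26,0.74,5.54,0.15,15.80,0.62,10.5,1.66,0.06
regular,hot,powder,OTG Jin hot,8.77,0.48,6.27,0.88,15.04,0.92,11.4,1.71,0.11
regular,hot,powder,NS OJE,9.25,0.45,5.91,1.71,15.16,0.64,11.8,1.79,0.08
regular,hot,powder,NS Shin,11.62,1.24,8.40,2.33,20.02,1.11,10.5,2.10,0.12
regular,extremely hot,powder,OTG Yeol,15.40,1.13,12.91,2.39,28.31,1.68,11.7,3.31,0.20
regular,extremely hot,powder,PD TS,26.65,2.60,25.95,3.64,52.60,1.07,12.0,6.31,0.13
regular,extremely hot,liquid,SY BD,17.23,0.95,8.31,1.64,25.54,0.71,28.1,7.18,0.20
cup,mild,powder,NS YGJ,5.83,0.33,3.33,0.25,9.16,0.56,8.2,0.75,0.05
cup,hot,powder,SY MPM,6.46,0.13,3.15,0.08,9.61,0.06,13.0,1.25,0.01
cup,hot,powder,NS SW,6.63,0.34,4.25,0.54,10.88,0.87,13.0,1.41,0.11
cup,hot,powder,PD WTG,9.70,0.84,4.93,0.65,14.63,1.36,11.0,1.61,0.15
cup,hot,powder,NS OJE,7.39,0.32,5.03,0.34,12.42,0.3,11.8,1.47,0.05
cup,hot,powder,NS Shin,11.64,1.01,5.10,1.08,16.74,2.00,14.0,2.34,0.28
cup,hot,liquid,OTG RMB,4.85,0.49,2.70,0.57,7.55,0.29,34.9,2.63,0.10
cup,hot,liquid,OTG Jin hot,12.68,1.49,7.78,0.24,20.46,1.73,13.1,2.68,0.23
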