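dataset,subject,bone,mean_mm
patient,1,femur,0.01
patient,1,tibia,0.07
patient,1,fibula,-0.35
patient,1,patella,0.005
patient,2,femur,0.11
patient,2,tibia,0.05
patient,2,fibula,0.07
patient,2,patella,-0.07
patient,3,femur,0.003
patient,3,tibia,0.003
patient,3,fibula,-0.12
patient,3,patella,-0.07
patient,4,femur,-0.1
patient,4,tibia,-0.05
patient,4,fibula,0.09
patient,4,patella,-0.01
cadaver_single,1,femur,-0.05
cadaver_single,1,tibia,-0.17
cadaver_single,1,fibula,-0.16
cadaver_single,1,patella,0.03
cadaver_single,2,femur,0.05
cadaver_single,2,tibia,-0.23
cadaver_single,2,fibula,-0.11
cadaver_single,2,patella,-0.1
cadaver_single,3,femur,0.05
cadaver_single,3,tibia,0.04
cadaver_single,3,fibula,-0.07
cadaver_single,3,patella,0.01
cadaver_single,4,femur,0.03
cadaver_single,4,tibia,-0.04
cadaver_single,4,fibula,-0.11
cadaver_single,4,patella,-0.09
cadaver_single,5,femur,0.01
cadaver_single,5,tibia,-0.02
cadaver_single,5,fibula,-0.06
cadaver_single,5,patella,0.1
cadaver_single,6,femur,-0.27
cadaver_single,6,tibia,-0.16
cadaver_single,6,fibula,-0.18
cadaver_single,6,patella,-0.16
cadaver_single,7,femur,-0.05
cadaver_single,7,tibia,0.05
cadaver_single,7,fibula,-0.16
cadaver_single,7,patella,-0.02
cadaver_single,8,femur,0.11
cadaver_single,8,tibia,-0.06
cadaver_single,8,fibula,-0.07
cadaver_single,8,patella,-0.02
cadaver_single,9,femur,-0.18
cadaver_single,9,tibia,-0.26
cadaver_single,9,fibula,-0.28
cadaver_single,9,patella,-0.2
cadaver_single,10,femur,-0.04
cadaver_single,10,tibia,-0.06
cadaver_single,10,fibula,-0.08
cadaver_single,10,patella,0.06
cadaver_bilateral,1,femur,0.15
cadaver_bilateral,1,tibia,-0.08
cadaver_bilateral,1,fibula,-0.06
cadaver_bilateral,1,patella,-0.09
cadaver_bilateral,2,femur,0.04
cadaver_bilateral,2,tibia,-0.17
cadaver_bilateral,2,fibula,-0.04
cadaver_bilateral,2,patella,-0.06
cadaver_bilateral,3,femur,0.19
cadaver_bilateral,3,tibia,0.05
cadaver_bilateral,3,fibula,-0.04
cadaver_bilateral,3,patella,-0.09
cadaver_bilateral,4,femur,0.11
cadaver_bilateral,4,tibia,0.05
cadaver_bilateral,4,fibula,-0.02
cadaver_bilateral,4,patella,-0.07
cadaver_bilateral,5,femur,-0.05
cadaver_bilateral,5,tibia,-0.1
cadaver_bilateral,5,fibula,-0.15
cadaver_bilateral,5,patella,-0.04
cadaver_bilateral,6,femur,-0.21
cadaver_bilateral,6,tibia,-0.08
cadaver_bilateral,6,fibula,-0.2
cadaver_bilateral,6,patella,-0.12
cadaver_bilateral,7,femur,0.03
cadaver_bilateral,7,tibia,-0.24
cadaver_bilateral,7,fibula,-0.19
cadaver_bilateral,7,patella,-0.05
cadaver_bilateral,8,femur,-0.22
cadaver_bilateral,8,tibia,-0.27
cadaver_bilateral,8,fibula,-0.13
cadaver_bilateral,8,patella,-0.04
cadaver_bilateral,9,femur,-0.3
cadaver_bilateral,9,tibia,-0.23
cadaver_bilateral,9,fibula,-0.22
cadaver_bilateral,9,patella,-0.1
cadaver_bilateral,10,femur,-0.25
cadaver_bilateral,10,tibia,-0.2
cadaver_bilateral,10,fibula,-0.14
cadaver_bilateral,10,patella,0.01
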