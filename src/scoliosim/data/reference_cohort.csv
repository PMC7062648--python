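patient,sex,age_y,height_cm,mass_kg,curve_type,cobb_deg,convexity
P1,Female,14,157,47,4B,23.9,Left
P2,Female,13,168,46,5,18.1,Left
P3,Female,12,140,35,1B,14.0,Right
P4,Female,14,165,50,3B,24.0,Right
P5,Female,15,168,48,5,24.5,Left
P6,Female,16,172,54,1A,25.5,Right
P7,Female,14,160,50,5,23.4,Right
P8,Male,11,134,39,5,26.5,Left
P9,Female,12,160,45,5,22.1,Left
P10,Female,15,165,45,5,22.4,Right
P11,Male,14,180,50,5,16.3,Right
P12,Female,13,155,44,5,18.3,Left
P13,Male,15,175,52,1A,28.3,Left
P14,Female,15,170,60,5,19.2,Left
P15,Female,15,157,48,5,27.7,Right
P16,Female,9,133,29,5,18.8,Right
P17,Female,11,144,35,5,18.3,Right
P18,Female,14,165,42,5,27.7,Left
P19,Female,13,167,60,5,21.1,Left
P20,Female,14,167,48,5,27.9,Right
P21,Female,16,169,63,1A,25.0,Right
P22,Female,15,168,51,1A,13.6,Right
P23,Female,17,170,53,5,24.7,Right
P24,Female,14,160,45,5,18.3,Left
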