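subject_id,sex,height,motion,theta1,theta2,theta3,theta4,theta5,theta6
M_1,M,170,abduction_adduction,33.1,18.1,44.5,127.3,79.9,26.4
M_2,M,174,abduction_adduction,30.8,15.9,45.3,133.7,72.0,18.3
M_3,M,177,abduction_adduction,24.8,25.9,43.9,130.4,69.8,24.0
M_4,M,190,abduction_adduction,29.1,14.9,33.8,134.3,54.8,10.5
M_5,M,172,abduction_adduction,26.8,13.4,63.1,126.4,70.1,24.5
F_1,F,161,abduction_adduction,21.5,11.3,26.0,132.9,48.2,24.9
F_2,F,159,abduction_adduction,14.4,12.4,25.8,116.1,23.5,33.7
F_3,F,165,abduction_adduction,13.5,6.6,33.1,108.2,63.6,28.0
F_4,F,160,abduction_adduction,21.7,14.8,45.2,146.4,42.5,14.5
F_5,F,154,abduction_adduction,20.3,12.5,29.2,132.5,46.3,29.9
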