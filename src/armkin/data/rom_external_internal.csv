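subject_id,sex,height,motion,theta1,theta2,theta3,theta4,theta5,theta6
M_1,M,170,external_internal,2.6,3.4,8.5,9.4,109.9,18.8
M_2,M,174,external_internal,2.8,2.9,3.5,3.9,97.5,22.1
M_3,M,177,external_internal,2.0,2.2,5.4,9.3,99.5,20.6
M_4,M,190,external_internal,9.0,4.4,11.5,10.2,125.9,32.1
M_5,M,172,external_internal,8.0,3.3,11.2,9.5,122.7,23.6
F_1,F,161,external_internal,6.6,6.9,12.3,8.8,138.5,42.9
F_2,F,159,external_internal,1.3,1.0,5.6,5.1,79.7,22.3
F_3,F,165,external_internal,1.2,1.8,5.7,4.4,89.9,19.2
F_4,F,160,external_internal,3.4,4.5,7.5,8.4,122.4,19.5
F_5,F,154,external_internal,2.0,3.0,8.4,10.9,90.3,13.9
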