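current,C_control,C_caf,N_control,N_caf,M_control,M_caf,K_control,K_caf,G_control,G_caf
I_Na,-440.15,-427.77,-317.39,-328.65,-347.84,-370.27,-332.62,-375.75,-564.11,-1749.59
I_bNa,-0.23,-0.23,-0.41,-0.43,-0.41,-0.42,-0.40,-0.42,-0.51,-0.54
I_CaL,-9.88,-3.62,-10.48,-3.57,-9.87,-3.15,-19.50,-5.09,-47.56,-18.77
I_bCa,-0.55,-0.57,-0.77,-0.81,-0.76,-0.79,-0.78,-0.80,-0.68,-0.71
I_NCX_max,1.33,1.48,2.81,3.61,2.91,3.66,0.69,0.91,0.16,0.70
I_NCX_min,-0.76,-0.78,-1.72,-0.95,-1.55,-0.88,-0.76,-0.83,-5.02,-1.62
I_NKA,0.54,0.54,0.89,0.90,0.86,0.86,0.89,0.92,1.64,1.67
I_PMCA,0.38,0.27,0.16,0.15,0.16,0.15,0.06,0.05,0.26,0.14
I_to,23.31,10.69,19.59,9.28,23.00,10.67,24.16,10.61,30.39,25.82
I_Kur,7.03,5.45,13.67,8.15,11.34,6.67,12.66,7.24,16.29,15.52
I_Kr,0.55,0.50,0.07,0.10,0.08,0.12,0.09,0.13,0.07,0.53
I_Ks,0.21,0.09,4.98,6.05,0.04,0.07,0.05,0.07,0.01,3.34E-3
I_K1,1.17,2.46,1.24,2.60,1.29,2.69,1.29,2.71,1.33,15.91
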