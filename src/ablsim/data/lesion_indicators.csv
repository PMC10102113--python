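case,SV_mL,EF_pct,dEF_pp,AT_pct,IT_pct
Control,21.93,31.53,0,0,0
PVI,18.61,27.73,3.80,8.67,14.30
PVI+BL,15.22,22.55,8.97,12.18,28.96
PVI+AL,17.41,26.18,5.34,11.22,17.69
PVI+AL+BL,13.31,20.09,11.43,14.72,32.35
PVI+AL+RL,16.58,25.13,6.39,13.31,20.28
PVI+MIL,18.91,28.07,3.45,10.03,16.10
PVI+MIL+BL,14.99,22.31,9.21,13.53,30.76
PVI+MIL+RL,18.19,27.18,4.35,12.12,18.68
PVI+RL,18.38,27.34,4.18,10.76,16.88
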