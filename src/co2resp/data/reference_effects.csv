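parameter,term,level,value
meta,reference_intensity,350,
meta,reference_spectrum,37R36G27B,
c,intercept,,-6.89
c,intensity,30,2.27
c,intensity,90,4.55
c,intensity,200,-4.72
c,intensity,500,-5.99
c,intensity,700,-1.87
c,intensity,1000,-6.85
c,spectrum,100B,0.50
c,spectrum,100G,0.17
c,spectrum,100R,0.65
c,spectrum,20B80G,0.12
c,spectrum,20G80R,0.15
c,spectrum,20R80B,0.74
c,spectrum,80B20G,0.51
c,spectrum,80G20R,-0.01
c,spectrum,80R20B,0.18
d,intercept,,9.28
d,intensity,30,-9.02
d,intensity,90,-1.55
d,intensity,200,-2.54
d,intensity,500,0.40
d,intensity,700,2.73
d,intensity,1000,2.70
d,spectrum,100B,2.13
d,spectrum,100G,0.23
d,spectrum,100R,1.57
d,spectrum,20B80G,1.99
d,spectrum,20G80R,-0.32
d,spectrum,20R80B,3.54
d,spectrum,80B20G,1.78
d,spectrum,80G20R,0.21
d,spectrum,80R20B,3.34
b,intercept,,310.32
b,intensity,30,10.39
b,intensity,90,954.64
b,intensity,200,-107.34
b,intensity,500,-107.98
b,intensity,700,23.00
b,intensity,1000,-78.54
b,spectrum,100B,10.37
b,spectrum,100G,0.59
b,spectrum,100R,24.36
b,spectrum,20B80G,15.27
b,spectrum,20G80R,-4.54
b,spectrum,20R80B,4.14
b,spectrum,80B20G,11.42
b,spectrum,80G20R,-1.95
b,spectrum,80R20B,10.81
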