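spectrum,intensity,co2,value
37R36G27B,30,200,-2.36
37R36G27B,90,200,-0.87
37R36G27B,200,200,-0.11
37R36G27B,350,200,0.79
37R36G27B,500,200,1.28
37R36G27B,700,200,0.61
37R36G27B,1000,200,1.13
37R36G27B,30,400,-1.14
37R36G27B,90,400,0.39
37R36G27B,200,400,4.18
37R36G27B,350,400,4.82
37R36G27B,500,400,6.56
37R36G27B,700,400,5.75
37R36G27B,1000,400,7.4
37R36G27B,30,850,-0.08
37R36G27B,90,850,2.59
37R36G27B,200,850,6.46
37R36G27B,350,850,8.23
37R36G27B,500,850,9.34
37R36G27B,700,850,10.39
37R36G27B,1000,850,11.32
100B,30,200,-1.17
100B,90,200,-0.14
100B,200,200,1.05
100B,350,200,1.87
100B,500,200,2.36
100B,700,200,1.62
100B,1000,200,2.14
100B,30,400,0.45
100B,90,400,1.31
100B,200,400,5.81
100B,350,400,6.3
100B,500,400,8.12
100B,700,400,7.14
100B,1000,400,8.87
100B,30,850,1.89
100B,90,850,3.85
100B,200,850,8.5
100B,350,850,10.15
100B,500,850,11.37
100B,700,850,12.25
100B,1000,850,13.29
100G,30,200,-2.16
100G,90,200,-0.69
100G,200,200,0.07
100G,350,200,0.97
100G,500,200,1.46
100G,700,200,0.79
100G,1000,200,1.31
100G,30,400,-0.93
100G,90,400,0.58
100G,200,400,4.39
100G,350,400,5.02
100G,500,400,6.76
100G,700,400,5.95
100G,1000,400,7.6
100G,30,850,0.14
100G,90,850,2.78
100G,200,850,6.69
100G,350,850,8.45
100G,500,850,9.57
100G,700,850,10.61
100G,1000,850,11.55
100R,30,200,-1.42
100R,90,200,-0.11
100R,200,200,0.32
100R,350,200,1.44
100R,500,200,1.53
100R,700,200,1.18
100R,1000,200,1.35
100R,30,400,0.01
100R,90,400,1.24
100R,200,400,4.99
100R,350,400,5.67
100R,500,400,7.23
100R,700,400,6.49
100R,1000,400,7.96
100R,30,850,1.34
100R,90,850,3.62
100R,200,850,7.85
100R,350,850,9.5
100R,500,850,10.7
100R,700,850,11.57
100R,1000,850,12.59
20B80G,30,200,-1.47
20B80G,90,200,-0.49
20B80G,200,200,0.64
20B80G,350,200,1.51
20B80G,500,200,1.93
20B80G,700,200,1.24
20B80G,1000,200,1.69
20B80G,30,400,0.2
20B80G,90,400,0.98
20B80G,200,400,5.5
20B80G,350,400,5.99
20B80G,500,400,7.78
20B80G,700,400,6.81
20B80G,1000,400,8.5
20B80G,30,850,1.71
20B80G,90,850,3.57
20B80G,200,850,8.32
20B80G,350,850,9.94
20B80G,500,850,11.18
20B80G,700,850,12.02
20B80G,1000,850,13.08
20G80R,30,200,-2.4
20G80R,90,200,-0.77
20G80R,200,200,-0.1
20G80R,350,200,0.8
20G80R,500,200,1.32
20G80R,700,200,0.64
20G80R,1000,200,1.19
20G80R,30,400,-1.3
20G80R,90,400,0.43
20G80R,200,400,4.04
20G80R,350,400,4.72
20G80R,500,400,6.44
20G80R,700,400,5.68
20G80R,1000,400,7.32
20G80R,30,850,-0.36
20G80R,90,850,2.52
20G80R,200,850,6.17
20G80R,350,850,7.99
20G80R,500,850,9.06
20G80R,700,850,10.16
20G80R,1000,850,11.06
20R80B,30,200,-0.35
20R80B,90,200,0.29
20R80B,200,200,2.23
20R80B,350,200,2.78
20R80B,500,200,3.59
20R80B,700,200,2.52
20R80B,1000,200,3.31
20R80B,30,400,1.56
20R80B,90,400,1.89
20R80B,200,400,7.21
20R80B,350,400,7.5
20R80B,500,400,9.57
20R80B,700,400,8.35
20R80B,1000,400,10.29
20R80B,30,850,3.24
20R80B,90,850,4.69
20R80B,200,850,9.93
20R80B,350,850,11.55
20R80B,500,850,12.81
20R80B,700,850,13.65
20R80B,1000,850,14.74
80B20G,30,200,-1.33
80B20G,90,200,-0.18
80B20G,200,200,0.8
80B20G,350,200,1.69
80B20G,500,200,2.11
80B20G,700,200,1.45
80B20G,1000,200,1.91
80B20G,30,400,0.2
80B20G,90,400,1.23
80B20G,200,400,5.48
80B20G,350,400,6.03
80B20G,500,400,7.79
80B20G,700,400,6.88
80B20G,1000,400,8.55
80B20G,30,850,1.56
80B20G,90,850,3.69
80B20G,200,850,8.15
80B20G,350,850,9.82
80B20G,500,850,11.01
80B20G,700,850,11.92
80B20G,1000,850,12.94
80G20R,30,200,-2.25
80G20R,90,200,-0.84
80G20R,200,200,0.08
80G20R,350,200,0.92
80G20R,500,200,1.49
80G20R,700,200,0.74
80G20R,1000,200,1.32
80G20R,30,400,-0.98
80G20R,90,400,0.44
80G20R,200,400,4.41
80G20R,350,400,5.01
80G20R,500,400,6.79
80G20R,700,400,5.94
80G20R,1000,400,7.64
80G20R,30,850,0.12
80G20R,90,850,2.69
80G20R,200,850,6.68
80G20R,350,850,8.45
80G20R,500,850,9.56
80G20R,700,850,10.61
80G20R,1000,850,11.55
80R20B,30,200,-0.8
80R20B,90,200,-0.23
80R20B,200,200,1.64
80R20B,350,200,2.25
80R20B,500,200,2.96
80R20B,700,200,1.97
80R20B,1000,200,2.66
80R20B,30,400,1.19
80R20B,90,400,1.41
80R20B,200,400,6.77
80R20B,350,400,7.06
80R20B,500,400,9.08
80R20B,700,400,7.87
80R20B,1000,400,9.77
80R20B,30,850,2.98
80R20B,90,850,4.28
80R20B,200,850,9.68
80R20B,350,850,11.25
80R20B,500,850,12.54
80R20B,700,850,13.33
80R20B,1000,850,14.45
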