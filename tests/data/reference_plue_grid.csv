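spectrum,intensity,co2,value
37R36G27B,30,200,-78.52
37R36G27B,90,200,-9.64
37R36G27B,200,200,-0.55
37R36G27B,350,200,2.26
37R36G27B,500,200,2.57
37R36G27B,700,200,0.87
37R36G27B,1000,200,1.13
37R36G27B,30,400,-38.07
37R36G27B,90,400,4.33
37R36G27B,200,400,20.91
37R36G27B,350,400,13.78
37R36G27B,500,400,13.11
37R36G27B,700,400,8.22
37R36G27B,1000,400,7.4
37R36G27B,30,850,-2.82
37R36G27B,90,850,28.75
37R36G27B,200,850,32.31
37R36G27B,350,850,23.53
37R36G27B,500,850,18.68
37R36G27B,700,850,14.84
37R36G27B,1000,850,11.32
100B,30,200,-38.94
100B,90,200,-1.58
100B,200,200,5.23
100B,350,200,5.34
100B,500,200,4.72
100B,700,200,2.32
100B,1000,200,2.14
100B,30,400,14.84
100B,90,400,14.55
100B,200,400,29.03
100B,350,400,17.99
100B,500,400,16.24
100B,700,400,10.21
100B,1000,400,8.87
100B,30,850,63.01
100B,90,850,42.8
100B,200,850,42.49
100B,350,850,29.01
100B,500,850,22.73
100B,700,850,17.5
100B,1000,850,13.29
100G,30,200,-72.03
100G,90,200,-7.66
100G,200,200,0.37
100G,350,200,2.79
100G,500,200,2.93
100G,700,200,1.13
100G,1000,200,1.31
100G,30,400,-31.08
100G,90,400,6.39
100G,200,400,21.94
100G,350,400,14.35
100G,500,400,13.52
100G,700,400,8.5
100G,1000,400,7.6
100G,30,850,4.65
100G,90,850,30.94
100G,200,850,33.43
100G,350,850,24.16
100G,500,850,19.13
100G,700,850,15.15
100G,1000,850,11.55
100R,30,200,-47.29
100R,90,200,-1.23
100R,200,200,1.58
100R,350,200,4.12
100R,500,200,3.06
100R,700,200,1.69
100R,1000,200,1.35
100R,30,400,0.34
100R,90,400,13.79
100R,200,400,24.96
100R,350,400,16.21
100R,500,400,14.45
100R,700,400,9.27
100R,1000,400,7.96
100R,30,850,44.54
100R,90,850,40.17
100R,200,850,39.26
100R,350,850,27.15
100R,500,850,21.39
100R,700,850,16.52
100R,1000,850,12.59
20B80G,30,200,-49.07
20B80G,90,200,-5.48
20B80G,200,200,3.21
20B80G,350,200,4.31
20B80G,500,200,3.85
20B80G,700,200,1.78
20B80G,1000,200,1.69
20B80G,30,400,6.59
20B80G,90,400,10.93
20B80G,200,400,27.48
20B80G,350,400,17.11
20B80G,500,400,15.57
20B80G,700,400,9.73
20B80G,1000,400,8.5
20B80G,30,850,57.08
20B80G,90,850,39.7
20B80G,200,850,41.59
20B80G,350,850,28.41
20B80G,500,850,22.36
20B80G,700,850,17.18
20B80G,1000,850,13.08
20G80R,30,200,-80.09
20G80R,90,200,-8.59
20G80R,200,200,-0.51
20G80R,350,200,2.28
20G80R,500,200,2.65
20G80R,700,200,0.92
20G80R,1000,200,1.19
20G80R,30,400,-43.48
20G80R,90,400,4.75
20G80R,200,400,20.2
20G80R,350,400,13.47
20G80R,500,400,12.87
20G80R,700,400,8.11
20G80R,1000,400,7.32
20G80R,30,850,-11.99
20G80R,90,850,28.05
20G80R,200,850,30.87
20G80R,350,850,22.82
20G80R,500,850,18.12
20G80R,700,850,14.51
20G80R,1000,850,11.06
20R80B,30,200,-11.64
20R80B,90,200,3.17
20R80B,200,200,11.14
20R80B,350,200,7.94
20R80B,500,200,7.19
20R80B,700,200,3.6
20R80B,1000,200,3.31
20R80B,30,400,51.94
20R80B,90,400,20.96
20R80B,200,400,36.07
20R80B,350,400,21.44
20R80B,500,400,19.13
20R80B,700,400,11.92
20R80B,1000,400,10.29
20R80B,30,850,107.97
20R80B,90,850,52.09
20R80B,200,850,49.65
20R80B,350,850,33.0
20R80B,500,850,25.61
20R80B,700,850,19.5
20R80B,1000,850,14.74
80B20G,30,200,-44.26
80B20G,90,200,-1.96
80B20G,200,200,4.02
80B20G,350,200,4.84
80B20G,500,200,4.22
80B20G,700,200,2.07
80B20G,1000,200,1.91
80B20G,30,400,6.52
80B20G,90,400,13.65
80B20G,200,400,27.42
80B20G,350,400,17.23
80B20G,500,400,15.58
80B20G,700,400,9.83
80B20G,1000,400,8.55
80B20G,30,850,52.14
80B20G,90,850,40.99
80B20G,200,850,40.74
80B20G,350,850,28.05
80B20G,500,850,22.03
80B20G,700,850,17.03
80B20G,1000,850,12.94
80G20R,30,200,-75.11
80G20R,90,200,-9.37
80G20R,200,200,0.42
80G20R,350,200,2.63
80G20R,500,200,2.98
80G20R,700,200,1.06
80G20R,1000,200,1.32
80G20R,30,400,-32.8
80G20R,90,400,4.93
80G20R,200,400,22.05
80G20R,350,400,14.32
80G20R,500,400,13.59
80G20R,700,400,8.49
80G20R,1000,400,7.64
80G20R,30,850,3.85
80G20R,90,850,29.89
80G20R,200,850,33.4
80G20R,350,850,24.14
80G20R,500,850,19.12
80G20R,700,850,15.15
80G20R,1000,850,11.55
80R20B,30,200,-26.6
80R20B,90,200,-2.58
80R20B,200,200,8.2
80R20B,350,200,6.43
80R20B,500,200,5.91
80R20B,700,200,2.81
80R20B,1000,200,2.66
80R20B,30,400,25.12
80R20B,90,400,15.65
80R20B,200,400,33.84
80R20B,350,400,20.16
80R20B,500,400,18.16
80R20B,700,400,11.24
80R20B,1000,400,9.77
80R20B,30,850,99.36
80R20B,90,850,47.55
80R20B,200,850,48.38
80R20B,350,850,32.14
80R20B,500,850,25.09
80R20B,700,850,19.04
80R20B,1000,850,14.45
Mean,30,200,-52.36
Mean,90,200,-4.49
Mean,200,200,3.31
Mean,350,200,4.29
Mean,500,200,4.01
Mean,700,200,1.82
Mean,1000,200,1.8
Mean,30,400,-4.01
Mean,90,400,10.99
Mean,200,400,26.39
Mean,350,400,16.61
Mean,500,400,15.22
Mean,700,400,9.55
Mean,1000,400,8.39
Mean,30,850,41.78
Mean,90,850,38.09
Mean,200,850,39.21
Mean,350,850,27.24
Mean,500,850,21.43
Mean,700,850,16.64
Mean,1000,850,12.66
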