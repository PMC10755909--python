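spectrum,intensity,co2,value
37R36G27B,30,200,-149.0
37R36G27B,90,200,-118.0
37R36G27B,200,200,-102.0
37R36G27B,350,200,-84.0
37R36G27B,500,200,-73.0
37R36G27B,700,200,-87.0
37R36G27B,1000,200,-77.0
37R36G27B,30,400,-124.0
37R36G27B,90,400,-92.0
37R36G27B,200,400,-13.0
37R36G27B,350,400,0.0
37R36G27B,500,400,36.0
37R36G27B,700,400,19.0
37R36G27B,1000,400,53.0
37R36G27B,30,850,-102.0
37R36G27B,90,850,-46.0
37R36G27B,200,850,34.0
37R36G27B,350,850,71.0
37R36G27B,500,850,94.0
37R36G27B,700,850,115.0
37R36G27B,1000,850,135.0
100B,30,200,-124.0
100B,90,200,-103.0
100B,200,200,-78.0
100B,350,200,-61.0
100B,500,200,-51.0
100B,700,200,-66.0
100B,1000,200,-56.0
100B,30,400,-91.0
100B,90,400,-73.0
100B,200,400,20.0
100B,350,400,31.0
100B,500,400,68.0
100B,700,400,48.0
100B,1000,400,84.0
100B,30,850,-61.0
100B,90,850,-20.0
100B,200,850,76.0
100B,350,850,110.0
100B,500,850,136.0
100B,700,850,154.0
100B,1000,850,176.0
100G,30,200,-145.0
100G,90,200,-114.0
100G,200,200,-98.0
100G,350,200,-80.0
100G,500,200,-70.0
100G,700,200,-84.0
100G,1000,200,-73.0
100G,30,400,-119.0
100G,90,400,-88.0
100G,200,400,-9.0
100G,350,400,4.0
100G,500,400,40.0
100G,700,400,23.0
100G,1000,400,58.0
100G,30,850,-97.0
100G,90,850,-42.0
100G,200,850,39.0
100G,350,850,75.0
100G,500,850,98.0
100G,700,850,120.0
100G,1000,850,139.0
100R,30,200,-129.0
100R,90,200,-102.0
100R,200,200,-93.0
100R,350,200,-70.0
100R,500,200,-68.0
100R,700,200,-76.0
100R,1000,200,-72.0
100R,30,400,-100.0
100R,90,400,-74.0
100R,200,400,3.0
100R,350,400,18.0
100R,500,400,50.0
100R,700,400,35.0
100R,1000,400,65.0
100R,30,850,-72.0
100R,90,850,-25.0
100R,200,850,63.0
100R,350,850,97.0
100R,500,850,122.0
100R,700,850,140.0
100R,1000,850,161.0
20B80G,30,200,-131.0
20B80G,90,200,-110.0
20B80G,200,200,-87.0
20B80G,350,200,-69.0
20B80G,500,200,-60.0
20B80G,700,200,-74.0
20B80G,1000,200,-65.0
20B80G,30,400,-96.0
20B80G,90,400,-80.0
20B80G,200,400,14.0
20B80G,350,400,24.0
20B80G,500,400,61.0
20B80G,700,400,41.0
20B80G,1000,400,76.0
20B80G,30,850,-65.0
20B80G,90,850,-26.0
20B80G,200,850,72.0
20B80G,350,850,106.0
20B80G,500,850,132.0
20B80G,700,850,149.0
20B80G,1000,850,171.0
20G80R,30,200,-150.0
20G80R,90,200,-116.0
20G80R,200,200,-102.0
20G80R,350,200,-83.0
20G80R,500,200,-73.0
20G80R,700,200,-87.0
20G80R,1000,200,-75.0
20G80R,30,400,-127.0
20G80R,90,400,-91.0
20G80R,200,400,-16.0
20G80R,350,400,-2.0
20G80R,500,400,33.0
20G80R,700,400,18.0
20G80R,1000,400,52.0
20G80R,30,850,-107.0
20G80R,90,850,-48.0
20G80R,200,850,28.0
20G80R,350,850,66.0
20G80R,500,850,88.0
20G80R,700,850,111.0
20G80R,1000,850,129.0
20R80B,30,200,-107.0
20R80B,90,200,-94.0
20R80B,200,200,-54.0
20R80B,350,200,-42.0
20R80B,500,200,-26.0
20R80B,700,200,-48.0
20R80B,1000,200,-31.0
20R80B,30,400,-68.0
20R80B,90,400,-61.0
20R80B,200,400,50.0
20R80B,350,400,56.0
20R80B,500,400,98.0
20R80B,700,400,73.0
20R80B,1000,400,113.0
20R80B,30,850,-33.0
20R80B,90,850,-3.0
20R80B,200,850,106.0
20R80B,350,850,139.0
20R80B,500,850,165.0
20R80B,700,850,183.0
20R80B,1000,850,206.0
80B20G,30,200,-128.0
80B20G,90,200,-104.0
80B20G,200,200,-83.0
80B20G,350,200,-65.0
80B20G,500,200,-56.0
80B20G,700,200,-70.0
80B20G,1000,200,-61.0
80B20G,30,400,-96.0
80B20G,90,400,-75.0
80B20G,200,400,14.0
80B20G,350,400,25.0
80B20G,500,400,62.0
80B20G,700,400,43.0
80B20G,1000,400,77.0
80B20G,30,850,-68.0
80B20G,90,850,-24.0
80B20G,200,850,69.0
80B20G,350,850,104.0
80B20G,500,850,128.0
80B20G,700,850,147.0
80B20G,1000,850,168.0
80G20R,30,200,-147.0
80G20R,90,200,-117.0
80G20R,200,200,-98.0
80G20R,350,200,-81.0
80G20R,500,200,-69.0
80G20R,700,200,-85.0
80G20R,1000,200,-73.0
80G20R,30,400,-120.0
80G20R,90,400,-91.0
80G20R,200,400,-9.0
80G20R,350,400,4.0
80G20R,500,400,41.0
80G20R,700,400,23.0
80G20R,1000,400,58.0
80G20R,30,850,-98.0
80G20R,90,850,-44.0
80G20R,200,850,38.0
80G20R,350,850,75.0
80G20R,500,850,98.0
80G20R,700,850,120.0
80G20R,1000,850,139.0
80R20B,30,200,-117.0
80R20B,90,200,-105.0
80R20B,200,200,-66.0
80R20B,350,200,-53.0
80R20B,500,200,-39.0
80R20B,700,200,-59.0
80R20B,1000,200,-45.0
80R20B,30,400,-75.0
80R20B,90,400,-71.0
80R20B,200,400,40.0
80R20B,350,400,46.0
80R20B,500,400,88.0
80R20B,700,400,63.0
80R20B,1000,400,102.0
80R20B,30,850,-38.0
80R20B,90,850,-11.0
80R20B,200,850,101.0
80R20B,350,850,133.0
80R20B,500,850,160.0
80R20B,700,850,176.0
80R20B,1000,850,200.0
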