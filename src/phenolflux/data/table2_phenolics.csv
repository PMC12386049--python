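category,compound,rt_min,mean:40C-NE,sd:40C-NE,mean:40C-0.5%,sd:40C-0.5%,mean:40C-1%,sd:40C-1%,mean:50C-NE,sd:50C-NE,mean:50C-0.5%,sd:50C-0.5%,mean:50C-1%,sd:50C-1%
phenolic acid,Homovanillic acid,26.76,100.42,0.26,139.05,4.43,91.74,0.88,201.14,5.34,106.30,0.49,213.36,0.26
phenolic acid,p-Coumaric acid,34.70,16.22,1.87,27.75,1.04,15.31,0.27,104.67,13.35,33.41,9.17,60.00,0.33
phenolic acid,Chlorogenic acid,23.01,142.92,0.96,108.15,9.85,99.36,3.13,158.11,3.73,125.42,7.44,240.74,1.20
phenolic acid,p-Hydroxybenzoic acid,24.81,23.74,3.05,50.50,2.37,24.13,3.12,47.90,7.90,53.34,3.07,140.97,5.16
phenolic acid,Syringic acid,28.05,34.90,1.42,56.84,0.89,32.39,0.83,148.27,3.74,47.00,3.30,101.14,2.44
phenolic acid,Ferulic acid,35.72,13.75,2.08,28.10,1.34,12.88,0.65,50.62,2.36,19.43,3.02,40.57,8.57
phenolic acid,Gallic acid,11.84,27.86,0.24,12.21,0.07,28.23,4.01,61.96,0.91,38.00,4.52,52.86,7.81
phenolic acid,Protocatechuic acid,17.95,148.61,3.36,174.34,6.91,34.64,1.54,82.64,2.15,43.37,3.22,70.91,3.39
phenolic acid,Caffeic acid,27.37,78.96,2.40,31.49,1.38,19.48,0.79,171.52,1.82,74.47,9.47,98.12,3.07
dihydrochalcone,Phloretic acid,30.95,154.32,1.94,263.92,6.46,161.05,3.66,404.97,3.78,194.31,13.44,438.13,1.34
dihydrochalcone,Phloretin,50.68,-,-,-,-,21.49,1.51,30.26,5.35,8.50,2.02,64.34,1.79
flavanol,Procyanidin B2,20.23,136.16,1.86,183.73,8.42,131.19,3.34,328.96,23.37,227.33,27.33,311.20,18.50
flavanol,Catechin,20.03,309.10,5.72,578.69,14.18,539.73,2.50,44.08,3.45,475.80,45.72,855.66,10.93
flavanol,Epicatechin,25.89,179.66,1.27,202.32,33.64,169.94,1.44,500.73,4.35,255.04,12.89,413.93,8.69
flavonol,Rutin,40.27,-,-,-,-,-,-,16.88,1.34,19.05,3.05,20.05,3.88
flavonol,Quercetin-3-O-rutinoside,43.89,-,-,-,-,-,-,1.46,0.96,2.02,0.97,3.06,1.06
flavonol,Myricetin,43.55,11.19,1.34,10.53,0.13,9.67,0.57,23.74,4.23,27.44,3.26,26.63,6.63
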