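taxon,n,PN_mean,PN_sd,MD_mean,MD_sd,ML_mean,ML_sd
P. acuta,5,1.93,0.07,205.35,14.12,221.30,7.59
P. albopicta,6,2.19,0.05,184.59,8.43,188.08,10.44
P. americana americana,140,3.10,0.21,236.13,19.46,213.40,38.12
P. americana coloradensis,62,3.37,0.23,211.89,29.54,147.22,34.39
P. americana metcalfi,82,2.80,0.19,230.57,26.82,110.93,19.25
P. arctostaphylae,8,3.10,0.13,253.40,9.44,216.27,11.71
P. armata,6,2.28,0.14,182.26,13.79,177.44,12.42
P. bimini,6,2.67,0.09,219.96,21.90,118.72,21.02
P. borica,10,2.64,0.22,240.11,16.38,148.43,26.47
P. carinata,6,3.37,0.23,237.03,24.01,128.41,5.30
P. chilensis,10,3.14,0.15,226.21,28.46,115.99,18.54
P. communis,5,2.59,0.13,237.67,14.91,132.27,6.26
P. crassipes,6,2.74,0.10,230.98,9.51,177.97,17.28
P. delpontei,5,2.38,0.04,188.34,25.78,170.63,19.00
P. fasciata fasciata,38,3.07,0.22,186.61,27.05,163.33,26.58
P. fasciata mexicana,7,3.11,0.16,217.15,15.06,181.59,24.12
P. fasciata panamensis,4,3.29,0190,222.41,27.05,171.36,16.16
P. fortficata argentina,9,3.70,0.19,205.77,11.91,187.74,14.92
P. fortificata fortificata,9,4.04,0.28,192.77,25.98,189.18,24.83
P. granulosa,6,3.35,0.32,253.23,9.66,209.89,26.17
P. guerini,7,2.97,0.24,201.19,16.23,145.83,16.05
P. lindigiana,6,1.87,0.08,235.57,10.57,136.71,8.66
P. luxa,6,1.91,0.15,179.80,13.70,173.70,15.28
P. marginata,8,2.17,0.09,196.83,8.76,156.73,21.82
P. monstrosa,5,2.67,0.17,246.32,14.64,206.51,34.22
P. mystica,55,3.15,0.25,209.69,37.69,176.76,45.31
P. nouahlieri,5,2.28,0.06,186.64,21.75,194.61,19.24
P. pacifica pacifica,10,2.61,0.15,164.92,35.22,131.51,16.05
P. pacifica stanfordi,6,2.58,0.18,210.43,34.32,116.81,19.67
P. pennsylvanica,143,2.76,0.18,226.31,23.05,213.81,29.22
P. praestans,8,4.19,0.11,215.09,17.96,138.95,11.70
P. rossi,7,2.84,0.16,212.57,12.52,135.62,9.26
P. salicis,7,2.50,0.11,160.51,27.88,119.79,12.48
P. severini,6,2.21,0.09,218.31,15.95,203.70,28.05
P. simulans,5,2.03,0.12,235.62,13.18,184.18,40.65
P. stali,13,2.55,0.10,204.85,30.43,154.59,30.00
P. vicina,52,2.19,0.19,221.68,25.27,182.00,31.92
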