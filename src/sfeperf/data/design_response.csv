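run_id,pressure_mpa,temperature_c,water_pct,ccd_role,yield_pct,solubility_e3
1,24,60,30,factorial,12.9,2.4
2,24,70,30,factorial,15.9,2.35
3,21,58,20,axial,4.05,0.2
4,18,70,30,factorial,6.26,0.1
5,24,60,10,factorial,3.73,0.3
6,21,72,20,axial,7.87,0.2
7,25,65,20,axial,12.74,1.0
8,21,65,33,axial,11.8,0.89
9,21,65,20,center,4.9,0.4
10,18,60,30,factorial,2.23,0.5
11,21,65,20,center,5.61,0.3
12,24,70,10,factorial,4.5,0.9
13,18,70,10,factorial,2.47,0.3
14,18,60,10,factorial,2.35,0.1
15,21,65,7,axial,3.18,0.8
16,17,65,20,axial,2.9,0.5
17,21,65,20,center,5.8,0.4
18,21,65,20,center,6.88,0.5
19,21,65,20,center,6.9,0.6
20,21,65,20,center,7.5,0.3
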