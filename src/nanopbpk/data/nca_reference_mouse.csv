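np_label,compartment,metric,value,provenance
8A,plasma,cmax,33,printed
8A,plasma,tmax,0,printed
8A,plasma,auc_0_inf,76,printed
8A,plasma,auc_0_72,71,printed
8A,plasma,cl,5.24,printed
8A,plasma,vdss,123.4,printed
8A,plasma,t_half,16.5,printed
8A,lungs,cmax,32,parsed-with-caution
8A,lungs,tmax,0,printed
8A,lungs,auc_0_inf,720,printed
8A,lungs,auc_0_72,710,printed
8A,lungs,cl,0.56,printed
8A,lungs,vdss,27.6,printed
8A,lungs,t_half,9.49,printed
8A,mps,cmax,66,parsed-with-caution
8A,mps,tmax,1.92,printed
8A,mps,auc_0_inf,4540,printed
8A,mps,auc_0_72,2430,printed
8A,mps,cl,0.088,printed
8A,mps,vdss,37.38,printed
8A,mps,t_half,57.75,printed
8A,kidneys,cmax,12,parsed-with-caution
8A,kidneys,tmax,0,printed
8A,kidneys,auc_0_inf,91,printed
8A,kidneys,auc_0_72,78,printed
8A,kidneys,cl,4.41,printed
8A,kidneys,vdss,136.27,printed
8A,kidneys,t_half,21.66,printed
AR8,plasma,cmax,21,printed
AR8,plasma,tmax,0,printed
AR8,plasma,auc_0_inf,120,printed
AR8,plasma,auc_0_72,110,printed
AR8,plasma,cl,3.3,printed
AR8,plasma,vdss,84.4,printed
AR8,plasma,t_half,17.76,printed
AR8,lungs,cmax,77,parsed-with-caution
AR8,lungs,tmax,0,printed
AR8,lungs,auc_0_inf,2680,printed
AR8,lungs,auc_0_72,2590,printed
AR8,lungs,cl,0.15,printed
AR8,lungs,vdss,32.7,printed
AR8,lungs,t_half,43.31,printed
AR8,mps,cmax,330,printed
AR8,mps,tmax,0.42,printed
AR8,mps,auc_0_inf,60050,printed
AR8,mps,auc_0_72,17200,printed
AR8,mps,cl,0.0067,printed
AR8,mps,vdss,21.31,printed
AR8,mps,t_half,135.88,printed
AR8,kidneys,cmax,12,printed
AR8,kidneys,tmax,0,printed
AR8,kidneys,auc_0_inf,490,printed
AR8,kidneys,auc_0_72,210,printed
AR8,kidneys,cl,0.82,printed
AR8,kidneys,vdss,114.23,printed
AR8,kidneys,t_half,96.25,printed
MA,plasma,cmax,29,printed
MA,plasma,tmax,0,printed
MA,plasma,auc_0_inf,61,printed
MA,plasma,auc_0_72,60,printed
MA,plasma,cl,6.59,printed
MA,plasma,vdss,104.88,printed
MA,plasma,t_half,11,printed
MA,lungs,cmax,16,printed
MA,lungs,tmax,0,printed
MA,lungs,auc_0_inf,150,printed
MA,lungs,auc_0_72,100,printed
MA,lungs,cl,2.61,printed
MA,lungs,vdss,159.2,printed
MA,lungs,t_half,43.3,printed
MA,mps,cmax,120,printed
MA,mps,tmax,0,printed
MA,mps,auc_0_inf,9600,printed
MA,mps,auc_0_72,6030,printed
MA,mps,cl,0.042,printed
MA,mps,vdss,33.44,printed
MA,mps,t_half,216.5,printed
MA,kidneys,cmax,8.4,printed
MA,kidneys,tmax,0,printed
MA,kidneys,auc_0_inf,90,printed
MA,kidneys,auc_0_72,52,printed
MA,kidneys,cl,4.45,printed
MA,kidneys,vdss,18.7,printed
MA,kidneys,t_half,63,printed
Meso,plasma,cmax,16,parsed-with-caution
Meso,plasma,tmax,0,printed
Meso,plasma,auc_0_inf,150,printed
Meso,plasma,auc_0_72,130,printed
Meso,plasma,cl,2.66,printed
Meso,plasma,vdss,85.5,printed
Meso,plasma,t_half,22.35,printed
Meso,lungs,cmax,590,parsed-with-caution
Meso,lungs,tmax,0.42,printed
Meso,lungs,auc_0_inf,12950,printed
Meso,lungs,auc_0_72,11790,printed
Meso,lungs,cl,0.031,printed
Meso,lungs,vdss,70.8,printed
Meso,lungs,t_half,18.72,printed
Meso,mps,cmax,73,parsed-with-caution
Meso,mps,tmax,0.42,printed
Meso,mps,auc_0_inf,19040,printed
Meso,mps,auc_0_72,4290,printed
Meso,mps,cl,0.021,printed
Meso,mps,vdss,46.49,printed
Meso,mps,t_half,216.56,printed
Meso,kidneys,cmax,6,parsed-with-caution
Meso,kidneys,tmax,0,printed
Meso,kidneys,auc_0_inf,440,printed
Meso,kidneys,auc_0_72,270,printed
Meso,kidneys,cl,0.91,printed
Meso,kidneys,vdss,77.22,printed
Meso,kidneys,t_half,57.75,printed
SA,plasma,cmax,8.2,printed
SA,plasma,tmax,0,printed
SA,plasma,auc_0_inf,49,printed
SA,plasma,auc_0_72,38,printed
SA,plasma,cl,8.08,printed
SA,plasma,vdss,344.76,printed
SA,plasma,t_half,30.13,printed
SA,lungs,cmax,6.8,printed
SA,lungs,tmax,0.42,printed
SA,lungs,auc_0_inf,170,printed
SA,lungs,auc_0_72,160,printed
SA,lungs,cl,2.32,printed
SA,lungs,vdss,58.61,printed
SA,lungs,t_half,17.32,printed
SA,mps,cmax,130,printed
SA,mps,tmax,1.92,printed
SA,mps,auc_0_72,8520,printed
SA,kidneys,cmax,6,printed
SA,kidneys,tmax,0,printed
SA,kidneys,auc_0_inf,81,printed
SA,kidneys,auc_0_72,55,printed
SA,kidneys,cl,4.96,printed
SA,kidneys,vdss,320.02,printed
SA,kidneys,t_half,46.2,printed
Stober,plasma,cmax,7.5,printed
Stober,plasma,tmax,0,printed
Stober,plasma,auc_0_inf,83,printed
Stober,plasma,auc_0_72,58,printed
Stober,plasma,cl,4.84,printed
Stober,plasma,vdss,186.58,printed
Stober,plasma,t_half,26.65,printed
Stober,lungs,cmax,6.8,printed
Stober,lungs,tmax,0.42,printed
Stober,lungs,auc_0_inf,170,printed
Stober,lungs,auc_0_72,160,printed
Stober,lungs,cl,2.32,printed
Stober,lungs,vdss,58.61,printed
Stober,lungs,t_half,17.32,printed
Stober,mps,cmax,100,printed
Stober,mps,tmax,72,parsed-with-caution
Stober,mps,auc_0_72,6450,printed
Stober,kidneys,cmax,9.6,printed
Stober,kidneys,tmax,0,printed
Stober,kidneys,auc_0_inf,640,printed
Stober,kidneys,auc_0_72,120,printed
Stober,kidneys,cl,0.62,printed
Stober,kidneys,vdss,115.46,printed
Stober,kidneys,t_half,128.33,printed
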