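np_label,species,parameter,value,provenance
8A,mouse,f_lu,0.121,printed
8A,mouse,f_mps,0.073,printed
8A,mouse,f_k,0.907,printed
8A,mouse,f_o,0.541,printed
8A,mouse,q_mps,4.17,printed
8A,mouse,q_o,9.564,printed
8A,mouse,k_e_mps,0.032,printed
8A,mouse,k_e_k,27.3,printed
AR8,mouse,f_lu,0.011,printed
AR8,mouse,f_mps,0.003,printed
AR8,mouse,f_k,0.596,printed
AR8,mouse,f_o,0.029,printed
AR8,mouse,q_mps,19.0,printed
AR8,mouse,q_o,3.492,printed
AR8,mouse,k_e_mps,0.016,printed
AR8,mouse,k_e_k,21.7,printed
MA,mouse,f_lu,0.999,printed
MA,mouse,f_mps,0.497,printed
MA,mouse,f_k,0.926,printed
MA,mouse,f_o,0.508,printed
MA,mouse,q_mps,0.032,printed
MA,mouse,q_o,6.962,printed
MA,mouse,k_e_mps,0.009,printed
MA,mouse,k_e_k,32.6,printed
Meso,mouse,f_lu,0.006,printed
Meso,mouse,f_mps,0.005,printed
Meso,mouse,f_k,0.513,printed
Meso,mouse,f_o,0.065,printed
Meso,mouse,q_mps,3.08,printed
Meso,mouse,q_o,1.649,printed
Meso,mouse,k_e_mps,0.01,printed
Meso,mouse,k_e_k,3.41,text-vs-table-conflict
SA,mouse,f_lu,0.718,printed
SA,mouse,f_mps,0.0057,printed
SA,mouse,f_k,0.747,printed
SA,mouse,f_o,0.083,printed
SA,mouse,q_mps,60.9,printed
SA,mouse,q_o,76.078,printed
SA,mouse,k_e_mps,0.0025,printed
SA,mouse,k_e_k,2.21,printed
Stober,mouse,f_lu,0.478,printed
Stober,mouse,f_mps,0.002,printed
Stober,mouse,f_k,0.541,printed
Stober,mouse,f_o,0.019,printed
Stober,mouse,q_mps,35.6,printed
Stober,mouse,q_o,4.858,printed
Stober,mouse,k_e_mps,0.003,printed
Stober,mouse,k_e_k,5.4,printed
C dots,human,f_lu,0.889,printed
C dots,human,f_mps,0.155,printed
C dots,human,f_k,0.078,printed
C dots,human,f_o,0.964,printed
C dots,human,q_mps,80854,printed
C dots,human,q_o,165380,printed
C dots,human,k_e_mps,0.452,printed
C dots,human,k_e_k,2.67e-4,printed
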