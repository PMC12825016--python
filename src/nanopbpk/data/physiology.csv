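species,parameter,value,provenance
mouse,v_p,1.7,printed
mouse,v_mps,1.56,printed
mouse,v_lu,0.514,printed
mouse,v_k,0.496,printed
mouse,v_o,13.2,printed
mouse,q_lu,667,printed
mouse,q_mps,113.4,printed
mouse,q_k,78,printed
mouse,q_o,60,printed
mouse,bw,0.02,printed
human,v_p,3000,printed
human,v_mps,1882,derived-sum
human,v_lu,1170,printed
human,v_k,280,printed
human,v_o,38453.9,derived-sum
human,q_lu,330000,printed
human,q_mps,87000,printed
human,q_k,74400,printed
human,q_o,167400,printed
human,bw,70,printed
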