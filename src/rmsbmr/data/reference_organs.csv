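organ,msbmr_k,w0k_r,wk_r
skeletal_muscle,13.0,28.0,27.46
liver,200.0,1.8,1.78
brain,240.0,1.4,1.38
heart,440.0,0.33,0.32
kidneys,440.0,0.31,0.30
adipose_tissue,5.0,15.0,13.18
residual,4.5,23.16,22.57
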