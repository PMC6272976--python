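condition,level,RS,T,IS,mu_m,X0,Xm,R2_biomass,alpha,beta,R2_product
RS,80,80,30,3,0.186,0.017,0.396,0.976,352.453,6.770,0.979
RS,130,130,30,3,0.201,0.021,0.567,0.978,95.433,42.558,0.969
RS,200,200,30,3,0.214,0.017,0.451,0.988,106.824,46.014,0.971
T,10,130,10,3,0.198,0.009,0.329,0.96,458.271,0.000,0.993
T,20,130,20,3,0.257,0.008,0.553,0.972,300.319,20.764,0.961
T,30,130,30,3,0.217,0.014,0.577,0.974,280.334,23.532,0.97
IS,2,130,30,2,0.255,0.007,0.504,0.978,341.826,17.908,0.96
IS,3,130,30,3,0.214,0.016,0.655,0.976,330.606,16.432,0.981
IS,4,130,30,4,0.190,0.026,0.726,0.968,262.767,13.541,0.979
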