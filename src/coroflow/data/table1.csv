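# 27-case validation cohort: per-case FFR, percentage stenosis (operator
# visual / 2D QCA / 3D QCA), absolute coronary flow Q (mL/min) and
# microvascular resistance Rmicro (mmHg min/L) measured invasively by
# continuous-infusion thermodilution (CIT) and computed with the regional
# porous-wall method (CFD).
vessel,case,ffr,sten_op,sten_2d,sten_3d,q_cit,q_cfd,rmicro_cit,rmicro_cfd
LAD,1,0.87,10,16,11,343,459,250,184
LAD,2,0.82,0,15,22,182,302,340,191
LAD,3,0.69,10,29,34,192,219,320,276
LAD,4,0.83,15,31,30,197,241,320,259
LAD,5,0.83,15,9,8,215,316,310,196
LAD,6,0.85,5,17,16,202,148,410,547
LAD,7,0.84,5,19,11,177,283,280,164
LAD,8,0.81,0,0,0,278,192,210,274
LAD,9,0.86,20,16,15,217,229,350,330
LAD,10,0.86,0,0,0,330,157,210,410
LAD,11,0.97,0,0,0,234,103,360,761
LAD,12,0.74,35,43,55,66,74,1140,992
LAD,13,0.83,40,31,33,123,129,520,462
LAD,14,0.95,25,18,37,185,88,460,969
LAD,15,0.93,0,0,0,239,350,320,203
LAD,16,0.81,10,10,11,226,258,390,329
LAD,17,0.91,35,33,32,155,87,450,793
LAD,18,0.93,20,32,39,206,169,400,482
LCx,19,0.98,0,0,0,333,234,290,402
LCx,20,0.95,45,53,43,247,324,360,253
LCx,21,0.88,50,39,33,215,314,600,392
LCx,22,0.78,40,31,15,130,176,580,420
LCx,23,0.93,15,9,12,259,373,270,176
LCx,24,0.96,0,0,0,197,199,540,521
LCx,25,0.96,0,0,0,265,91,250,716
RCA,26,0.96,5,12,19,242,178,400,538
RCA,27,0.97,10,26,23,250,204,390,465
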