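name,abbreviation,domain,timepoint,unit,network
hei,HEI,diet,baseline,score,1
hei_no_oil,HEI1,diet,baseline,score,1
vitamin_b6,B6,b_vitamins,baseline,nm/L,1
vitamin_b12,B12,b_vitamins,baseline,pg/mL,1
behenic_acid,1,fatty_acid,baseline,% total FA,1
lignoceric_acid,2,fatty_acid,baseline,% total FA,1
nervonic_acid,3,fatty_acid,baseline,% total FA,1
dha,4,fatty_acid,baseline,% total FA,1
total_n3,5,fatty_acid,baseline,% total FA,1
fa_06,6,fatty_acid,baseline,% total FA,1
fa_07,7,fatty_acid,baseline,% total FA,1
fa_08,8,fatty_acid,baseline,% total FA,1
fa_09,9,fatty_acid,baseline,% total FA,1
fa_10,10,fatty_acid,baseline,% total FA,1
fa_11,11,fatty_acid,baseline,% total FA,1
fa_12,12,fatty_acid,baseline,% total FA,1
fa_13,13,fatty_acid,baseline,% total FA,1
fa_14,14,fatty_acid,baseline,% total FA,1
fa_15,15,fatty_acid,baseline,% total FA,1
fa_16,16,fatty_acid,baseline,% total FA,1
fa_17,17,fatty_acid,baseline,% total FA,1
fa_18,18,fatty_acid,baseline,% total FA,1
fa_19,19,fatty_acid,baseline,% total FA,1
fa_20,20,fatty_acid,baseline,% total FA,1
fa_21,21,fatty_acid,baseline,% total FA,1
fa_22,22,fatty_acid,baseline,% total FA,1
fa_23,23,fatty_acid,baseline,% total FA,1
fa_24,24,fatty_acid,baseline,% total FA,1
fa_25,25,fatty_acid,baseline,% total FA,1
fa_26,26,fatty_acid,baseline,% total FA,1
crp,CRP,immune,year12,mg/L,1
il6,IL-6,immune,year12,pg/mL,1
tnf_alpha,TNFa,immune,year12,pg/mL,1
total_cholesterol,Cholesterol,lipids,year12,mg/dL,1
ldl,LDL,lipids,year12,mg/dL,1
hdl,HDL,lipids,year12,mg/dL,1
triglycerides,TG,lipids,year12,mg/dL,1
phosphorus,Phosphorus,other_blood,year12,mg/dL,1
creatinine,Creatinine,other_blood,year12,mg/dL,1
glucose,Glucose,other_blood,year12,mg/dL,1
klotho,Klotho,other_blood,year12,pg/mL,1
fgf23,Fgf23,other_blood,year12,nmol/L,1
cvr,CVR,clinical,year12,count,1
bmi,BMI,clinical,year12,kg/m2,1
wm_nd_left_ifof,WM #1,wm_nd,year12,ND,1
wm_nd_right_ifof,WM #2,wm_nd,year12,ND,1
wm_nd_left_ilf,WM #3,wm_nd,year12,ND,1
wm_nd_right_ilf,WM #4,wm_nd,year12,ND,1
wm_nd_left_slft,WM #5,wm_nd,year12,ND,1
wm_nd_right_slft,WM #6,wm_nd,year12,ND,1
wm_od_left_ifof,OD #1,wm_od,year12,OD,0
wm_od_right_ifof,OD #2,wm_od,year12,OD,0
wm_od_left_ilf,OD #3,wm_od,year12,OD,0
wm_od_right_ilf,OD #4,wm_od,year12,OD,0
wm_od_left_slft,OD #5,wm_od,year12,OD,0
wm_od_right_slft,OD #6,wm_od,year12,OD,0
left_hippocampus,LHip,gm_volume,year12,mm3,0
right_hippocampus,RHip,gm_volume,year12,mm3,0
icv,ICV,gm_volume,year12,mm3,0
mmse,MMSE,cognition,year12,score,0
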