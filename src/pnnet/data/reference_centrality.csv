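node,degree,betweenness,closeness
sleep,5,11.33,0.040
depression,4,9.33,0.045
anxiety,3,0,0.037
oral_pain,3,3.67,0.042
fatigue,5,9,0.048
cortisol_slope,1,0,0.028
crp,3,15.67,0.048
il6,4,25.33,0.045
il10,2,0,0.033
tnfa,3,10,0.034
age,2,8.67,0.043
bmi,1,0,0.026
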