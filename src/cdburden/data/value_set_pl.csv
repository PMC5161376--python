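term,dimension,level,decrement
constant_any_problem,,,0.148
any_level_3,,,0.256
main,mobility,2,0.098
main,mobility,3,0.245
main,self_care,2,0.049
main,self_care,3,0.129
main,usual_activities,2,0.044
main,usual_activities,3,0.117
main,pain,2,0.080
main,pain,3,0.252
main,anxiety,2,0.063
main,anxiety,3,0.205
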