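patient_id,femur_id,physician_risk,bos_risk,treatment,fractured_6mo,died_6mo,delivery_days,bos_used
P01,F01,low,low,none,0,1,0,1
P01,F02,low,low,rt_single,0,1,0,1
P02,F03,low,low,rt_single,0,0,0,1
P02,F04,low,low,rt_single,0,0,0,1
P03,F05,low,low,rt_single,0,0,0,1
P03,F06,low,low,rt_multiple,0,0,0,1
P04,F07,low,moderate,rt_single,0,1,0,1
P05,F08,low,moderate,rt_multiple,0,0,0,1
P06,F09,low,moderate,rt_multiple,0,1,0,1
P07,F10,low,moderate,rt_multiple,0,0,0,1
P08,F11,low,moderate,rt_multiple,0,1,0,1
P09,F12,low,moderate,rt_multiple,0,0,0,1
P10,F13,low,moderate,rt_multiple,0,0,0,1
P11,F14,low,high,rt_single,0,1,0,0
P12,F15,low,high,rt_single,0,0,1,0
P13,F16,low,high,rt_single,0,0,1,1
P14,F17,low,high,rt_multiple,1,1,1,1
P15,F18,low,high,rt_multiple,0,0,1,1
P16,F19,low,high,rt_multiple,0,0,1,1
P17,F20,low,high,rt_multiple,0,1,1,1
P18,F21,low,high,rt_multiple,0,0,1,1
P19,F22,low,high,rt_multiple,0,0,1,1
P20,F23,low,high,rt_multiple,0,1,1,1
P21,F24,low,high,rt_multiple,0,0,1,1
P22,F25,low,high,rt_multiple,0,0,1,1
P23,F26,low,high,rt_multiple,0,1,1,1
P24,F27,low,high,rt_multiple,0,0,1,1
P25,F28,low,high,elective_surgery,0,0,1,1
P26,F29,high,low,rt_single,0,1,1,1
P27,F30,high,low,rt_single,0,0,1,1
P28,F31,high,low,rt_multiple,0,0,1,1
P29,F32,high,low,rt_multiple,0,1,1,1
P30,F33,high,low,rt_multiple,0,0,1,1
P31,F34,high,low,rt_multiple,0,0,1,1
P32,F35,high,low,rt_multiple,0,1,1,1
P33,F36,high,moderate,none,0,0,1,1
P34,F37,high,moderate,rt_multiple,0,0,1,1
P35,F38,high,high,elective_surgery,1,1,2,1
P36,F39,high,high,elective_surgery,1,0,2,1
P37,F40,high,high,elective_surgery,0,0,2,1
P38,F41,high,high,elective_surgery,0,0,2,1
P39,F42,high,high,elective_surgery,0,0,2,1
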