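round,field,agree_num,agree_den,improve_num,improve_den
1,pressure_relief,3,4,1.0,2.0
1,nutritional_management,4,4,1.0,1.0
1,shear_relief,4,4,,
1,moisture_management,3,4,1.0,2.0
1,wound_dressing_use,4,4,,
1,physical_factor,4,4,1.0,1.0
1,systemic_disorder,3,4,0.0,1.0
1,dressing_selection,4,4,3.0,3.0
1,wound_cleansing,4,4,1.0,1.0
2,pressure_relief,4,4,,
2,nutritional_management,4,4,1.0,1.0
2,shear_relief,3,4,1.0,2.0
2,moisture_management,4,4,,
2,wound_dressing_use,4,4,1.0,1.0
2,physical_factor,4,4,,
2,systemic_disorder,3,4,0.0,1.0
2,dressing_selection,1,4,0.0,3.0
2,wound_cleansing,0,4,0.0,4.0
3,pressure_relief,4,4,,
3,nutritional_management,3,4,2.0,3.0
3,shear_relief,4,4,3.0,3.0
3,moisture_management,3,4,1.0,2.0
3,wound_dressing_use,4,4,,
3,physical_factor,4,4,,
3,systemic_disorder,3,4,1.0,2.0
3,dressing_selection,3,4,3.0,4.0
3,wound_cleansing,4,4,3.0,3.0
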